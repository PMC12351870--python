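"""In-memory containers for genotype panels, dosage matrices and truth tables.

The central object is :class:`GenotypeMatrix`: an ``n_samples x n_snps`` dosage
matrix (copies of the counted A1 allele, ``0/1/2``, ``NaN`` for missing calls)
together with per-SNP metadata (the *panel*) and ordered sample IDs. It is the
post-parse, pre-encoding representation shared by the PLINK readers, the QC
stage and the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]

#: truth-table category used for any crossbred individual
HYBRID = "hybrid"


def make_panel(
    snp_ids, chrom, pos, a1, a2
) -> pd.DataFrame:
    """Assemble and validate a SNP panel table.

    ``a1`` is the counted allele (dosage = copies of A1), matching the first
    allele column of PLINK ``.bim``/``.map`` files; positions are 1-based.
    """
    panel = pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids, dtype=object),
            "chrom": np.asarray(chrom, dtype=object).astype(str),
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": np.asarray(a1, dtype=object),
            "a2": np.asarray(a2, dtype=object),
        }
    )
    validate_panel(panel)
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if panel["snp_id"].duplicated().any():
        dup = panel.loc[panel["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate SNP id: {dup!r}")
    if (panel["pos"] < 0).any():
        raise ValueError("SNP positions must be >= 0")
    same = panel["a1"] == panel["a2"]
    if same.any():
        bad = panel.loc[same, "snp_id"].iloc[0]
        raise ValueError(f"SNP {bad!r} has identical A1/A2 alleles")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with metadata.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers.
    panel : pandas.DataFrame
        SNP metadata with columns ``snp_id, chrom, pos, a1, a2``.
    dosage : ndarray of float
        ``(n_samples, n_snps)``; entries in ``{0, 1, 2}`` or ``NaN`` (missing).
    """

    samples: list[str]
    panel: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        validate_panel(self.panel)
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(
                f"dosage has {n} rows but {len(self.samples)} sample IDs"
            )
        if m != len(self.panel):
            raise ValueError(
                f"dosage has {m} columns but panel lists {len(self.panel)} SNPs"
            )
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.panel)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.panel["snp_id"].to_numpy()

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosage).any())

    def select_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the SNP columns in ``index`` (positional)."""
        return GenotypeMatrix(
            samples=list(self.samples),
            panel=self.panel.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
        )

    def select_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            panel=self.panel.copy(),
            dosage=self.dosage[index, :].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.panel[PANEL_COLUMNS].equals(other.panel[PANEL_COLUMNS])
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class FeatureMatrix:
    """One-hot genotype features: ``n_samples x (3 * n_snps)`` binary matrix.

    Column ``3*j + d`` is the indicator of dosage class ``d`` at SNP ``j``;
    each 3-column SNP block contains exactly one ``1`` per sample.
    """

    values: np.ndarray = field(repr=False)
    columns: list[tuple[str, int]]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.samples), len(self.columns)):
            raise ValueError("feature matrix shape does not match metadata")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def validate_truth_table(truth: pd.DataFrame, n_breeds: int | None = None) -> None:
    """Check a truth table: sample_id, category, q_1..q_K on the simplex."""
    for col in ("sample_id", "category"):
        if col not in truth.columns:
            raise ValueError(f"truth table missing column {col!r}")
    qcols = [c for c in truth.columns if c.startswith("q_")]
    if n_breeds is not None and len(qcols) != n_breeds:
        raise ValueError(f"expected {n_breeds} ancestry columns, found {len(qcols)}")
    q = truth[qcols].to_numpy(dtype=float)
    if (q < -1e-9).any() or (q > 1 + 1e-9).any():
        raise ValueError("ancestry proportions must lie in [0, 1]")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ancestry proportions must sum to 1")


def truth_q_matrix(truth: pd.DataFrame) -> np.ndarray:
    """Extract the K-column ancestry matrix from a truth table."""
    qcols = sorted(
        (c for c in truth.columns if c.startswith("q_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    return truth[qcols].to_numpy(dtype=float)
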