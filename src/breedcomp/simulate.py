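"""Synthetic multi-breed SNP population simulator.

Breed allele frequencies follow the Balding–Nichols model: for SNP *j* an
ancestral frequency ``p0_j`` is drawn uniformly from ``ancestral_maf_range``
and each breed's frequency from ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)``, whose
mean is ``p0`` and variance ``F p0 (1-p0)`` — so ``F`` plays the role of the
FST-like divergence between breeds. Within a breed genotypes are in
Hardy–Weinberg equilibrium (``Binomial(2, p_kj)``); an F1 cross draws one
allele from each parental breed; a general admixed individual with ancestry
``q`` draws each of its two alleles from breed ``k`` with probability
``q_k``. Missing calls are masked i.i.d. at ``missing_rate``.

The defaults emulate a three-breed pig study design (two highly used
maternal breeds plus a terminal sire breed, with maternal-line F1 hybrids):
``F = 0.15``, 1,000 SNPs, 300 purebreds per breed plus 150 F1 crosses for
training, and an independent test population drawn from the *same* breed
frequencies with a fresh seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import HYBRID, GenotypeMatrix, make_panel

DEFAULT_BREEDS = ("Yorkshire", "Landrace", "Duroc")


@dataclass(frozen=True)
class CrossSpec:
    """A cross between two breeds: each individual has ancestry
    (proportion_a, 1 - proportion_a) from (breed_a, breed_b)."""

    breed_a: str
    breed_b: str
    proportion_a: float = 0.5
    n_individuals: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion_a < 1.0:
            raise ValueError("proportion_a must lie strictly in (0, 1)")
        if self.breed_a == self.breed_b:
            raise ValueError("a cross needs two distinct parental breeds")


@dataclass
class SimConfig:
    """Full specification of a synthetic multi-breed study."""

    breeds: tuple[str, ...] = DEFAULT_BREEDS
    n_snps: int = 1000
    fst: float = 0.15
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    breed_sizes: tuple[int, ...] = (300, 300, 300)
    crosses: tuple[CrossSpec, ...] = (CrossSpec("Yorkshire", "Landrace", 0.5, 150),)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.breed_sizes) != len(self.breeds):
            raise ValueError("breed_sizes must match the number of breeds")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(
                "fst must lie strictly in (0, 1); use a small floor such as "
                "1e-4 instead of 0"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for cross in self.crosses:
            for b in (cross.breed_a, cross.breed_b):
                if b not in self.breeds:
                    raise ValueError(f"cross references unknown breed {b!r}")

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        crosses = tuple(CrossSpec(**c) for c in raw.pop("crosses", []))
        for key in ("breeds", "breed_sizes", "ancestral_maf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(crosses=crosses, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["crosses"] = [asdict(c) for c in self.crosses]
        for key in ("breeds", "breed_sizes", "ancestral_maf_range"):
            raw[key] = list(raw[key])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def sample_breed_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-breed allele frequencies, shape ``(n_breeds, n_snps)``.

    Frequencies are clipped into ``(1e-6, 1 - 1e-6)`` so downstream binomial
    draws and likelihoods never see a degenerate frequency.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_maf_range
    p0 = rng.uniform(lo, hi, size=cfg.n_snps)
    f = cfg.fst
    a = p0 * (1 - f) / f
    b = (1 - p0) * (1 - f) / f
    freqs = rng.beta(a[None, :], b[None, :], size=(cfg.n_breeds, cfg.n_snps))
    return np.clip(freqs, 1e-6, 1 - 1e-6)


def sample_genotypes(
    freqs: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "S",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw genotypes for all purebreds and crosses in ``cfg``.

    Returns the genotype matrix and a truth table with columns
    ``sample_id, category, q_1..q_K`` (``category`` is the breed name for
    purebreds, ``"hybrid"`` for any cross).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    k, m = freqs.shape
    if k != cfg.n_breeds or m != cfg.n_snps:
        raise ValueError("frequency table shape does not match config")

    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    counter = 0

    def record(category: str, q: np.ndarray) -> str:
        nonlocal counter
        counter += 1
        sid = f"{sample_prefix}{counter:05d}"
        row = {"sample_id": sid, "category": category}
        row.update({f"q_{i + 1}": q[i] for i in range(k)})
        truth_rows.append(row)
        return sid

    for b, (breed, size) in enumerate(zip(cfg.breeds, cfg.breed_sizes)):
        if size == 0:
            continue
        dosage = rng.binomial(2, freqs[b][None, :], size=(size, m)).astype(np.float64)
        rows.append(dosage)
        q = np.zeros(k)
        q[b] = 1.0
        for _ in range(size):
            record(breed, q)

    for cross in cfg.crosses:
        if cross.n_individuals == 0:
            continue
        ia = cfg.breeds.index(cross.breed_a)
        ib = cfg.breeds.index(cross.breed_b)
        q = np.zeros(k)
        q[ia] += cross.proportion_a
        q[ib] += 1 - cross.proportion_a
        if cross.proportion_a == 0.5:
            # F1: one allele from each parental breed
            dosage = (
                rng.binomial(1, freqs[ia][None, :], size=(cross.n_individuals, m))
                + rng.binomial(1, freqs[ib][None, :], size=(cross.n_individuals, m))
            ).astype(np.float64)
        else:
            # general admixture: each allele's breed of origin ~ q
            origin = rng.random(size=(cross.n_individuals, m, 2)) < q[ia]
            p = np.where(origin, freqs[ia][None, :, None], freqs[ib][None, :, None])
            dosage = (rng.random(size=p.shape) < p).sum(axis=2).astype(np.float64)
        rows.append(dosage)
        for _ in range(cross.n_individuals):
            record(HYBRID, q)

    if not rows:
        raise ValueError("config generates no individuals")
    dosage = np.concatenate(rows, axis=0)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    panel = make_panel(
        snp_ids=[f"snp{j + 1}" for j in range(m)],
        chrom=["1"] * m,
        pos=np.arange(1, m + 1) * 1000,
        a1=["A"] * m,  # counted (alternate) allele; lexically before A2
        a2=["G"] * m,
    )
    truth = pd.DataFrame(truth_rows)
    g = GenotypeMatrix(
        samples=truth["sample_id"].tolist(), panel=panel, dosage=dosage
    )
    return g, truth


def simulate(cfg: SimConfig, sample_prefix: str = "S") -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Frequencies + genotypes in one call; returns (genotypes, truth, freqs)."""
    rng = np.random.default_rng(cfg.seed)
    freqs = sample_breed_frequencies(cfg, rng)
    g, truth = sample_genotypes(freqs, cfg, rng, sample_prefix=sample_prefix)
    return g, truth, freqs


def sample_population_pair(
    cfg: SimConfig,
    test_breed_sizes: tuple[int, ...] = (100, 100, 100),
    test_cross_sizes: tuple[int, ...] | None = (100,),
    test_seed_offset: int = 104729,
) -> tuple[tuple[GenotypeMatrix, pd.DataFrame], tuple[GenotypeMatrix, pd.DataFrame], np.ndarray]:
    """Simulate a training population and an independent test population.

    Both populations share the same breed allele frequencies (the same
    breeds) but are drawn with distinct seeds — emulating a cross-validation
    population and a genetically connected independent population.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = sample_breed_frequencies(cfg, rng)
    g1, t1 = sample_genotypes(freqs, cfg, rng, sample_prefix="P1_")

    if test_cross_sizes is None:
        test_cross_sizes = tuple(c.n_individuals for c in cfg.crosses)
    test_cfg = SimConfig(
        breeds=cfg.breeds,
        n_snps=cfg.n_snps,
        fst=cfg.fst,
        ancestral_maf_range=cfg.ancestral_maf_range,
        breed_sizes=tuple(test_breed_sizes),
        crosses=tuple(
            CrossSpec(c.breed_a, c.breed_b, c.proportion_a, n)
            for c, n in zip(cfg.crosses, test_cross_sizes)
        ),
        missing_rate=cfg.missing_rate,
        seed=cfg.seed + test_seed_offset,
    )
    rng2 = np.random.default_rng(test_cfg.seed)
    g2, t2 = sample_genotypes(freqs, test_cfg, rng2, sample_prefix="P2_")
    return (g1, t1), (g2, t2), freqs


def write_fixture(g: GenotypeMatrix, truth: pd.DataFrame, prefix, dialect: str = "bed_bim_fam") -> None:
    """Write PLINK files plus the truth table TSV next to them."""
    from .plink import write_plink

    prefix = Path(prefix)
    write_plink(g, prefix, dialect=dialect)
    out = truth.copy()
    qcols = [c for c in out.columns if c.startswith("q_")]
    out[qcols] = out[qcols].map(lambda v: f"{v:.6f}")
    out.to_csv(prefix.parent / (prefix.name + ".truth.tsv"), sep="\t", index=False)
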