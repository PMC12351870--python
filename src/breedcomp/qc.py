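"""Per-SNP genotype quality control and missing-call imputation.

Three filters, applied to every SNP on non-missing calls only:

* call rate — fraction of genotyped samples; SNPs below ``call_rate_min`` go;
* minor allele frequency — SNPs with MAF below ``maf_min`` go (monomorphic
  SNPs have MAF 0 and always fail);
* Hardy–Weinberg equilibrium — a two-sided exact test on the heterozygote
  count conditional on the allele counts; SNPs with P strictly below
  ``hwe_p_floor`` go.

A SNP failing several rules is attributed to the first failing rule in the
fixed order (call rate, MAF, HWE) in the report; the surviving set itself is
order-independent because every surviving SNP passes all three rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds: MAF < maf_min, call rate < call_rate_min, HWE P < hwe_p_floor."""

    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    n_input_snps: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_surviving: int
    per_snp: pd.DataFrame = field(repr=False)  # snp_id, status, maf, call_rate, hwe_p

    def to_tsv(self, path) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False, float_format="%.6g")


class AllSNPsRemovedError(ValueError):
    """QC removed every SNP in the panel."""


def hwe_exact_pvalue(n_het: int, n_hom_a1: int, n_hom_a2: int) -> float:
    """Two-sided exact Hardy–Weinberg test P-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (Wigginton-style exact test, as used by PLINK's ``--hwe``).
    """
    for v in (n_het, n_hom_a1, n_hom_a2):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_a1 + n_hom_a2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_a1, n_hom_a2) + n_het  # rare-allele count
    # possible heterozygote counts share the parity of n_rare
    het_lo = n_rare % 2
    het_hi = min(n_rare, 2 * n - n_rare)

    # conditional distribution of the het count given the allele counts:
    # P(het) ∝ 2^het / (hom_r! het! hom_c!); computed in log space so
    # large sample sizes cannot overflow
    from scipy.special import gammaln, logsumexp

    n_hets = np.arange(het_lo, het_hi + 1, 2)
    hom_r = (n_rare - n_hets) // 2
    hom_c = n - n_hets - hom_r
    logw = (
        n_hets * np.log(2.0)
        - gammaln(hom_r + 1.0)
        - gammaln(n_hets + 1.0)
        - gammaln(hom_c + 1.0)
    )
    probs = np.exp(logw - logsumexp(logw))

    p_obs = probs[(n_hets == n_het)][0] if n_het in n_hets else 0.0
    if p_obs == 0.0:
        raise ValueError(
            f"heterozygote count {n_het} impossible given allele counts"
        )
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_statistics(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, MAF and HWE exact P, from non-missing calls."""
    d = g.dosage
    observed = ~np.isnan(d)
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / g.n_samples

    n_hom_a1 = np.nansum(d == 2, axis=0)
    n_het = np.nansum(d == 1, axis=0)
    n_hom_a2 = np.nansum(d == 0, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a1 = (2 * n_hom_a1 + n_het) / (2 * n_obs)
    maf = np.minimum(p_a1, 1 - p_a1)
    maf = np.where(n_obs > 0, maf, 0.0)

    hwe_p = np.array(
        [
            hwe_exact_pvalue(int(h), int(a), int(b)) if nob > 0 else 1.0
            for h, a, b, nob in zip(n_het, n_hom_a1, n_hom_a2, n_obs)
        ]
    )
    return pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )


def apply_qc(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by call rate, MAF and HWE; samples are never removed.

    Returns the filtered matrix (surviving genotype values untouched) and a
    :class:`QCReport` attributing each removed SNP to its first failing rule.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if g.n_samples < 2:
        raise ValueError("QC requires at least 2 samples")

    stats = snp_statistics(g)
    fail_cr = stats["call_rate"].to_numpy() < thresholds.call_rate_min
    fail_maf = stats["maf"].to_numpy() < thresholds.maf_min
    fail_hwe = stats["hwe_p"].to_numpy() < thresholds.hwe_p_floor

    status = np.full(g.n_snps, "pass", dtype=object)
    status[fail_hwe] = "fail_hwe"
    status[fail_maf] = "fail_maf"  # earlier rules take attribution precedence
    status[fail_cr] = "fail_callrate"
    stats["status"] = status

    keep = status == "pass"
    report = QCReport(
        n_input_snps=g.n_snps,
        n_removed_callrate=int((status == "fail_callrate").sum()),
        n_removed_maf=int((status == "fail_maf").sum()),
        n_removed_hwe=int((status == "fail_hwe").sum()),
        n_surviving=int(keep.sum()),
        per_snp=stats[["snp_id", "status", "call_rate", "maf", "hwe_p"]],
    )
    if report.n_surviving == 0:
        raise AllSNPsRemovedError(
            "all SNPs removed by QC "
            f"(call rate: {report.n_removed_callrate}, MAF: {report.n_removed_maf}, "
            f"HWE: {report.n_removed_hwe})"
        )
    return g.select_snps(np.flatnonzero(keep)), report


def impute_missing(g: GenotypeMatrix, strategy: str = "mode") -> GenotypeMatrix:
    """Fill missing calls per SNP from that SNP's observed calls.

    ``mode``: most frequent observed dosage (ties toward the smaller value);
    ``mean_rounded``: observed mean rounded half away from zero to {0,1,2}.
    """
    if strategy not in ("mode", "mean_rounded"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if not g.has_missing():
        return g
    d = g.dosage.copy()
    missing = np.isnan(d)
    for j in np.flatnonzero(missing.any(axis=0)):
        obs = d[~missing[:, j], j]
        if obs.size == 0:
            raise ValueError(
                f"SNP {g.snp_ids[j]!r} has no observed calls; cannot impute"
            )
        if strategy == "mode":
            counts = [(obs == v).sum() for v in (0.0, 1.0, 2.0)]
            fill = float(np.argmax(counts))
        else:
            fill = float(min(2, int(np.floor(obs.mean() + 0.5))))
        d[missing[:, j], j] = fill
    return GenotypeMatrix(samples=list(g.samples), panel=g.panel.copy(), dosage=d)
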