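"""Balding–Nichols simulator: distributional oracles and determinism."""

import hashlib

import numpy as np
import pytest
from scipy import stats

from breedcomp import CrossSpec, SimConfig, read_plink, simulate, write_fixture
from breedcomp.simulate import sample_breed_frequencies, sample_genotypes


def test_beta_variance_matches_closed_form():
    """At p0 = 0.3, F = 0.15 the breed-frequency variance is F p0 (1-p0)."""
    cfg = SimConfig(
        breeds=("A", "B"), breed_sizes=(2, 2), crosses=(),
        n_snps=10_000, fst=0.15, ancestral_maf_range=(0.3, 0.3), seed=5,
    )
    freqs = sample_breed_frequencies(cfg)
    expected = 0.15 * 0.3 * 0.7  # 0.0315
    assert np.var(freqs) == pytest.approx(expected, rel=0.05)
    assert np.mean(freqs) == pytest.approx(0.3, abs=0.01)


def test_small_fst_shrinks_breed_frequencies_to_ancestral():
    cfg = SimConfig(
        breeds=("A", "B"), breed_sizes=(2, 2), crosses=(),
        n_snps=2_000, fst=1e-4, ancestral_maf_range=(0.3, 0.3), seed=5,
    )
    freqs = sample_breed_frequencies(cfg)
    assert np.abs(freqs - 0.3).max() < 0.05


def test_fst_zero_rejected():
    with pytest.raises(ValueError, match="floor"):
        SimConfig(breeds=("A", "B"), breed_sizes=(2, 2), crosses=(), fst=0.0)


def test_frequency_table_is_seed_deterministic():
    cfg = SimConfig(seed=9)
    assert np.array_equal(sample_breed_frequencies(cfg), sample_breed_frequencies(cfg))


def test_f1_mean_dosage_is_sum_of_parental_frequencies():
    cfg = SimConfig(
        n_snps=10, breed_sizes=(0, 0, 0), missing_rate=0.0, seed=2,
        crosses=(CrossSpec("Yorkshire", "Landrace", 0.5, 5000),),
    )
    freqs = sample_breed_frequencies(cfg)
    g, truth = sample_genotypes(freqs, cfg)
    expected = freqs[0] + freqs[1]
    se = np.sqrt((freqs[0] * (1 - freqs[0]) + freqs[1] * (1 - freqs[1])) / 5000)
    assert (np.abs(g.dosage.mean(axis=0) - expected) < 3.5 * se).all()
    assert (truth["category"] == "hybrid").all()
    assert np.allclose(truth[["q_1", "q_2", "q_3"]].sum(axis=1), 1.0)


def test_purebred_genotypes_follow_binomial_hwe():
    """Pooled chi-square GOF of purebred genotype counts vs Binomial(2, p)."""
    cfg = SimConfig(
        n_snps=1000, breed_sizes=(500, 0, 0), crosses=(), missing_rate=0.0, seed=4
    )
    freqs = sample_breed_frequencies(cfg)
    g, _ = sample_genotypes(freqs, cfg)
    chi2 = 0.0
    df = 0
    for j in range(cfg.n_snps):
        p = freqs[0, j]
        exp = 500 * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        if exp.min() < 5:  # chi-square validity rule
            continue
        obs = np.array([(g.dosage[:, j] == v).sum() for v in (0, 1, 2)])
        chi2 += ((obs - exp) ** 2 / exp).sum()
        df += 2
    assert stats.chi2.sf(chi2, df) > 0.001


def test_general_admixture_dosage_mean():
    """Ancestry (0.75, 0.25): each allele is alt with 0.75 p_a + 0.25 p_b."""
    cfg = SimConfig(
        breeds=("A", "B"), breed_sizes=(0, 0), n_snps=10, missing_rate=0.0, seed=8,
        crosses=(CrossSpec("A", "B", 0.75, 4000),),
    )
    freqs = sample_breed_frequencies(cfg)
    g, truth = sample_genotypes(freqs, cfg)
    p_mix = 0.75 * freqs[0] + 0.25 * freqs[1]
    se = np.sqrt(2 * p_mix * (1 - p_mix) / 4000)
    assert (np.abs(g.dosage.mean(axis=0) - 2 * p_mix) < 4 * se).all()
    assert truth["q_1"].iloc[0] == 0.75


def test_missing_rate_zero_and_nonzero():
    cfg0 = SimConfig(n_snps=50, breed_sizes=(30, 30, 30), crosses=(), missing_rate=0.0, seed=6)
    g0, _, _ = simulate(cfg0)
    assert not g0.has_missing()
    cfg1 = SimConfig(n_snps=50, breed_sizes=(30, 30, 30), crosses=(), missing_rate=0.1, seed=6)
    g1, _, _ = simulate(cfg1)
    rate = np.isnan(g1.dosage).mean()
    assert 0.05 < rate < 0.15


def test_unknown_cross_breed_rejected():
    with pytest.raises(ValueError, match="unknown breed"):
        SimConfig(crosses=(CrossSpec("Yorkshire", "Pietrain", 0.5, 10),))


def test_hudson_fst_recovers_configured_divergence():
    """Mean pairwise Hudson FST across simulated purebreds ~ configured F."""
    cfg = SimConfig(n_snps=2000, breed_sizes=(100, 100, 100), crosses=(), missing_rate=0.0, seed=13)
    g, truth, _ = simulate(cfg)
    cats = truth["category"].to_numpy()
    ests = []
    for a in range(3):
        for b in range(a + 1, 3):
            da = g.dosage[cats == cfg.breeds[a]]
            db = g.dosage[cats == cfg.breeds[b]]
            na, nb = len(da), len(db)
            p1, p2 = da.mean(axis=0) / 2, db.mean(axis=0) / 2
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (na - 1) - p2 * (1 - p2) / (nb - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            ests.append(num.sum() / den.sum())
    fst = np.mean(ests)
    assert 0.8 * cfg.fst < fst < 1.2 * cfg.fst


def test_fixture_write_is_byte_identical_across_reruns(tmp_path):
    cfg = SimConfig(n_snps=40, breed_sizes=(10, 10, 10), seed=21,
                    crosses=(CrossSpec("Yorkshire", "Duroc", 0.5, 5),))
    digests = []
    for run in ("a", "b"):
        g, truth, _ = simulate(cfg)
        prefix = tmp_path / run / "fx"
        write_fixture(g, truth, prefix)
        digests.append(hashlib.sha256((prefix.parent / "fx.bed").read_bytes()).hexdigest())
        back = read_plink(prefix)
        assert np.array_equal(back.dosage, g.dosage, equal_nan=True)
        truth_lines = (prefix.parent / "fx.truth.tsv").read_text().splitlines()
        assert len(truth_lines) == g.n_samples + 1  # header + one row per sample
    assert digests[0] == digests[1]


def test_yaml_config_round_trip(tmp_path):
    cfg = SimConfig(seed=33)
    cfg.to_yaml(tmp_path / "sim.yaml")
    assert SimConfig.from_yaml(tmp_path / "sim.yaml") == cfg
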