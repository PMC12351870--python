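"""Backend contracts: simplex validity, determinism, serialisation, oracles."""

import numpy as np
import pytest

from breedcomp import (
    MLPGBCRegressor,
    RandomForestGBC,
    SVRGBC,
    SupervisedAdmixture,
    load_model,
    make_backend,
    save_model,
)
from breedcomp.models import NotOnSimplexError, simplex_project


def _toy_two_breed(n_per=40, m=30, seed=0):
    """Two well-separated synthetic breeds, one-hot features + GBC targets."""
    rng = np.random.default_rng(seed)
    pa = rng.uniform(0.05, 0.3, size=m)
    pb = rng.uniform(0.7, 0.95, size=m)
    da = rng.binomial(2, pa, size=(n_per, m))
    db = rng.binomial(2, pb, size=(n_per, m))
    d = np.concatenate([da, db])
    x = np.zeros((2 * n_per, 3 * m))
    x[np.arange(2 * n_per)[:, None], 3 * np.arange(m)[None, :] + d] = 1
    y = np.zeros((2 * n_per, 2))
    y[:n_per, 0] = 1
    y[n_per:, 1] = 1
    return x, y


@pytest.fixture(scope="module")
def toy():
    return _toy_two_breed()


def test_simplex_project_properties():
    rng = np.random.default_rng(1)
    raw = rng.normal(0.3, 0.8, size=(50, 3))
    q = simplex_project(raw)
    assert (q >= 0).all() and (q <= 1).all()
    assert np.allclose(q.sum(axis=1), 1.0)
    with pytest.raises(NotOnSimplexError):
        simplex_project(np.array([[-1.0, -0.5, 0.0]]))


@pytest.mark.parametrize("backend", ["mlp", "rf", "svr", "likelihood"])
def test_all_backends_emit_simplex_valid_gbc(backend, toy):
    x, y = toy
    params = {"mlp": dict(hidden_sizes=(32,), max_epochs=30, random_state=0)}.get(backend, {})
    model = make_backend(backend, **params).fit(x, y)
    q = model.predict(x)
    assert q.shape == (x.shape[0], 2)
    assert (q >= 0).all() and (q <= 1 + 1e-9).all()
    assert np.allclose(q.sum(axis=1), 1.0, atol=1e-6)


@pytest.mark.parametrize("backend", ["mlp", "rf", "svr", "likelihood"])
def test_serialise_reload_repredict_bitwise(backend, toy, tmp_path):
    x, y = toy
    params = {"mlp": dict(hidden_sizes=(16,), max_epochs=10, random_state=3)}.get(backend, {})
    model = make_backend(backend, breeds=("A", "B"), **params).fit(x, y)
    before = model.predict(x)
    save_model(model, tmp_path / backend)
    reloaded = load_model(tmp_path / backend)
    assert reloaded.breeds_ == ("A", "B")
    assert np.array_equal(reloaded.predict(x), before)


def test_mlp_training_is_seed_deterministic(toy):
    x, y = toy
    runs = [
        MLPGBCRegressor(hidden_sizes=(16,), max_epochs=15, random_state=7).fit(x, y)
        for _ in range(2)
    ]
    assert runs[0].n_epochs_ == runs[1].n_epochs_
    assert runs[0].loss_curve_ == runs[1].loss_curve_
    assert np.array_equal(runs[0].predict(x), runs[1].predict(x))


def test_mlp_permutation_equivariance(toy):
    x, y = toy
    m = MLPGBCRegressor(hidden_sizes=(16,), max_epochs=10, random_state=0).fit(x, y)
    perm = np.random.default_rng(0).permutation(len(x))
    assert np.array_equal(m.predict(x[perm]), m.predict(x)[perm])


def test_mlp_rejects_single_class_targets(toy):
    x, _ = toy
    y = np.zeros((len(x), 2))
    y[:, 0] = 1.0
    with pytest.raises(ValueError, match="degenerate"):
        MLPGBCRegressor(hidden_sizes=(8,), max_epochs=5).fit(x, y)


def test_mlp_feature_width_mismatch_names_expected(toy):
    x, y = toy
    m = MLPGBCRegressor(hidden_sizes=(8,), max_epochs=5, random_state=0).fit(x, y)
    with pytest.raises(ValueError, match=str(x.shape[1])):
        m.predict(x[:, :-3])


def test_rf_single_stump_fits_separable_toy():
    """One depth-1 tree on a single diagnostic SNP reproduces the targets."""
    d = np.array([0] * 20 + [2] * 20)
    x = np.zeros((40, 3))
    x[np.arange(40), d] = 1
    y = np.zeros((40, 2))
    y[:20, 0] = 1
    y[20:, 1] = 1
    m = RandomForestGBC(n_estimators=1, max_depth=1, max_features=1.0, random_state=0).fit(x, y)
    assert np.abs(m.predict(x) - y).max() < 0.01


def test_svr_raw_outputs_leave_unit_interval_but_projection_never_does(toy):
    x, y = toy
    m = SVRGBC(C=100.0, epsilon=0.001).fit(x, y)
    raw = np.column_stack([est.predict(x) for est in m.models_])
    assert (raw < 0).any() or (raw > 1).any()  # kernel regression overshoots
    q = m.predict(x)
    assert (q >= 0).all() and (q <= 1).all()


def test_classification_framework_returns_class_probabilities(toy):
    x, y = toy
    for backend in ("rf", "svr", "mlp"):
        params = {
            "mlp": dict(hidden_sizes=(16,), max_epochs=80, batch_size=16, random_state=0)
        }.get(backend, {})
        m = make_backend(backend, framework="classification", **params).fit(x, y)
        assert m.framework == "classification"
        probs = m.predict(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs.argmax(axis=1) == y.argmax(axis=1)).mean() > 0.95


def test_likelihood_backend_rejects_classification_framework():
    with pytest.raises(ValueError, match="regression"):
        make_backend("likelihood", framework="classification")


def test_unknown_backend_name():
    with pytest.raises(ValueError, match="unknown backend"):
        make_backend("transformer")
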