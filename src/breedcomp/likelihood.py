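"""Supervised maximum-likelihood ancestry estimation.

A supervised analogue of model-based ancestry clustering: breed allele
frequencies are estimated directly from labelled training purebreds, then
each sample's ancestry vector ``q`` maximises the binomial admixture
log-likelihood

    L(q) = sum_j [ g_j log(sum_k q_k p_kj) + (2 - g_j) log(sum_k q_k (1 - p_kj)) ]

over the probability simplex via expectation–maximisation. The EM update is
the classic allele-origin responsibility step, so the log-likelihood is
non-decreasing at every iteration (asserted at run time).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .encoding import one_hot_decode
from .containers import FeatureMatrix


class EMMonotonicityError(RuntimeError):
    """The EM log-likelihood decreased — internal error."""


def admixture_loglik(g: np.ndarray, freqs: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Binomial admixture log-likelihood per sample.

    ``g``: (n, M) dosages; ``freqs``: (K, M) breed frequencies; ``q``: (n, K).
    """
    a = q @ freqs
    b = q @ (1.0 - freqs)
    return (g * np.log(a) + (2.0 - g) * np.log(b)).sum(axis=1)


def estimate_q_em(
    g: np.ndarray,
    freqs: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """EM ancestry estimates for a batch of samples.

    Returns ``(q, loglik)`` with ``q`` of shape (n, K) on the simplex.
    Converged when every sample's log-likelihood gain drops below ``tol``
    or after ``max_iter`` iterations.
    """
    g = np.atleast_2d(np.asarray(g, dtype=np.float64))
    k, m = freqs.shape
    n = g.shape[0]
    if g.shape[1] != m:
        raise ValueError("dosage width does not match frequency table")
    if np.isnan(g).any():
        raise ValueError("dosages contain missing values; impute first")
    if k == 1:
        q = np.ones((n, 1))
        return q, admixture_loglik(g, freqs, q)

    q = np.full((n, k), 1.0 / k)
    ll = admixture_loglik(g, freqs, q)
    two_m = 2.0 * m
    active = np.arange(n)  # samples whose likelihood is still improving
    for _ in range(max_iter):
        ga, qa = g[active], q[active]
        a = qa @ freqs          # P(alt allele) per active sample x SNP
        b = qa @ (1.0 - freqs)  # P(ref allele)
        q_new = qa * ((ga / a) @ freqs.T + ((2.0 - ga) / b) @ (1.0 - freqs).T) / two_m
        q_new /= q_new.sum(axis=1, keepdims=True)
        ll_new = admixture_loglik(ga, freqs, q_new)
        gain = ll_new - ll[active]
        if (gain < -1e-9 * np.maximum(1.0, np.abs(ll[active]))).any():
            worst = active[int(np.argmin(gain))]
            raise EMMonotonicityError(
                f"log-likelihood decreased for sample {worst}: "
                f"{ll[worst]:.10g} -> {ll_new[int(np.argmin(gain))]:.10g}"
            )
        q[active], ll[active] = q_new, ll_new
        active = active[gain >= tol]
        if active.size == 0:
            break
    return q, ll


def estimate_q_mle(g_i: np.ndarray, freqs: np.ndarray, **kwargs) -> np.ndarray:
    """Maximum-likelihood ancestry vector for a single dosage vector."""
    q, _ = estimate_q_em(np.atleast_2d(g_i), freqs, **kwargs)
    return q[0]


class SupervisedAdmixture(BaseEstimator):
    """Ancestry estimator with breed frequencies learnt from labelled purebreds.

    ``fit`` expects the same inputs as the other backends: one-hot genotype
    features (decoded back to dosages internally; set ``features="dosage"``
    to pass raw dosage matrices) and GBC target vectors, of which only the
    purebred rows (a single component equal to 1) inform the frequency
    table. ``predict`` runs per-sample EM and returns simplex-valid
    ancestry vectors.
    """

    framework = "regression"

    def __init__(
        self,
        eps: float = 1e-4,
        tol: float = 1e-8,
        max_iter: int = 2000,
        features: str = "onehot",
        breeds: tuple[str, ...] | None = None,
    ):
        self.eps = eps
        self.tol = tol
        self.max_iter = max_iter
        self.features = features
        self.breeds = breeds

    def _dosages(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        X = np.asarray(X)
        if self.features == "onehot":
            return one_hot_decode(X)
        if self.features == "dosage":
            return X.astype(np.float64)
        raise ValueError(f"unknown feature mode {self.features!r}")

    def fit(self, X, y):
        g = self._dosages(X)
        y = np.asarray(y, dtype=np.float64)
        if g.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        k = y.shape[1]
        freqs = np.empty((k, g.shape[1]))
        for b in range(k):
            pure = np.isclose(y[:, b], 1.0)
            if not pure.any():
                name = self.breeds[b] if self.breeds else f"breed {b}"
                raise ValueError(f"no training purebreds for {name}")
            freqs[b] = g[pure].mean(axis=0) / 2.0
        self.freqs_ = np.clip(freqs, self.eps, 1.0 - self.eps)
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else np.asarray(X).shape[1]
        self.n_outputs_ = k
        self.breeds_ = tuple(self.breeds) if self.breeds is not None else tuple(
            f"class{i}" for i in range(k)
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "freqs_"):
            raise RuntimeError("model is not fitted")
        g = self._dosages(X)
        if g.shape[1] != self.freqs_.shape[1]:
            raise ValueError(
                f"expected {self.freqs_.shape[1]} SNPs, got {g.shape[1]}"
            )
        q, _ = estimate_q_em(g, self.freqs_, tol=self.tol, max_iter=self.max_iter)
        return q

    predict_gbc = predict
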