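"""Breed calling from ancestry vectors and threshold evaluation.

An individual whose largest GBC component strictly exceeds the
determination threshold θ is called purebred of that breed; otherwise it is
called hybrid (with the top-two breed pair reported for information).
Equality at the boundary therefore yields a hybrid call. Raising θ can only
move calls from purebred to hybrid, so on fixed predictions purebred
accuracy is non-increasing and hybrid accuracy non-decreasing in θ — the
threshold scan exploits this to pick the best operating point over the
standard grid 0.60–0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HYBRID

DEFAULT_GRID = (0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90)


@dataclass(frozen=True)
class DecisionConfig:
    """Determination threshold (default 0.75) and scan grid."""

    threshold: float = 0.75
    grid: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0.5, 1)")
        if len(self.grid) == 0:
            raise ValueError("threshold grid is empty")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("threshold grid must be strictly increasing")


@dataclass(frozen=True)
class BreedCall:
    sample_id: str
    call: str  # breed name, or "hybrid"
    max_component: float
    argmax_breed: str
    top2_pair: tuple[str, str]


@dataclass
class EvalResult:
    threshold: float
    accuracy: dict[str, float]  # per true category, 4 decimals
    n: dict[str, int]
    confusion: pd.DataFrame = field(repr=False)  # rows: true category, cols: call

    def overall(self, weighted: bool = False) -> float:
        cats = sorted(self.accuracy)
        if weighted:
            total = sum(self.n[c] for c in cats)
            return sum(self.accuracy[c] * self.n[c] for c in cats) / total
        return float(np.mean([self.accuracy[c] for c in cats]))


def _validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if (q < -1e-6).any() or (q > 1 + 1e-6).any() or not np.allclose(
        q.sum(axis=-1), 1.0, atol=1e-6
    ):
        raise ValueError("ancestry vector is not on the probability simplex")
    return q


def call_breed(
    q: np.ndarray,
    breeds: list[str],
    cfg: DecisionConfig | None = None,
    sample_id: str = "",
) -> BreedCall:
    """Call one sample from its ancestry vector (strict > at the threshold)."""
    cfg = cfg or DecisionConfig()
    q = _validate_q(np.asarray(q).ravel())
    if len(q) != len(breeds):
        raise ValueError("ancestry vector width does not match breed panel")
    order = np.argsort(q)[::-1]
    top = int(order[0])
    second = int(order[1]) if len(q) > 1 else top
    is_pure = q[top] > cfg.threshold
    return BreedCall(
        sample_id=sample_id,
        call=breeds[top] if is_pure else HYBRID,
        max_component=float(q[top]),
        argmax_breed=breeds[top],
        top2_pair=(breeds[top], breeds[second]),
    )


def call_breeds(
    q_matrix: np.ndarray,
    breeds: list[str],
    sample_ids: list[str] | None = None,
    cfg: DecisionConfig | None = None,
) -> pd.DataFrame:
    """Vectorised calling; returns a calls table."""
    cfg = cfg or DecisionConfig()
    q = _validate_q(np.atleast_2d(q_matrix))
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(q.shape[0])]
    order = np.argsort(q, axis=1)[:, ::-1]
    top = order[:, 0]
    second = order[:, 1] if q.shape[1] > 1 else top
    maxc = q[np.arange(len(q)), top]
    names = np.asarray(breeds, dtype=object)
    calls = np.where(maxc > cfg.threshold, names[top], HYBRID)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "call": calls,
            "max_component": maxc,
            "argmax_breed": names[top],
            "second_breed": names[second],
        }
    )


def evaluate(calls: pd.DataFrame, truth: pd.DataFrame, threshold: float | None = None) -> EvalResult:
    """Per-category accuracy and confusion table.

    A purebred is correct iff called as its own breed; a hybrid is correct
    iff called hybrid (a hybrid called purebred is one error — no partial
    credit). Accuracies are rounded to 4 decimals.
    """
    merged = calls.merge(truth[["sample_id", "category"]], on="sample_id", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", "sample_id"].tolist()[:5]
        raise ValueError(f"calls and truth sample sets differ (e.g. {missing})")
    correct = merged["call"] == merged["category"]
    acc = {}
    n = {}
    for cat, grp in merged.groupby("category"):
        n[cat] = len(grp)
        acc[cat] = round(float(correct[grp.index].mean()), 4)
    confusion = pd.crosstab(merged["category"], merged["call"])
    thr = threshold if threshold is not None else float("nan")
    return EvalResult(threshold=thr, accuracy=acc, n=n, confusion=confusion)


def threshold_scan(
    q_matrix: np.ndarray,
    truth: pd.DataFrame,
    breeds: list[str],
    cfg: DecisionConfig | None = None,
    weighted: bool = False,
) -> tuple[pd.DataFrame, float, list[EvalResult]]:
    """Evaluate every grid threshold on fixed predictions.

    Returns (tidy table, optimal threshold, per-threshold EvalResults); the
    optimum maximises overall accuracy (unweighted mean over categories by
    default), ties broken toward the larger threshold.
    """
    cfg = cfg or DecisionConfig()
    sample_ids = truth["sample_id"].tolist()
    results = []
    rows = []
    for theta in cfg.grid:
        calls = call_breeds(q_matrix, breeds, sample_ids, DecisionConfig(threshold=theta, grid=cfg.grid))
        res = evaluate(calls, truth, threshold=theta)
        results.append(res)
        for cat in sorted(res.accuracy):
            rows.append(
                {
                    "threshold": theta,
                    "category": cat,
                    "n": res.n[cat],
                    "accuracy": res.accuracy[cat],
                }
            )
        rows.append(
            {
                "threshold": theta,
                "category": "overall",
                "n": sum(res.n.values()),
                "accuracy": round(res.overall(weighted=weighted), 4),
            }
        )
    overall = np.array([r.overall(weighted=weighted) for r in results])
    # argmax with ties toward the larger threshold
    best = len(overall) - 1 - int(np.argmax(overall[::-1]))
    return pd.DataFrame(rows), float(cfg.grid[best]), results
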