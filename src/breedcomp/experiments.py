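"""Desk-scale evaluation designs: grid search, replicated cross-validation,
independent-population testing and training-set titration.

Every design takes a prepared :class:`Dataset` (QC'd, imputed, one-hot
encoded genotypes plus the truth table) and a dictionary of model builders,
and serves *byte-identical* train/test matrices to every method — fold
membership depends only on the plan seed, never on the backend — so method
comparisons are fair by construction. Results come back as tidy tables
(method, framework, replicate, fold, category, n, accuracy).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import GenotypeMatrix
from .decision import DecisionConfig, EvalResult, call_breeds, evaluate
from .encoding import classification_classes, encode_targets, one_hot_encode
from .qc import QCThresholds, apply_qc, impute_missing


@dataclass
class Dataset:
    """Model-ready features + truth for one population."""

    X: np.ndarray = field(repr=False)  # n x 3M one-hot features
    truth: pd.DataFrame = field(repr=False)
    breeds: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            X=self.X[idx],
            truth=self.truth.iloc[idx].reset_index(drop=True),
            breeds=self.breeds,
        )

    def targets(self, framework: str = "regression") -> np.ndarray:
        return encode_targets(self.truth, list(self.breeds), framework)


def prepare_dataset(
    g: GenotypeMatrix,
    truth: pd.DataFrame,
    breeds: tuple[str, ...],
    qc: QCThresholds | None = None,
    impute: str = "mode",
) -> Dataset:
    """QC -> impute -> one-hot encode -> align truth rows to sample order."""
    g_qc, _ = apply_qc(g, qc or QCThresholds())
    g_imp = impute_missing(g_qc, strategy=impute)
    x = one_hot_encode(g_imp)
    truth = truth.set_index("sample_id").loc[g.samples].reset_index()
    return Dataset(X=x.values.astype(np.float64), truth=truth, breeds=tuple(breeds))


def intersect_panels(
    g1: GenotypeMatrix, g2: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both matrices to their common SNPs, in g1's order.

    Mirrors building a common panel from the intersection of several chips;
    alleles must agree on the shared SNPs.
    """
    common = pd.Index(g1.panel["snp_id"]).intersection(g2.panel["snp_id"])
    if len(common) == 0:
        raise ValueError("SNP panels are disjoint; no common markers to align")
    idx1 = np.flatnonzero(g1.panel["snp_id"].isin(common))
    pos2 = {s: i for i, s in enumerate(g2.panel["snp_id"])}
    idx2 = np.array([pos2[s] for s in g1.panel["snp_id"].iloc[idx1]])
    out1, out2 = g1.select_snps(idx1), g2.select_snps(idx2)
    for col in ("a1", "a2"):
        if not (out1.panel[col].to_numpy() == out2.panel[col].to_numpy()).all():
            raise ValueError("allele columns disagree on shared SNPs")
    return out1, out2


@dataclass(frozen=True)
class CVPlan:
    """Five replicates of (stratified) fivefold CV; replicate r splits with
    seed ``seed + r`` and the splits are shared across all methods."""

    n_folds: int = 5
    n_replicates: int = 5
    stratify_by: str = "category"
    seed: int = 0


@dataclass(frozen=True)
class TitrationPlan:
    """Vary the training count of one category over a ladder, keeping the
    other categories fixed and the test set constant across rows."""

    varied_category: str
    ladder: tuple[int, ...] = (0, 50, 100, 150, 200, 250, 300)
    seed: int = 0


def mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def grid_search(
    make_model,
    grid: list[dict],
    data: Dataset,
    framework: str = "regression",
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Pick the config with minimal mean validation MSE over shared folds.

    ``make_model(**config)`` must return an unfitted backend. Failed fits
    are recorded with status ``failed`` and excluded from the argmin; ties
    go to the first config in grid order.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = data.targets(framework)
    splits = list(
        KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(data.X)
    )
    rows = []
    means = []
    for i, params in enumerate(grid):
        fold_mse = []
        status = "ok"
        try:
            for tr, va in splits:
                model = make_model(**params)
                model.fit(data.X[tr], y[tr])
                fold_mse.append(mse(model.predict(data.X[va]), y[va]))
        except Exception as exc:  # recorded, excluded from argmin
            status = "failed"
            fold_mse = [np.nan]
            rows_err = str(exc)
        mean = float(np.mean(fold_mse))
        means.append(np.inf if status == "failed" else mean)
        rows.append(
            {
                "config_index": i,
                "params": repr(params),
                "mean_mse": mean,
                "status": status,
                **({"error": rows_err} if status == "failed" else {}),
            }
        )
    table = pd.DataFrame(rows)
    if not np.isfinite(means).any():
        raise RuntimeError("every hyperparameter config failed to train")
    best = int(np.argmin(means))  # first minimum wins ties
    return grid[best], table


def cv_splits(plan: CVPlan, truth: pd.DataFrame) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Fold memberships per replicate, depending only on the plan and labels."""
    labels = truth[plan.stratify_by].to_numpy()
    out = []
    for r in range(plan.n_replicates):
        kf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed + r)
        out.append([(tr, te) for tr, te in kf.split(np.zeros(len(labels)), labels)])
    return out


def splits_digest(plan: CVPlan, truth: pd.DataFrame) -> str:
    """Hash of all fold memberships — for split-reproducibility checks."""
    h = hashlib.sha256()
    for replicate in cv_splits(plan, truth):
        for tr, te in replicate:
            h.update(tr.tobytes())
            h.update(te.tobytes())
    return h.hexdigest()


def _evaluate_method(model, framework, train: Dataset, test: Dataset, cfg: DecisionConfig) -> EvalResult:
    """Fit on train, call breeds on test, evaluate against the truth."""
    model.fit(train.X, train.targets(framework))
    pred = model.predict(test.X)
    if framework == "classification":
        # -CLA models emit class probabilities; the call is the argmax class
        classes = classification_classes(train.truth, list(train.breeds))
        calls = pd.DataFrame(
            {
                "sample_id": test.truth["sample_id"],
                "call": [classes[i] for i in pred.argmax(axis=1)],
                "max_component": pred.max(axis=1),
            }
        )
    else:
        calls = call_breeds(pred, list(train.breeds), test.truth["sample_id"].tolist(), cfg)
    return evaluate(calls, test.truth, threshold=cfg.threshold)


def _tidy(res: EvalResult, **keys) -> list[dict]:
    return [
        {**keys, "category": cat, "n": res.n[cat], "accuracy": res.accuracy[cat]}
        for cat in sorted(res.accuracy)
    ]


def run_cv(
    plan: CVPlan,
    data: Dataset,
    methods: dict,
    decision: DecisionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated stratified CV with splits shared across methods.

    ``methods`` maps a display name to a zero-argument builder returning an
    unfitted backend (its ``framework`` attribute decides target encoding).
    Returns (tidy per-fold table, per-method mean-accuracy summary over the
    ``n_replicates * n_folds`` runs, unweighted).
    """
    decision = decision or DecisionConfig()
    rows = []
    for r, folds in enumerate(cv_splits(plan, data.truth)):
        for f, (tr, te) in enumerate(folds):
            train, test = data.subset(tr), data.subset(te)
            for name, build in methods.items():
                model = build()
                framework = getattr(model, "framework", "regression")
                res = _evaluate_method(model, framework, train, test, decision)
                rows.extend(
                    _tidy(res, method=name, framework=framework, replicate=r, fold=f)
                )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["method", "framework", "category"])["accuracy"]
        .mean()
        .round(4)
        .reset_index()
    )
    return table, summary


def run_independent_test(
    train: Dataset,
    test: Dataset,
    methods: dict,
    decision: DecisionConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, EvalResult]]:
    """Fit once on the training population, evaluate on the independent one."""
    decision = decision or DecisionConfig()
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError(
            "train/test feature widths differ; intersect panels before encoding"
        )
    rows = []
    results = {}
    for name, build in methods.items():
        model = build()
        framework = getattr(model, "framework", "regression")
        res = _evaluate_method(model, framework, train, test, decision)
        results[name] = res
        rows.extend(_tidy(res, method=name, framework=framework))
    return pd.DataFrame(rows), results


def run_titration(
    plan: TitrationPlan,
    train: Dataset,
    test: Dataset,
    make_model,
    decision: DecisionConfig | None = None,
) -> pd.DataFrame:
    """Accuracy versus training count of one category.

    Each ladder row subsamples the varied category (seeded, nested so larger
    counts contain smaller ones), keeps every other category complete, fits
    a fresh model and evaluates on the fixed test set.
    """
    decision = decision or DecisionConfig()
    cats = train.truth["category"].to_numpy()
    varied_idx = np.flatnonzero(cats == plan.varied_category)
    other_idx = np.flatnonzero(cats != plan.varied_category)
    if max(plan.ladder) > len(varied_idx):
        raise ValueError(
            f"ladder count {max(plan.ladder)} exceeds the {len(varied_idx)} "
            f"available {plan.varied_category!r} training individuals"
        )
    order = np.random.default_rng(plan.seed).permutation(varied_idx)
    rows = []
    for count in plan.ladder:
        idx = np.sort(np.concatenate([other_idx, order[:count]]))
        model = make_model()
        framework = getattr(model, "framework", "regression")
        res = _evaluate_method(model, framework, train.subset(idx), test, decision)
        for cat in sorted(res.accuracy):
            rows.append(
                {
                    "n_varied": count,
                    "category": cat,
                    "n": res.n[cat],
                    "accuracy": res.accuracy[cat],
                }
            )
    return pd.DataFrame(rows)
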