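"""Genotype one-hot feature encoding and ancestry-target encoding.

Each SNP dosage in {0, 1, 2} becomes a 3-column indicator block, so a panel
of M SNPs yields a ``3M``-column binary feature matrix — the input shared by
every model backend. Training targets are encoded either as genomic breed
composition (GBC) vectors on the probability simplex (multi-output
regression framework) or as one-hot class labels over the purebred names
plus any hybrid classes present (classification framework).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import HYBRID, FeatureMatrix, GenotypeMatrix


class MissingGenotypesError(ValueError):
    """One-hot encoding requires a fully imputed matrix."""


def one_hot_encode(g: GenotypeMatrix) -> FeatureMatrix:
    """Expand dosages into per-SNP 3-class indicator blocks."""
    if g.has_missing():
        raise MissingGenotypesError(
            "genotype matrix contains missing calls; run impute_missing first"
        )
    d = g.dosage.astype(np.int64)
    n, m = d.shape
    values = np.zeros((n, 3 * m), dtype=np.uint8)
    cols = 3 * np.arange(m)[None, :] + d
    values[np.arange(n)[:, None], cols] = 1
    columns = [(sid, c) for sid in g.snp_ids for c in (0, 1, 2)]
    return FeatureMatrix(values=values, columns=columns, samples=list(g.samples))


def one_hot_decode(x: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Invert :func:`one_hot_encode`, returning the dosage matrix."""
    v = np.asarray(x.values if isinstance(x, FeatureMatrix) else x)
    n, p = v.shape
    if p % 3:
        raise ValueError("feature width is not a multiple of 3")
    blocks = v.reshape(n, p // 3, 3)
    if not (blocks.sum(axis=2) == 1).all():
        raise ValueError("some SNP block does not have exactly one active class")
    return blocks.argmax(axis=2).astype(np.float64)


def save_features(x: FeatureMatrix, prefix) -> None:
    """Cache a feature matrix as ``<prefix>.npz`` plus a JSON column-map sidecar."""
    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), values=x.values)
    sidecar = {
        "samples": x.samples,
        "columns": [[sid, int(c)] for sid, c in x.columns],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_features(prefix) -> FeatureMatrix:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npz"))["values"]
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return FeatureMatrix(
        values=values,
        columns=[(sid, int(c)) for sid, c in sidecar["columns"]],
        samples=sidecar["samples"],
    )


def encode_targets(
    truth: pd.DataFrame,
    breeds: list[str],
    framework: str = "regression",
) -> np.ndarray:
    """Encode truth-table rows as model training targets.

    Regression framework: each row is the GBC ancestry vector over ``breeds``
    (an F1 of breeds 1 and 2 under a 3-breed panel encodes to
    ``[0.50, 0.50, 0.0]``); rows sum to 1.

    Classification framework: one-hot over ``breeds`` plus a trailing
    ``hybrid`` class if any hybrids are present.
    """
    if len(set(breeds)) != len(breeds):
        raise ValueError("breed names must be unique")
    qcols = [f"q_{k + 1}" for k in range(len(breeds))]
    for col in qcols:
        if col not in truth.columns:
            raise ValueError(f"truth table lacks ancestry column {col!r}")

    if framework == "regression":
        y = truth[qcols].to_numpy(dtype=np.float64)
        if not np.allclose(y.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("ancestry targets must sum to 1")
        return y
    if framework == "classification":
        classes = classification_classes(truth, breeds)
        idx = {c: i for i, c in enumerate(classes)}
        y = np.zeros((len(truth), len(classes)), dtype=np.float64)
        for i, cat in enumerate(truth["category"]):
            if cat not in idx:
                raise ValueError(f"category {cat!r} not resolvable against panel {breeds}")
            y[i, idx[cat]] = 1.0
        return y
    raise ValueError(f"unknown framework {framework!r}")


def classification_classes(truth: pd.DataFrame, breeds: list[str]) -> list[str]:
    """Class list for the classification framework: purebreds then hybrid (if present)."""
    classes = list(breeds)
    if (truth["category"] == HYBRID).any():
        classes.append(HYBRID)
    unknown = set(truth["category"]) - set(classes)
    if unknown:
        raise ValueError(f"categories {sorted(unknown)} not resolvable against panel {breeds}")
    return classes
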