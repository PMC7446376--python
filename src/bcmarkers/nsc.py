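"""Nearest shrunken centroid (NSC) multigene classifiers, from scratch.

The multigene classifier (MGC) for each biomarker is an NSC model fit on
the top-varying gene space.  Per gene i and class k:

    d_ik  = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)
    d'_ik = sign(d_ik) (|d_ik| − Δ)₊                       (soft threshold)
    x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik                    (shrunken centroid)

with s_i the pooled within-class SD, s0 the median of the s_i (fudge
factor guarding against near-zero variances).  A test sample x is
assigned argmin_k of the discriminant

    δ_k(x) = Σ_i (x_i − x̄'_ik)² / (s_i + s0)² − 2 log π_k .

Genes whose d'_ik vanish for every class drop out of the rule entirely —
the sparsity that makes the per-biomarker gene signatures reportable.
The shrinkage Δ is chosen by repeated stratified cross-validation on
balanced accuracy (ties prefer the sparser, larger-Δ model).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "NSCModel",
    "CVResult",
    "select_top_varying",
    "fit_nsc",
    "predict_nsc",
    "cv_select_delta",
    "nonzero_union",
]


def select_top_varying(expr: pd.DataFrame, k: int) -> list[str]:
    """The k genes with the largest sample variance across samples.

    Returned in decreasing-variance order; exact variance ties are
    broken by gene id (lexicographic), making the selection
    deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > expr.shape[0]:
        raise ValueError(f"k={k} exceeds the {expr.shape[0]} available genes")
    var = expr.var(axis=1, ddof=1)
    order = (
        pd.DataFrame({"__var__": var.to_numpy(), "__gene__": var.index.to_numpy()})
        .sort_values(["__var__", "__gene__"], ascending=[False, True], kind="mergesort")["__gene__"]
        .to_numpy()
    )
    return list(order[:k])


@dataclass
class NSCModel:
    """A fitted nearest-shrunken-centroid model (all arrays genes-major)."""

    gene_ids: list[str]
    classes: list
    priors: np.ndarray
    delta: float
    overall_centroid: np.ndarray  # (g,)
    class_centroids: np.ndarray  # (g, K) raw
    shrunken_centroids: np.ndarray  # (g, K)
    s: np.ndarray  # (g,) pooled within-class SD
    s0: float
    m: np.ndarray  # (K,) standardizers
    d: np.ndarray  # (g, K) t-like scores
    d_shrunk: np.ndarray  # (g, K)
    name: str | None = None

    @property
    def nonzero_mask(self) -> np.ndarray:
        return np.any(self.d_shrunk != 0.0, axis=1)

    @property
    def nonzero_genes(self) -> list[str]:
        """Genes with nonzero weight in the classification rule."""
        return [g for g, nz in zip(self.gene_ids, self.nonzero_mask) if nz]

    def to_json(self, path: str | None = None) -> str:
        d = {
            "name": self.name,
            "gene_ids": list(self.gene_ids),
            "classes": [str(c) for c in self.classes],
            "priors": self.priors.tolist(),
            "delta": self.delta,
            "s0": self.s0,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "s": self.s.tolist(),
            "m": self.m.tolist(),
            "d": self.d.tolist(),
            "d_shrunk": self.d_shrunk.tolist(),
        }
        s = json.dumps(d)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path: str) -> "NSCModel":
        with open(path) as fh:
            d = json.load(fh)
        arrays = {
            k: np.asarray(d[k])
            for k in (
                "priors",
                "overall_centroid",
                "class_centroids",
                "shrunken_centroids",
                "s",
                "m",
                "d",
                "d_shrunk",
            )
        }
        return cls(
            gene_ids=d["gene_ids"],
            classes=d["classes"],
            delta=d["delta"],
            s0=d["s0"],
            name=d.get("name"),
            **arrays,
        )


def _sufficient_stats(x: np.ndarray, y: np.ndarray, classes: list):
    """Centroids, pooled SD, fudge and standardizers for an NSC fit."""
    n = x.shape[1]
    K = len(classes)
    xbar = x.mean(axis=1)
    cent = np.empty((x.shape[0], K))
    nk = np.empty(K)
    ss = np.zeros(x.shape[0])
    for j, c in enumerate(classes):
        cols = y == c
        nk[j] = cols.sum()
        cent[:, j] = x[:, cols].mean(axis=1)
        ss += ((x[:, cols] - cent[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    m = np.sqrt(1.0 / nk - 1.0 / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (cent - xbar[:, None]) / (m[None, :] * (s + s0)[:, None])
    d = np.nan_to_num(d, nan=0.0, posinf=0.0, neginf=0.0)
    return xbar, cent, nk, s, s0, m, d


def _shrink(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def fit_nsc(
    expr: pd.DataFrame,
    labels: pd.Series,
    delta: float,
    priors: np.ndarray | dict | None = None,
    name: str | None = None,
) -> NSCModel:
    """Fit an NSC model at shrinkage ``delta``.

    ``expr`` is genes × samples; ``labels`` is aligned to the columns
    (samples with missing labels are dropped).  Priors default to the
    empirical class frequencies; pass a mapping or array (in sorted
    class order) to override — e.g. population frequencies when the
    training set is enriched.
    """
    if delta < 0:
        raise ValueError("delta must be ≥ 0")
    labels = labels.reindex(expr.columns).dropna()
    x = expr[labels.index].to_numpy(dtype=float)
    y = labels.to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")

    xbar, cent, nk, s, s0, m, d = _sufficient_stats(x, y, classes)
    d_shr = _shrink(d, delta)
    shrunk = xbar[:, None] + m[None, :] * (s + s0)[:, None] * d_shr

    if priors is None:
        pri = nk / nk.sum()
    elif isinstance(priors, dict):
        pri = np.array([priors[c] for c in classes], dtype=float)
    else:
        pri = np.asarray(priors, dtype=float)
    if len(pri) != len(classes) or abs(pri.sum() - 1.0) > 1e-8 or np.any(pri <= 0):
        raise ValueError("priors must be positive and sum to 1 over the classes")

    return NSCModel(
        gene_ids=list(expr.index),
        classes=classes,
        priors=pri,
        delta=float(delta),
        overall_centroid=xbar,
        class_centroids=cent,
        shrunken_centroids=shrunk,
        s=s,
        s0=s0,
        m=m,
        d=d,
        d_shrunk=d_shr,
        name=name,
    )


def _discriminants(
    x: np.ndarray, shrunk: np.ndarray, s: np.ndarray, s0: float, priors: np.ndarray
) -> np.ndarray:
    """δ_k for samples (columns of x); returns samples × classes."""
    w = 1.0 / (s + s0) ** 2
    # Σ_i w_i (x_i − c_ik)² expanded for vectorization
    xw = (x**2 * w[:, None]).sum(axis=0)  # (n,)
    cross = (x * w[:, None]).T @ shrunk  # (n, K)
    cw = (shrunk**2 * w[:, None]).sum(axis=0)  # (K,)
    return xw[:, None] - 2 * cross + cw[None, :] - 2 * np.log(priors)[None, :]


def predict_nsc(
    model: NSCModel, expr: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Classify samples; returns (labels, per-class discriminant scores).

    Lower discriminant wins; exact ties go to the first class in sorted
    label order.  Up to 10% of the model's genes may be missing from the
    input (they are dropped from the sum with a warning); more is an
    error.
    """
    present = [g for g in model.gene_ids if g in expr.index]
    n_missing = len(model.gene_ids) - len(present)
    if n_missing > 0.1 * len(model.gene_ids):
        raise ValueError(
            f"{n_missing}/{len(model.gene_ids)} model genes missing from input"
        )
    keep = np.array([g in expr.index for g in model.gene_ids])
    if n_missing:
        warnings.warn(
            f"dropping {n_missing} model genes absent from the input", stacklevel=2
        )
    x = expr.loc[present].to_numpy(dtype=float)
    scores = _discriminants(
        x, model.shrunken_centroids[keep], model.s[keep], model.s0, model.priors
    )
    idx = np.argmin(scores, axis=1)  # first minimum = first sorted class
    labels = pd.Series(
        [model.classes[i] for i in idx], index=expr.columns, name=model.name
    )
    return labels, pd.DataFrame(scores, index=expr.columns, columns=model.classes)


def _balanced_accuracy(pred: np.ndarray, truth: np.ndarray, classes) -> float:
    recalls = []
    for c in classes:
        m = truth == c
        if m.any():
            recalls.append(float((pred[m] == c).mean()))
    return float(np.mean(recalls))


@dataclass
class CVResult:
    """Cross-validation profile over the shrinkage grid."""

    delta_grid: np.ndarray
    mean_balanced_accuracy: np.ndarray
    sd_balanced_accuracy: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    nonzero_counts: np.ndarray  # full-data fit, per Δ
    chosen_delta: float
    n_folds: int
    n_repeats: int
    seed: int
    fold_assignments: list = field(repr=False, default_factory=list)
    model: NSCModel | None = field(repr=False, default=None)


def cv_select_delta(
    expr: pd.DataFrame,
    labels: pd.Series,
    delta_grid: np.ndarray | None = None,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    priors: np.ndarray | dict | None = None,
    grid_size: int = 30,
    name: str | None = None,
) -> CVResult:
    """Choose Δ by repeated stratified CV on balanced accuracy.

    The default grid is ``grid_size`` evenly spaced values from 0 to
    max|d_ik| of the full-data fit (the smallest Δ that zeroes every
    gene).  Ties on mean balanced accuracy go to the larger (sparser)
    Δ.  The returned result carries the final model refit on all
    samples at the chosen Δ.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be ≥ 2")
    labels = labels.reindex(expr.columns).dropna()
    x_df = expr[labels.index]
    y = labels.to_numpy()
    classes = sorted(pd.unique(y))
    counts = pd.Series(y).value_counts()
    min_class = int(counts.min())
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds "
            f"from {n_folds} to {max(2, min_class)}",
            stacklevel=2,
        )
        n_folds = max(2, min_class)

    full = fit_nsc(x_df, labels, 0.0, priors=priors, name=name)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.abs(full.d).max()), grid_size)
    delta_grid = np.asarray(delta_grid, dtype=float)

    x = x_df.to_numpy(dtype=float)
    cv = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    ba = np.zeros((n_folds * n_repeats, len(delta_grid)))
    acc = np.zeros_like(ba)
    assignments = []
    for f, (tr, te) in enumerate(cv.split(x.T, y)):
        assignments.append((tr.copy(), te.copy()))
        xbar, cent, nk, s, s0, m, d = _sufficient_stats(x[:, tr], y[tr], classes)
        if priors is None:
            pri = nk / nk.sum()
        elif isinstance(priors, dict):
            pri = np.array([priors[c] for c in classes], dtype=float)
        else:
            pri = np.asarray(priors, dtype=float)
        for j, delta in enumerate(delta_grid):
            shrunk = xbar[:, None] + m[None, :] * (s + s0)[:, None] * _shrink(d, delta)
            scores = _discriminants(x[:, te], shrunk, s, s0, pri)
            pred = np.array([classes[i] for i in np.argmin(scores, axis=1)])
            ba[f, j] = _balanced_accuracy(pred, y[te], classes)
            acc[f, j] = float((pred == y[te]).mean())

    mean_ba = ba.mean(axis=0)
    # ties → larger Δ: scan from the sparse end
    best = len(delta_grid) - 1 - int(np.argmax(mean_ba[::-1]))
    chosen = float(delta_grid[best])

    nonzero = np.array(
        [int(np.any(_shrink(full.d, dl) != 0.0, axis=1).sum()) for dl in delta_grid]
    )
    model = fit_nsc(x_df, labels, chosen, priors=priors, name=name)
    return CVResult(
        delta_grid=delta_grid,
        mean_balanced_accuracy=mean_ba,
        sd_balanced_accuracy=ba.std(axis=0, ddof=1),
        mean_accuracy=acc.mean(axis=0),
        sd_accuracy=acc.std(axis=0, ddof=1),
        nonzero_counts=nonzero,
        chosen_delta=chosen,
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
        fold_assignments=assignments,
        model=model,
    )


def nonzero_union(models: list[NSCModel]) -> tuple[set, dict]:
    """Union of nonzero gene sets across models, with per-model counts."""
    if not models:
        raise ValueError("empty model list")
    union: set = set()
    counts: dict = {}
    for i, m in enumerate(models):
        nz = set(m.nonzero_genes)
        union |= nz
        counts[m.name if m.name is not None else i] = len(nz)
    return union, counts
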