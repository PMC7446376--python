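"""Single-gene threshold classifiers (SGC).

One biomarker, one gene (ESR1 for ER, PGR for PgR, ERBB2 for HER2,
MKI67 for Ki67): the model is a single expression threshold chosen to
maximize concordance with the histopathology consensus labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .agreement import ContingencyTable, cohens_kappa, overall_agreement
from .config import NEG, POS

__all__ = ["SGCModel", "train_sgc", "predict_sgc"]


@dataclass
class SGCModel:
    """A trained single-gene threshold rule.

    Calls are positive iff expression strictly exceeds the threshold
    (``positive-above`` orientation, the default).
    """

    gene_id: str
    threshold: float
    orientation: str = "positive-above"
    training_concordance: float | None = None
    training_kappa: float | None = None

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path: str) -> "SGCModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _binary_stats(pred_pos: np.ndarray, label_pos: np.ndarray) -> tuple[float, float]:
    counts = np.array(
        [
            [np.sum(~pred_pos & ~label_pos), np.sum(~pred_pos & label_pos)],
            [np.sum(pred_pos & ~label_pos), np.sum(pred_pos & label_pos)],
        ],
        dtype=float,
    )
    t = ContingencyTable((NEG, POS), counts)
    kap = cohens_kappa(t)
    return overall_agreement(t), (kap if np.isfinite(kap) else -np.inf)


def train_sgc(
    expr: pd.Series, labels: pd.Series, positive_label=POS, orientation: str = "positive-above"
) -> SGCModel:
    """Choose the expression threshold maximizing overall agreement.

    Candidate thresholds are the midpoints between consecutive sorted
    unique expression values plus below-minimum and above-maximum
    sentinels, so every distinct labeling of the samples is reachable.
    Ties on overall agreement are broken by higher kappa, then by the
    lower threshold.

    ``expr`` and ``labels`` are aligned on their index; unresolved
    (missing) labels are excluded.
    """
    if orientation not in ("positive-above", "positive-below"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.DataFrame({"x": expr, "y": labels}).dropna()
    if df.empty:
        raise ValueError("no usable (expression, label) pairs")
    x = df["x"].to_numpy(dtype=float)
    y = (df["y"] == positive_label).to_numpy()
    if y.all() or (~y).all():
        raise ValueError("labels contain a single class; threshold undefined")

    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    best = None
    for t in candidates:
        pred = x > t if orientation == "positive-above" else x < t
        oa, kap = _binary_stats(pred, y)
        key = (oa, kap, -t)  # lower threshold wins the final tie
        if best is None or key > best[0]:
            best = (key, t, oa, kap)
    _, t, oa, kap = best
    return SGCModel(
        gene_id=str(expr.name) if expr.name is not None else "",
        threshold=float(t),
        orientation=orientation,
        training_concordance=float(oa),
        training_kappa=float(kap) if np.isfinite(kap) else None,
    )


def predict_sgc(model: SGCModel, expr: pd.Series) -> pd.Series:
    """Apply a threshold rule; missing expression yields a missing call."""
    x = expr.to_numpy(dtype=float)
    if model.orientation == "positive-above":
        pos = x > model.threshold
    else:
        pos = x < model.threshold
    calls = np.where(pos, POS, NEG).astype(object)
    calls[~np.isfinite(x)] = None
    return pd.Series(calls, index=expr.index, name=model.gene_id)
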