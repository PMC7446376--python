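"""Validation-cohort evaluation of trained classifiers.

Concordance of SGC/MGC predictions against the histopathology labels
(forest-plot style agreement reports per biomarker), the derived
hormone-responsiveness label (ER-positive AND PgR-positive), technical
replicate reproducibility, balanced accuracy, and the discordance
rosters consumed by the survival analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import AgreementReport, agreement_report
from .config import NEG, POS

__all__ = [
    "derive_hormone_responsive",
    "replicate_concordance",
    "balanced_accuracy",
    "ValidationReport",
    "compile_validation_report",
]


def derive_hormone_responsive(er_calls: pd.Series, pgr_calls: pd.Series) -> pd.Series:
    """Hormone responsive iff ER positive AND PgR positive.

    Missing either call propagates to a missing responsiveness label.
    """
    er = pd.Series(er_calls)
    pgr = pd.Series(pgr_calls)
    if len(er) != len(pgr):
        raise ValueError("ER and PgR call vectors differ in length")
    if not er.index.equals(pgr.index):
        pgr = pd.Series(pgr.to_numpy(), index=er.index)
    out = np.where((er == POS) & (pgr == POS), POS, NEG).astype(object)
    missing = er.isna().to_numpy() | pgr.isna().to_numpy()
    out[missing] = None
    return pd.Series(out, index=er.index, name="hormone_responsive")


def replicate_concordance(pairs) -> dict:
    """Fraction of technical-replicate prediction pairs with identical calls.

    ``pairs`` is an iterable of (call_rep1, call_rep2); pairs with a
    missing call are excluded and counted.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no replicate pairs")
    n_excluded = 0
    concordant = 0
    evaluated = 0
    for a, b in pairs:
        if pd.isna(a) or pd.isna(b):
            n_excluded += 1
            continue
        evaluated += 1
        concordant += int(a == b)
    frac = concordant / evaluated if evaluated else float("nan")
    return {
        "concordance": frac,
        "n_pairs": evaluated,
        "n_concordant": concordant,
        "n_discordant": evaluated - concordant,
        "n_excluded": n_excluded,
    }


def balanced_accuracy(pred, truth, classes=None) -> float:
    """Unweighted mean of per-class recall.

    Classes absent from the truth vector are excluded with a warning.
    """
    pred = np.asarray(list(pred), dtype=object)
    truth = np.asarray(list(truth), dtype=object)
    if len(pred) != len(truth):
        raise ValueError("pred and truth differ in length")
    if classes is None:
        classes = sorted(set(truth))
    recalls = []
    for c in classes:
        m = truth == c
        if not m.any():
            warnings.warn(f"class {c!r} absent from truth; excluded", stacklevel=2)
            continue
        recalls.append(float((pred[m] == c).mean()))
    if not recalls:
        raise ValueError("no class present in truth")
    return float(np.mean(recalls))


@dataclass
class ValidationReport:
    """Per-biomarker classifier-vs-histopathology concordance report."""

    agreement: dict = field(default_factory=dict)  # (classifier, biomarker) -> AgreementReport
    discordance: dict = field(default_factory=dict)  # (classifier, biomarker) -> roster DataFrame
    replicate: dict = field(default_factory=dict)  # classifier -> stats (pooled + per biomarker)
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "agreement": {
                f"{clf}:{bm}": rep.to_dict() for (clf, bm), rep in self.agreement.items()
            },
            "discordance_counts": {
                f"{clf}:{bm}": int(len(df)) for (clf, bm), df in self.discordance.items()
            },
            "replicate": self.replicate,
        }

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def compile_validation_report(
    diagnostic: pd.DataFrame,
    predictions: dict[str, pd.DataFrame],
    replicates: dict[str, list] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Assemble the validation report.

    Parameters
    ----------
    diagnostic:
        Histopathology labels, samples × biomarkers.
    predictions:
        Mapping classifier name (e.g. ``"sgc"``, ``"mgc"``) → samples ×
        biomarkers prediction table (indexes aligned by sample id).
    replicates:
        Optional mapping classifier name → list of (rep1, rep2) call
        pairs pooled across biomarkers.
    """
    report = ValidationReport()
    any_overlap = False
    for clf, preds in predictions.items():
        common = diagnostic.index.intersection(preds.index)
        if len(common) == 0:
            continue
        any_overlap = True
        report.n_samples = max(report.n_samples, len(common))
        for bm in preds.columns:
            if bm not in diagnostic.columns:
                continue
            ref = diagnostic.loc[common, bm]
            hat = preds.loc[common, bm]
            rep = agreement_report(ref, hat, n_boot=n_boot, seed=seed)
            report.agreement[(clf, bm)] = rep
            usable = ref.notna() & hat.notna()
            disc = pd.DataFrame(
                {
                    "histopathology": ref[usable & (ref != hat)],
                    "classifier": hat[usable & (ref != hat)],
                }
            )
            report.discordance[(clf, bm)] = disc
    if not any_overlap:
        raise ValueError("no overlapping sample ids between labels and predictions")
    if replicates:
        for clf, pairs in replicates.items():
            report.replicate[clf] = replicate_concordance(pairs)
    return report
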