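"""Closed-form agreement of the rater noise models, and calibration.

Two independent pathologist reads of the same truth, each erring with
probability ε, have a computable joint distribution; from it follow the
expected pairwise overall agreement and Cohen's kappa.  Inverting the
kappa-vs-ε curve gives the per-read error rate that reproduces a target
inter-rater kappa — the route by which the generator's defaults are tied
to published panel concordances.

Binary biomarkers use a symmetric flip model: a read lands on the wrong
side of the cutoff with probability ε.  NHG uses an adjacent-grade
model: with probability ε the read moves one grade (G2 splits the error
evenly between G1 and G3).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def binary_read_matrix(epsilon: float) -> np.ndarray:
    """P(call | truth) for the symmetric binary flip model; order (neg, pos)."""
    return np.array([[1 - epsilon, epsilon], [epsilon, 1 - epsilon]])


def grade_read_matrix(epsilon: float) -> np.ndarray:
    """P(call | truth) for the adjacent-grade model; order (G1, G2, G3)."""
    e = epsilon
    return np.array(
        [
            [1 - e, e, 0.0],
            [e / 2, 1 - e, e / 2],
            [0.0, e, 1 - e],
        ]
    )


def pairwise_agreement_stats(
    truth_probs: np.ndarray, read_matrix: np.ndarray
) -> tuple[float, float]:
    """Expected (overall agreement, Cohen's kappa) of two independent reads.

    ``truth_probs[g]`` is the marginal probability of true category ``g``
    and ``read_matrix[g, c]`` the probability a rater calls ``c`` given
    truth ``g``.
    """
    truth_probs = np.asarray(truth_probs, dtype=float)
    R = np.asarray(read_matrix, dtype=float)
    # joint over the two raters' calls: sum_g P(g) R[g,a] R[g,b]
    joint = np.einsum("g,ga,gb->ab", truth_probs, R, R)
    p_o = float(np.trace(joint))
    marg = truth_probs @ R
    p_e = float(np.sum(marg**2))
    if p_e >= 1.0 - 1e-15:
        return p_o, float("nan")
    return p_o, (p_o - p_e) / (1.0 - p_e)


def expected_pairwise_kappa(epsilon: float, truth_probs, ordinal: bool = False) -> float:
    R = grade_read_matrix(epsilon) if ordinal else binary_read_matrix(epsilon)
    return pairwise_agreement_stats(np.asarray(truth_probs), R)[1]


def error_for_kappa(kappa_target: float, truth_probs, ordinal: bool = False) -> float:
    """Per-read error rate ε whose expected pairwise kappa hits the target.

    Kappa decreases monotonically in ε on [0, 0.5), so the root is unique.
    """
    if not (0.0 < kappa_target <= 1.0):
        raise ValueError("kappa target must be in (0, 1]")

    def f(e: float) -> float:
        return expected_pairwise_kappa(e, truth_probs, ordinal=ordinal) - kappa_target

    lo, hi = 1e-9, 0.499
    if f(lo) < 0:
        raise ValueError(f"kappa target {kappa_target} unreachable even at ε→0")
    if f(hi) > 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12))


def default_rater_error(config) -> dict[str, float]:
    """Per-biomarker read error rates calibrated to the default kappa targets."""
    from .config import BINARY_BIOMARKERS, DEFAULT_KAPPA_TARGETS

    out: dict[str, float] = {}
    for bm in BINARY_BIOMARKERS:
        p = config.biomarker_prevalence[bm]
        out[bm] = error_for_kappa(DEFAULT_KAPPA_TARGETS[bm], [1 - p, p], ordinal=False)
    out["nhg"] = error_for_kappa(
        DEFAULT_KAPPA_TARGETS["nhg"], list(config.grade_probs), ordinal=True
    )
    return out
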