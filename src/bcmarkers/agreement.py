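"""Inter-rater and classifier-vs-pathology agreement statistics.

Implements the concordance toolkit used throughout the package: overall
agreement, category-specific agreement (positive/negative agreement for
binary calls, per-grade agreement for NHG), Cohen's kappa with the
Viera-Garrett interpretation bands, the Matthews correlation
coefficient, percentile-bootstrap confidence intervals, average pairwise
statistics over a multi-rater panel, and majority-vote consensus labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "AgreementReport",
    "overall_agreement",
    "specific_agreement",
    "cohens_kappa",
    "matthews_cc",
    "interpret_kappa",
    "agreement_report",
    "panel_agreement",
    "majority_consensus",
    "consensus_table",
]

#: Kappa interpretation bands (Viera & Garrett).
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "less than chance"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass
class ContingencyTable:
    """Square cross-classification of two call vectors.

    ``counts[a, b]`` is the number of samples called ``categories[a]`` by
    the first party and ``categories[b]`` by the second.
    """

    categories: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the categories")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_calls(cls, calls_a, calls_b, categories=None) -> "ContingencyTable":
        """Cross-tabulate two aligned call vectors, dropping pairs with
        a missing value on either side (pairwise deletion)."""
        a = pd.Series(list(calls_a))
        b = pd.Series(list(calls_b))
        if len(a) != len(b):
            raise ValueError(f"call vectors differ in length: {len(a)} vs {len(b)}")
        keep = a.notna() & b.notna()
        a, b = a[keep], b[keep]
        if categories is None:
            categories = tuple(sorted(set(a) | set(b)))
        else:
            categories = tuple(categories)
        k = len(categories)
        ca = pd.Categorical(a, categories=categories).codes.astype(np.int64)
        cb = pd.Categorical(b, categories=categories).codes.astype(np.int64)
        if (ca < 0).any() or (cb < 0).any():
            bad = sorted((set(a) | set(b)) - set(categories))
            raise ValueError(f"calls outside the stated categories: {bad}")
        counts = np.bincount(ca * k + cb, minlength=k * k).reshape(k, k).astype(float)
        return cls(categories, counts)


def overall_agreement(table: ContingencyTable) -> float:
    """Fraction of samples assigned the same category by both parties."""
    if table.n == 0:
        raise ValueError("empty contingency table")
    return float(np.trace(table.counts)) / table.n


def specific_agreement(table: ContingencyTable, category) -> float:
    """Category-specific agreement 2·n_cc / (2·n_cc + off-diagonal mass
    involving the category).

    For a binary table this is the positive (resp. negative) agreement.
    Returns NaN when neither party ever calls the category (not
    estimable).
    """
    if category not in table.categories:
        raise ValueError(f"category {category!r} not in table")
    c = table.categories.index(category)
    ncc = table.counts[c, c]
    off = table.counts[c, :].sum() + table.counts[:, c].sum() - 2 * ncc
    denom = 2 * ncc + off
    if denom == 0:
        return float("nan")
    return float(2 * ncc / denom)


def cohens_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e).

    NaN (not estimable) when both parties are constant and identical, so
    chance agreement is 1.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = np.trace(table.counts) / n
    row = table.counts.sum(axis=1) / n
    col = table.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def matthews_cc(table: ContingencyTable) -> float:
    """Matthews correlation coefficient of a binary table.

    Equals the Pearson correlation of the two indicator vectors; defined
    as 0 when any margin is empty (one party constant).
    """
    if len(table.categories) != 2:
        raise ValueError("MCC requires a binary (2×2) table")
    (n11, n12), (n21, n22) = table.counts
    r1, r2 = n11 + n12, n21 + n22
    c1, c2 = n11 + n21, n12 + n22
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    return float((n11 * n22 - n12 * n21) / math.sqrt(denom))


def interpret_kappa(kappa: float) -> str:
    """Viera-Garrett interpretation band for a kappa value."""
    if math.isnan(kappa):
        return "not estimable"
    if kappa <= 0:
        return KAPPA_BANDS[0][1]
    for upper, label in KAPPA_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return label
    return KAPPA_BANDS[-1][1]


@dataclass
class AgreementReport:
    """Agreement statistics between two call vectors, with bootstrap CIs."""

    n: int
    n_dropped: int
    categories: tuple
    overall_agreement: float
    overall_agreement_ci: tuple[float, float]
    per_category_agreement: dict
    kappa: float
    kappa_ci: tuple[float, float]
    interpretation: str
    mcc: float | None = None
    table: ContingencyTable | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "n_dropped": self.n_dropped,
            "categories": list(self.categories),
            "overall_agreement": self.overall_agreement,
            "overall_agreement_ci": list(self.overall_agreement_ci),
            "per_category_agreement": {str(k): v for k, v in self.per_category_agreement.items()},
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci),
            "interpretation": self.interpretation,
        }
        if self.mcc is not None:
            d["mcc"] = self.mcc
        return d


def agreement_report(
    calls_a,
    calls_b,
    categories=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementReport:
    """Full agreement report between two aligned call vectors.

    Pairs with a missing value on either side are dropped and counted.
    Confidence intervals are percentile bootstrap over sample pairs.
    """
    a = pd.Series(list(calls_a))
    b = pd.Series(list(calls_b))
    if len(a) != len(b):
        raise ValueError("call vectors differ in length")
    keep = (a.notna() & b.notna()).to_numpy()
    n_dropped = int((~keep).sum())
    a = a[keep].reset_index(drop=True)
    b = b[keep].reset_index(drop=True)
    if len(a) < 2:
        raise ValueError("fewer than 2 usable call pairs")
    table = ContingencyTable.from_calls(a, b, categories)
    oa = overall_agreement(table)
    kap = cohens_kappa(table)
    per_cat = {c: specific_agreement(table, c) for c in table.categories}
    mcc = matthews_cc(table) if len(table.categories) == 2 else None

    rng = np.random.default_rng(seed)
    n = len(a)
    k = len(table.categories)
    ca = pd.Categorical(a, categories=table.categories).codes.astype(np.int64)
    cb = pd.Categorical(b, categories=table.categories).codes.astype(np.int64)
    pair_code = ca * k + cb
    diag = np.arange(k) * k + np.arange(k)
    oa_bs = np.empty(n_boot)
    k_bs = np.empty(n_boot)
    for i in range(n_boot):
        counts = np.bincount(pair_code[rng.integers(0, n, n)], minlength=k * k).astype(float)
        m = counts.reshape(k, k)
        p_o = counts[diag].sum() / n
        p_e = float(m.sum(axis=1) @ m.sum(axis=0)) / n**2
        oa_bs[i] = p_o
        k_bs[i] = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 - 1e-15 else np.nan
    oa_ci = tuple(np.percentile(oa_bs, [2.5, 97.5]))
    k_finite = k_bs[np.isfinite(k_bs)]
    if len(k_finite) == 0:
        k_ci = (float("nan"), float("nan"))
    else:
        k_ci = tuple(np.percentile(k_finite, [2.5, 97.5]))
    return AgreementReport(
        n=n,
        n_dropped=n_dropped,
        categories=table.categories,
        overall_agreement=oa,
        overall_agreement_ci=oa_ci,
        per_category_agreement=per_cat,
        kappa=kap,
        kappa_ci=k_ci,
        interpretation=interpret_kappa(kap),
        mcc=mcc,
        table=table,
    )


def _panel_wide(panel: pd.DataFrame, biomarker: str) -> pd.DataFrame:
    sub = panel[panel["biomarker"] == biomarker]
    if sub.empty:
        raise ValueError(f"no ratings for biomarker {biomarker!r}")
    return sub.pivot(index="sample_id", columns="rater_id", values="call")


def panel_agreement(
    panel: pd.DataFrame,
    biomarker: str,
    reference: str | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Average pairwise agreement over a multi-rater panel.

    With ``reference=None`` all rater pairs are averaged (all-pairs Aκ);
    with ``reference`` set to a rater id or ``"consensus"``, each other
    rater is compared against that reference and the pairwise statistics
    averaged (reference mode).
    """
    wide = _panel_wide(panel, biomarker)
    raters = list(wide.columns)
    if reference is None:
        pairs = list(itertools.combinations(raters, 2))
        get = lambda r: wide[r]  # noqa: E731
    else:
        if reference == "consensus":
            cons, _ = majority_consensus(panel, biomarker)
            wide = wide.join(cons.rename("__consensus__"))
            ref_col = "__consensus__"
        elif reference in raters:
            ref_col = reference
        else:
            raise ValueError(f"unknown reference {reference!r}")
        pairs = [(ref_col, r) for r in raters if r != ref_col]
        get = lambda r: wide[r]  # noqa: E731
    if not pairs:
        raise ValueError("panel has fewer than 2 raters")
    reports = [
        agreement_report(get(r1), get(r2), n_boot=n_boot, seed=seed + i)
        for i, (r1, r2) in enumerate(pairs)
    ]
    kappas = [r.kappa for r in reports]
    return {
        "biomarker": biomarker,
        "n_pairs": len(pairs),
        "mode": "all_pairs" if reference is None else f"vs:{reference}",
        "average_overall_agreement": float(np.mean([r.overall_agreement for r in reports])),
        "average_kappa": float(np.nanmean(kappas)) if np.isfinite(kappas).any() else float("nan"),
        "pairwise": reports,
    }


def majority_consensus(panel: pd.DataFrame, biomarker: str) -> tuple[pd.Series, dict]:
    """Majority-vote consensus label per sample for one biomarker.

    Samples whose calls tie for the modal category are left unresolved
    (NA) — they are reported, and excluded from classifier training.
    Returns ``(labels indexed by sample_id, tie report)``.
    """
    wide = _panel_wide(panel, biomarker)
    labels = {}
    ties = []
    for sample_id, row in wide.iterrows():
        calls = row.dropna()
        if len(calls) == 0:
            ties.append(sample_id)  # no calls at all: unresolved
            labels[sample_id] = None
            continue
        vc = calls.value_counts()
        top = vc.max()
        winners = sorted(vc[vc == top].index)
        if len(winners) > 1:
            labels[sample_id] = None
            ties.append(sample_id)
        else:
            labels[sample_id] = winners[0]
    out = pd.Series(labels, name=biomarker)
    out.index.name = "sample_id"
    return out, {"n_ties": len(ties), "tied_samples": ties}


def consensus_table(panel: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Consensus labels for every biomarker present in a rating panel."""
    cols = {}
    tie_reports = {}
    for bm in panel["biomarker"].unique():
        labels, ties = majority_consensus(panel, bm)
        cols[bm] = labels
        tie_reports[bm] = ties
    return pd.DataFrame(cols), tie_reports
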