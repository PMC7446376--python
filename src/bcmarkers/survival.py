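"""Overall-survival analyses: Kaplan-Meier, log-rank, Cox PH, and the
discordance-stratified analysis within treatment subgroups.

The estimators are backed by lifelines (Efron tie handling for Cox,
Wald confidence intervals); this module adapts them to the package's
tabular conventions and implements the discordance analysis: within a
histopathology-defined stratum (e.g. hormone-responsive by pathology),
samples are split by whether the multigene classifier agrees, and the
discordant-vs-concordant hazard ratio is estimated per adjuvant
treatment subgroup, unadjusted and adjusted for age, node status,
tumor size and the stratum-specific biomarker covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning

from .config import GRADES, NEG, POS
from .evaluation import derive_hormone_responsive

__all__ = [
    "KMCurve",
    "CoxFit",
    "kaplan_meier",
    "logrank_test",
    "cox_ph",
    "discordance_survival_analysis",
    "DISCORDANCE_RULES",
]

TREATMENT_ARMS = ("none", "endocrine_only", "chemo_containing")


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance."""

    times: np.ndarray  # distinct observed times (events and censorings)
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "variance": self.variance,
            }
        )


def kaplan_meier(times, events, label: str | None = None) -> KMCurve:
    """Kaplan-Meier estimator; censorings at an event time are counted
    as at risk for that event (the standard convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no subjects")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    tbl = tbl[tbl.index > 0]
    t = tbl.index.to_numpy(dtype=float)
    d = tbl["observed"].to_numpy(dtype=float)
    n = tbl["at_risk"].to_numpy(dtype=float)
    surv = np.array([kmf.survival_function_at_times(ti).iloc[0] for ti in t])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    greenwood = surv**2 * np.cumsum(terms)
    return KMCurve(times=t, at_risk=n, events=d, survival=surv, variance=greenwood, label=label)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if events.sum() < 1:
        raise ValueError("no events observed")
    m = group == levels[0]
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Efron ties, Wald CIs)."""

    params: pd.Series
    se: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    flag: str | None = None  # non-None marks a problematic fit

    @property
    def estimable(self) -> bool:
        return self.flag is None

    def summary_row(self, covariate: str) -> dict:
        return {
            "coef": float(self.params[covariate]),
            "hr": float(self.hazard_ratios[covariate]),
            "ci": (float(self.ci_lower[covariate]), float(self.ci_upper[covariate])),
            "p": float(self.p_values[covariate]),
        }


def cox_ph(times, events, covariates: pd.DataFrame) -> CoxFit:
    """Fit a Cox PH model by partial likelihood (Efron tie handling).

    Constant covariates are rejected; non-convergence or monotone
    likelihood yields a flagged fit rather than silent output.
    """
    covariates = pd.DataFrame(covariates).astype(float)
    nunique = covariates.nunique()
    constant = list(nunique[nunique <= 1].index)
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    df = covariates.copy()
    df["__time__"] = np.asarray(times, dtype=float)
    df["__event__"] = np.asarray(events, dtype=int)
    n_events = int(df["__event__"].sum())
    if n_events < covariates.shape[1]:
        return CoxFit(
            params=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            hazard_ratios=pd.Series(dtype=float),
            ci_lower=pd.Series(dtype=float),
            ci_upper=pd.Series(dtype=float),
            p_values=pd.Series(dtype=float),
            log_likelihood=float("nan"),
            n=len(df),
            n_events=n_events,
            flag=f"too few events ({n_events}) for {covariates.shape[1]} covariates",
        )
    cph = CoxPHFitter()
    flag = None
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="__time__", event_col="__event__")
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                flag = f"convergence warning: {w.message}"
                break
    except ConvergenceError as err:
        return CoxFit(
            params=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            hazard_ratios=pd.Series(dtype=float),
            ci_lower=pd.Series(dtype=float),
            ci_upper=pd.Series(dtype=float),
            p_values=pd.Series(dtype=float),
            log_likelihood=float("nan"),
            n=len(df),
            n_events=n_events,
            flag=f"did not converge: {err}",
        )
    s = cph.summary
    return CoxFit(
        params=s["coef"],
        se=s["se(coef)"],
        hazard_ratios=s["exp(coef)"],
        ci_lower=np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        ci_upper=np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        p_values=s["p"],
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        flag=flag,
    )


def _hormone_labels(calls: pd.DataFrame) -> pd.Series:
    return derive_hormone_responsive(calls["er"], calls["pgr"])


#: Histopathology-defined strata, the classifier call that makes a
#: sample discordant within each, and the stratum-specific multivariable
#: covariates (age, node status and tumor size are always included;
#: covariates constant within a stratum are dropped automatically).
DISCORDANCE_RULES: dict[str, dict] = {
    "hormone_responsive": {
        "stratum": lambda h: _hormone_labels(h) == POS,
        "discordant": lambda m: _hormone_labels(m) == NEG,
        "extra_covariates": ["er", "pgr", "nhg"],
    },
    "her2_negative": {
        "stratum": lambda h: h["her2"] == NEG,
        "discordant": lambda m: m["her2"] == POS,
        "extra_covariates": ["er", "pgr", "her2", "nhg"],
    },
    "ki67_high": {
        "stratum": lambda h: h["ki67"] == POS,
        "discordant": lambda m: m["ki67"] == NEG,
        "extra_covariates": ["her2", "nhg"],
    },
    "nhg_low_grade": {
        "stratum": lambda h: h["nhg"].isin(["G1", "G2"]),
        "discordant": lambda m: m["nhg"] == "G3",
        "extra_covariates": ["er", "pgr", "her2"],
    },
}


def _code_covariates(histo: pd.DataFrame, clinical: pd.DataFrame, extra: list[str]) -> pd.DataFrame:
    cov = clinical[["age", "node_status", "tumor_size"]].astype(float).copy()
    for bm in extra:
        if bm == "nhg":
            cov["nhg"] = histo["nhg"].map({g: i + 1 for i, g in enumerate(GRADES)}).astype(float)
        else:
            cov[bm] = (histo[bm] == POS).astype(float)
    return cov


def discordance_survival_analysis(
    histo: pd.DataFrame,
    mgc: pd.DataFrame,
    clinical: pd.DataFrame,
    rule: str,
) -> dict:
    """Fig-3 style analysis for one biomarker rule.

    Within the histopathology-defined stratum, samples are concordant or
    discordant according to the MGC call; for the whole stratum and for
    each adjuvant-treatment subgroup the result holds KM curves, the
    log-rank test, and unadjusted plus multivariable-adjusted Cox hazard
    ratios for discordant vs concordant.  Subgroups with fewer than two
    events in either arm are reported as not estimable.
    """
    if rule not in DISCORDANCE_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(DISCORDANCE_RULES)}")
    spec = DISCORDANCE_RULES[rule]
    common = histo.index.intersection(mgc.index).intersection(clinical.index)
    histo, mgc, clinical = histo.loc[common], mgc.loc[common], clinical.loc[common]
    in_stratum = spec["stratum"](histo).fillna(False)
    discordant = spec["discordant"](mgc).fillna(False)

    results: dict[str, dict] = {}
    for arm in ("all",) + TREATMENT_ARMS:
        sel = in_stratum if arm == "all" else in_stratum & (clinical["treatment"] == arm)
        sub_clin = clinical[sel]
        sub_disc = discordant[sel].to_numpy()
        times = sub_clin["time"].to_numpy()
        events = sub_clin["event"].to_numpy()
        res: dict = {
            "n": int(sel.sum()),
            "n_discordant": int(sub_disc.sum()),
            "n_events": int(events.sum()),
        }
        ev_disc = int(events[sub_disc].sum())
        ev_conc = int(events[~sub_disc].sum())
        if sub_disc.sum() == 0 or (~sub_disc).sum() == 0 or min(ev_disc, ev_conc) < 2:
            res["estimable"] = False
            res["reason"] = (
                f"events concordant/discordant = {ev_conc}/{ev_disc}; "
                "need ≥2 in each arm"
            )
            results[arm] = res
            continue
        res["estimable"] = True
        res["km"] = {
            "concordant": kaplan_meier(times[~sub_disc], events[~sub_disc], "concordant"),
            "discordant": kaplan_meier(times[sub_disc], events[sub_disc], "discordant"),
        }
        stat, p = logrank_test(times, events, sub_disc)
        res["logrank"] = {"statistic": stat, "p": p}
        res["unadjusted"] = cox_ph(
            times, events, pd.DataFrame({"discordant": sub_disc.astype(float)})
        )
        cov = _code_covariates(histo[sel], sub_clin, spec["extra_covariates"])
        cov.insert(0, "discordant", sub_disc.astype(float))
        nunique = cov.nunique()
        cov = cov.drop(columns=list(nunique[nunique <= 1].index.difference(["discordant"])))
        res["adjusted"] = cox_ph(times, events, cov)
        results[arm] = res
    return results
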