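"""Simulation and pipeline configuration.

The synthetic cohorts emulate the statistical structure of a
breast-cancer RNA-seq biomarker study: latent binary biomarker states
(ER, PgR, HER2, Ki67) and an ordinal grade (NHG) drive both gene
expression and noisy pathologist ratings; rated labels drive adjuvant
therapy assignment; survival carries a planted excess hazard for tumors
that are truly hormone-insensitive but rated hormone-responsive.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Binary biomarkers, in canonical order.
BINARY_BIOMARKERS: tuple[str, ...] = ("er", "pgr", "her2", "ki67")
#: All five conventional biomarkers.
BIOMARKERS: tuple[str, ...] = BINARY_BIOMARKERS + ("nhg",)
#: The designated single gene for each binary biomarker.
MARKER_GENES: dict[str, str] = {
    "er": "ESR1",
    "pgr": "PGR",
    "her2": "ERBB2",
    "ki67": "MKI67",
}
#: Category sets per biomarker.
GRADES: tuple[str, ...] = ("G1", "G2", "G3")
POS, NEG = "pos", "neg"

#: Multi-rater panel agreement targets (average pairwise Cohen's kappa)
#: used to calibrate the default per-read error rates.
DEFAULT_KAPPA_TARGETS: dict[str, float] = {
    "er": 0.920,
    "pgr": 0.891,
    "her2": 0.899,
    "ki67": 0.734,
    "nhg": 0.581,
}


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"invalid config field {fieldname!r}: {message}")


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_samples, n_genes:
        Cohort and transcriptome sizes.
    biomarker_prevalence:
        Fraction of truly-positive tumors per binary biomarker.
    marker_effect:
        Log2-scale mean shift between positive and negative tumors,
        applied to the designated marker gene and its informative block
        (for NHG: shift per grade step around G2).
    block_size:
        Number of informative (non-marker) genes per biomarker.
    block_correlation:
        Within-block residual correlation, via a shared latent factor.
    noise_sd:
        Residual SD of log2 expression.
    rater_error:
        Per-read misclassification probability per biomarker. ``None``
        entries are calibrated so that two independent reads reach the
        pairwise-kappa targets in :data:`DEFAULT_KAPPA_TARGETS`.
    n_raters:
        Independent pathologist readings per sample and biomarker.
    ihc_cutoff, ki67_cutoff:
        Positivity cutoffs on the latent staining fraction (1% stained
        cells for hormone receptors, >20% positive nuclei for Ki67).
    grade_probs:
        Marginal G1/G2/G3 probabilities.
    er_pgr_correlation:
        Latent-normal correlation of the ER and PgR states (their joint
        distribution is not pinned down by published marginals, so it is
        an explicit knob).
    proliferation_coupling:
        Correlation between the latent proliferation score that sets
        Ki67 status and the latent scale that sets NHG.
    treatment_override:
        Fraction of samples whose deterministic guideline treatment is
        replaced by a random arm (keeps all three arms populated).
    hazard_baseline:
        Baseline event rate, events per month.
    discordant_log_hr:
        Planted log hazard ratio for truly hormone-insensitive tumors
        rated hormone-responsive.
    censor_horizon:
        Administrative censoring time, months.
    """

    n_samples: int = 500
    n_genes: int = 1000
    biomarker_prevalence: dict[str, float] = field(
        default_factory=lambda: {"er": 0.85, "pgr": 0.72, "her2": 0.13, "ki67": 0.33}
    )
    marker_effect: dict[str, float] = field(
        default_factory=lambda: {"er": 4.0, "pgr": 3.0, "her2": 3.0, "ki67": 2.0, "nhg": 1.5}
    )
    block_size: int = 20
    block_correlation: float = 0.5
    noise_sd: float = 1.0
    #: SD of the purely technical (library/sequencing) noise, log2 units;
    #: the only component re-drawn between technical replicates.
    technical_sd: float = 0.25
    rater_error: dict[str, float] | None = None
    n_raters: int = 3
    ihc_cutoff: float = 0.01
    ki67_cutoff: float = 0.20
    grade_probs: tuple[float, float, float] = (0.15, 0.55, 0.30)
    er_pgr_correlation: float = 0.6
    proliferation_coupling: float = 0.7
    treatment_override: float = 0.10
    hazard_baseline: float = 0.003
    discordant_log_hr: float = math.log(2.64)
    censor_horizon: float = 60.0
    seed: int = 0
    #: Seed of the gene architecture (baseline means). Cohorts meant to
    #: share one transcriptome (training vs validation) must share it;
    #: it is deliberately separate from the cohort seed.
    gene_seed: int = 104729

    def __post_init__(self) -> None:
        self.validate()
        if self.rater_error is None:
            from .calibration import default_rater_error

            self.rater_error = default_rater_error(self)
        else:
            for bm, eps in self.rater_error.items():
                if bm not in BIOMARKERS:
                    raise ConfigError("rater_error", f"unknown biomarker {bm!r}")
                if not (0.0 <= eps < 0.5):
                    raise ConfigError("rater_error", f"{bm}: ε={eps} outside [0, 0.5)")

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples", "must be ≥ 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes", "must be ≥ 1")
        for bm in BINARY_BIOMARKERS:
            p = self.biomarker_prevalence.get(bm)
            if p is None or not (0.0 < p < 1.0):
                raise ConfigError("biomarker_prevalence", f"{bm}: must be in (0, 1)")
        if self.block_size < 0:
            raise ConfigError("block_size", "must be ≥ 0")
        if self.block_size * 5 + 4 > self.n_genes:
            raise ConfigError(
                "n_genes",
                f"need ≥ block_size×5 + 4 = {self.block_size * 5 + 4} genes",
            )
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigError("block_correlation", "must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd", "must be > 0")
        if self.technical_sd < 0:
            raise ConfigError("technical_sd", "must be ≥ 0")
        if self.n_raters < 1:
            raise ConfigError("n_raters", "must be ≥ 1")
        for name, c in (("ihc_cutoff", self.ihc_cutoff), ("ki67_cutoff", self.ki67_cutoff)):
            if not (0.0 < c < 1.0):
                raise ConfigError(name, "must be in (0, 1)")
        if len(self.grade_probs) != 3 or abs(sum(self.grade_probs) - 1.0) > 1e-9 or min(
            self.grade_probs
        ) <= 0:
            raise ConfigError("grade_probs", "must be 3 positive fractions summing to 1")
        if not (-1.0 < self.er_pgr_correlation < 1.0):
            raise ConfigError("er_pgr_correlation", "must be in (−1, 1)")
        if not (-1.0 < self.proliferation_coupling < 1.0):
            raise ConfigError("proliferation_coupling", "must be in (−1, 1)")
        if not (0.0 <= self.treatment_override <= 1.0):
            raise ConfigError("treatment_override", "must be in [0, 1]")
        if self.hazard_baseline < 0:
            raise ConfigError("hazard_baseline", "must be ≥ 0")
        if self.censor_horizon <= 0:
            raise ConfigError("censor_horizon", "must be > 0")

    def cutoff_for(self, biomarker: str) -> float:
        """Positivity cutoff on the latent fraction for a binary biomarker."""
        if biomarker in ("er", "pgr"):
            return self.ihc_cutoff
        if biomarker == "ki67":
            return self.ki67_cutoff
        if biomarker == "her2":
            # HER2 positivity is an amplification call, not a staining
            # fraction; an internal 0.5 scale point stands in for it.
            return 0.5
        raise ValueError(f"no latent-fraction cutoff for {biomarker!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grade_probs"] = list(self.grade_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "grade_probs" in d:
            d["grade_probs"] = tuple(d["grade_probs"])
        return cls(**d)


def save_config(config: Any, path: str) -> None:
    """Serialize a config dataclass to YAML (or JSON if path ends .json)."""
    d = config.to_dict()
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_sim_config(path: str) -> SimConfig:
    with open(path) as fh:
        if str(path).endswith(".json"):
            d = json.load(fh)
        else:
            d = yaml.safe_load(fh)
    return SimConfig.from_dict(d)
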