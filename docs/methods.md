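# Methods

`bcmarkers` re-creates, on fully synthetic data, the analysis pattern of
RNA-seq-based classification of the five conventional breast-cancer
biomarkers — ER, PgR, HER2, Ki67 and Nottingham histologic grade (NHG) —
against multi-rater histopathology: classifier training on consensus
labels, concordance evaluation with agreement statistics, and a survival
analysis of classifier-pathology discordance. This note documents the
models, the defaults and why they were chosen, and what the synthetic
results do and do not show about real cohorts.

## Synthetic cohort model

**Latent truth.** Each sample carries four binary states (ER, PgR, HER2,
Ki67) and an ordinal grade. States are thresholded latent Gaussians
(a Gaussian copula): ER and PgR share a latent correlation
(`er_pgr_correlation`, default 0.6 — the joint distribution of the
receptors is not pinned down by published marginals, so it is an explicit
knob rather than a guess); Ki67 is thresholded from a proliferation
score that also drives the grade through `proliferation_coupling`
(default 0.7), making Ki67-high tumors tend toward G3. Default
prevalences (ER 0.85, PgR 0.72, HER2 0.13, Ki67-high 0.33, grades
0.15/0.55/0.30) describe a population-based early-breast-cancer series;
Ki67's third reflects the quality-assurance convention of calibrating
the cutoff so that about one third of cases are Ki67-high.

Each binary biomarker also has a latent staining/positivity fraction
consistent with its state under the clinical cutoff (≥1% stained cells
for hormone receptors, >20% positive nuclei for Ki67; HER2 uses an
internal 0.5 scale point since its clinical call is an
amplification/overexpression judgment, not a fraction). Positive tumors
draw heavily stained fractions (Beta(4,1) above the cutoff), negative
tumors barely stained ones (Beta(1,4) below) — the strongly bimodal
pattern typical of hormone-receptor immunohistochemistry.

**Expression.** Log2-scale Gaussians directly: upstream read-level
quantification is out of scope, and all classifiers operate on log
expression. Each biomarker has a designated marker gene (ESR1, PGR,
ERBB2, MKI67) plus an informative block (`block_size`, default 20)
shifted by `marker_effect` between positive and negative tumors (for
NHG, per grade step around G2). Within a block, residuals share a latent
factor giving correlation `block_correlation` (default 0.5) — the
classifiers must be able to recruit co-expressed non-marker genes, which
is what makes multigene signatures non-trivial. Remaining genes are pure
noise. Residual SD splits into a biological component (`noise_sd`, 1.0
log2 units) and a technical component (`technical_sd`, 0.25 log2 units);
only the technical layer is re-drawn for technical replicates, so
replicate reproducibility reflects measurement noise, not fresh biology.
Gene baselines are keyed by a separate `gene_seed` so that cohorts meant
to share a transcriptome (training vs validation) do share it.

**Raters.** Each of `n_raters` independent readings errs with a
per-biomarker probability ε: binary reads land on the wrong side of the
cutoff with probability exactly ε (the read itself is a perturbed
fraction, so re-calling at a 10% hormone-receptor cutoff is supported);
NHG errs to an adjacent grade (G2 splits its error both ways). Because
the error model is exact, expected pairwise agreement and Cohen's κ have
closed forms, and ε defaults are *solved* (Brent root-finding on the
closed form) from published panel concordances: average pairwise κ of
0.920 (ER), 0.891 (PgR), 0.899 (HER2), 0.734 (Ki67) and 0.581 (NHG).
The resulting defaults are ε ≈ 0.011, 0.023, 0.012, 0.065 and 0.143.

**Clinical layer.** Therapy follows the *rated* labels
deterministically — chemotherapy-containing if rated HER2+, Ki67-high
or G3; endocrine alone if rated ER+ and PgR+; otherwise none — with a
10% random override so all arms stay populated. Overall survival is
exponential with log-hazard `log(hazard_baseline) + discordant_log_hr ·
I(truly hormone-insensitive ∧ rated hormone-responsive)`; defaults
(baseline 0.003/month, horizon 60 months) give roughly 15% deaths over
follow-up, and the planted discordance log-hazard is log 2.64. Censoring
is administrative at the horizon only; dropout would add nothing the
tests could detect. When a rating panel ties (possible with the
six-reading training panel), the consensus label stays unresolved for
classifier training, but therapy assignment falls back to the
conservative side (negative; G2 for grade).

## Classifiers

**Single-gene classifier (SGC).** One expression threshold per hormone
or proliferation biomarker, on its designated gene. Candidates are the
midpoints between consecutive sorted unique values plus sentinels below
and above the range, so every achievable labeling is considered; the
threshold maximizing overall agreement with the consensus labels wins,
ties broken by higher κ, then by the lower threshold. Calls are positive
strictly above the threshold — a convention, documented and tested.
Optimizing overall agreement (rather than κ or balanced accuracy) is a
package decision; it matches the headline concordance metric reported
throughout.

**Multigene classifier (MGC), nearest shrunken centroids.** Fit on the
`top_k` most-varying genes (default 5,000, capped at the transcriptome
size). Per gene i and class k:

    d_ik  = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)
    d'_ik = sign(d_ik) (|d_ik| − Δ)₊
    x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik

with s_i the pooled within-class SD, s0 the median of the s_i, and
prediction by the smallest δ_k(x) = Σ_i (x_i − x̄'_ik)²/(s_i+s0)²
− 2 log π_k (ties to the first class in sorted order). The m_k
convention follows the widely used reference implementation of the
method (its original publication prints 1/n_k + 1/n; the hand-checkable
identities in the test suite fix 1/n_k − 1/n as normative here). Priors
default to empirical class frequencies and are overridable, since a
deliberately enriched training cohort should not export its enrichment
to population deployment. NHG is one three-class model, not
one-vs-rest.

**Shrinkage selection.** Repeated stratified cross-validation (5 folds ×
10 repeats by default) over a grid of 30 evenly spaced Δ from 0 to
max|d_ik| (the smallest Δ that zeroes every gene), maximizing mean
balanced accuracy (unweighted mean of per-class recall); ties prefer the
larger, sparser Δ. Folds come from scikit-learn's seeded
RepeatedStratifiedKFold; classes smaller than the fold count shrink the
fold count with a warning. Per-fold sufficient statistics are computed
once and re-shrunk per Δ, so the grid costs little beyond the fits.

## Agreement statistics

Overall agreement trace(N)/n; category-specific agreement
2n_cc/(2n_cc + off-diagonal mass involving c), which reduces to the
familiar positive/negative agreement for binary tables; Cohen's
κ = (p_o − p_e)/(1 − p_e) with κ reported not-estimable when both
parties are constant and identical; MCC for binary tables (0 when a
margin is empty); bands per Viera-Garrett (slight/fair/moderate/
substantial/almost perfect). Confidence intervals are percentile
bootstrap over sample pairs (2,000 resamples, seeded) for both overall
agreement and κ — one uniform, auditable mechanism. Multi-rater panels
are summarized as average pairwise statistics, either over all rater
pairs or against a designated reference (a rater or the consensus);
missing calls are deleted pairwise per comparison. Majority consensus
takes the modal category per sample; ties are left unresolved and
excluded from training rather than arbitrated — excluding avoids
injecting labels the procedure cannot justify.

## Survival analysis

Kaplan-Meier, the two-group log-rank test and Cox proportional hazards
are delegated to lifelines (Efron tie handling, Wald CIs); the module
adds Greenwood variances from the event table, estimability guards, and
the discordance analysis. Within a histopathology-defined stratum
(hormone-responsive = ER+ and PgR+; HER2-negative; Ki67-high; G1+G2),
samples are discordant when the MGC calls the complementary state; per
treatment arm the module reports KM curves, the log-rank p, and the
discordant-vs-concordant HR unadjusted and adjusted for age (years,
continuous), node status (binary), tumor size (mm, continuous) and the
stratum-specific biomarker covariates (grade coded ordinally 1–3);
covariates constant within a stratum are dropped automatically. Arms
with fewer than two events on either side are reported not-estimable
rather than fitted. Raw p-values, no multiplicity correction, α = 0.05
conventions throughout.

## Pipeline defaults and calibration

The end-to-end replica mirrors a two-cohort design: a 405-sample
training cohort enriched for HER2-positive and ER-negative tumors
(prevalences 0.70/0.60/0.30/0.35) rated by a six-reading panel (three
readers × two stains), and a 3,273-sample population-prevalence
validation cohort with a single routine diagnostic rating. The
diagnostic read's error rates (ε = 0.08 ER, 0.11 PgR, 0.076 HER2, 0.30
Ki67, 0.20 NHG) are calibrated so classifier-vs-diagnostic concordance
lands in the published low-90s/high-60s percent range: in this
generator the classifiers track latent truth closely, so the diagnostic
read's own error necessarily carries most of the observed discordance
mass. That discordance mass is also what gives the survival analysis a
non-degenerate discordant arm. All cohort seeds derive from one global
seed; outputs (cohorts, nine model JSONs, concordance report, survival
analyses) are hashed into a manifest, and identical configurations
reproduce identical hashes.

## Verification scales

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each check is statistically
informative: agreement statistics against brute-force pair counting on
1,000 random tables; the NSC formulas against a fully hand-computed
2-gene example and a standardized-centroid oracle on 100 random
instances; SGC thresholds against exhaustive search on 200 random
vectors; rater calibration on 5,000-sample panels; planted-signal
recovery with 20 informative genes at Δμ = 2 (n = 300 train / 1,000
test, 10 seeds) against the generative Bayes rule (equal-prior variant,
the balanced-accuracy ceiling); Cox against a maximized exact partial
likelihood on tie-free data and a planted HR = 2 at n = 2,000; and the
discordance replica at 20 validation cohorts of 2,000 samples × 1,000
genes, checking CI coverage of the planted HR 2.64.

## Limitations

Passing tests show the machinery is correct under the generator's
assumptions, not that real cohorts behave this way. The expression model
is Gaussian with a single shared factor per biomarker block — no
count-level noise, library-size effects, batch structure, or inter-block
cross-talk beyond the planted state correlations; real marker
distributions are heavier-tailed and the MGC's advantage over the SGC is
correspondingly larger here than in tissue data. Rater errors are
independent across readers, with no shared-slide or laboratory effects,
so consensus labels are cleaner than a real panel's. Survival is
exponential with a single planted covariate; age, node status and tumor
size carry no hazard in the generator, so multivariable adjustment is
exercised structurally (estimability, coding, constant-dropping) rather
than against confounding. NHG is simulated directly as an ordinal latent
rather than through its three morphologic subscores, and grade G1 is
intentionally scarce — the grade classifier's weakness on G1 mirrors
that imbalance, not tissue morphology.
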