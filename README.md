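# bcmarkers

RNA-seq classifiers for the five conventional breast-cancer biomarkers —
estrogen receptor (ER), progesterone receptor (PgR), HER2, Ki67 and
Nottingham histologic grade (NHG) — trained and validated against
multi-rater histopathology, with the full agreement-statistics toolkit
and a survival analysis of classifier-pathology discordance. Everything
runs end-to-end on a built-in synthetic cohort generator, so the whole
analysis is reproducible on a laptop with no external data.

Who this is for: computational pathology / translational genomics groups
who want a tested, reusable implementation of this analysis pattern —
single-gene threshold classifiers (SGC), nearest-shrunken-centroid
multigene classifiers (MGC), consensus labeling, concordance reporting,
and discordance-stratified survival — and a generator that produces
cohorts with the right statistical structure for methods work.

## The models

**SGC** — one threshold t on the designated gene's log2 expression
(ESR1, PGR, ERBB2, MKI67), chosen over all midpoints of sorted unique
values to maximize overall agreement with consensus pathology.

**MGC** — nearest shrunken centroids on the top-varying gene space. Per
gene i, class k:

    d_ik  = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)
    d′_ik = sign(d_ik)(|d_ik| − Δ)₊,            x̄′_ik = x̄_i + m_k (s_i + s0) d′_ik
    δ_k(x) = Σ_i (x_i − x̄′_ik)²/(s_i + s0)² − 2 log π_k   →   argmin_k

Soft-thresholding by Δ zeroes uninformative genes; Δ is picked by
repeated stratified cross-validation on balanced accuracy.

**Agreement** — overall agreement, category-specific (positive/negative)
agreement 2n_cc/(2n_cc + discordant mass), Cohen's κ = (p_o−p_e)/(1−p_e)
with Viera-Garrett bands, MCC, percentile-bootstrap CIs, average
pairwise panel statistics, majority-vote consensus.

**Survival** — Kaplan-Meier, log-rank, Cox PH (Efron ties, via
lifelines). Within a pathology-defined stratum (e.g. hormone-responsive
= ER+ and PgR+), patients whose MGC call disagrees form the discordant
arm; the discordant-vs-concordant hazard ratio is estimated per
adjuvant-treatment subgroup, unadjusted and adjusted for age, nodal
status, tumor size and stratum-specific biomarkers.

## Worked example

```python
from bcmarkers import SimConfig, generate_cohort, train_sgc, predict_sgc
from bcmarkers.agreement import consensus_table, agreement_report

cfg = SimConfig(n_samples=400, n_genes=150, block_size=10, seed=1)
truth, expr, panel, clinical = generate_cohort(cfg)
consensus, _ = consensus_table(panel)

model = train_sgc(expr.loc["ESR1"], consensus["er"])
print(model.threshold, model.training_concordance)
```

prints `8.027... 0.9875`: ER-positive tumors express ESR1 about four
log2 units above negative ones, and the learned threshold separates them
with 99% concordance to the consensus labels. Applying the model to an
independent 1,000-sample cohort (`examples/03_single_gene_classifier.py`)
prints

```
overall agreement 0.986 (95% CI 0.978-0.992)
kappa 0.940, positive agreement 0.992, negative agreement 0.948
```

i.e. the single-gene rule recovers the true ER state of unseen tumors
almost as well as pathologists agree with each other.

The `examples/` directory has one short script per capability:
cohort simulation, rater agreement and consensus, SGC, MGC with the
shrinkage profile, the validation concordance report with technical
replicates, and the discordance survival analysis. The full study
replica runs from the shell:

```bash
bcpipe run --out runs/replica --seed 1 -v
```

writing cohorts, nine trained model JSONs, the concordance report, four
survival analyses and a hash manifest (re-running the same config
reproduces identical hashes).

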