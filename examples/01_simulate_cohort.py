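"""Simulate a breast-cancer cohort: biomarker truth, expression, ratings,
and clinical follow-up.

The generator plants binary ER/PgR/HER2/Ki67 states and an ordinal grade,
drives marker-gene expression blocks from them, rates each sample with
three noisy pathologist reads, assigns guideline-style therapy from the
rated labels, and draws overall survival.
"""

from bcmarkers import SimConfig, generate_cohort

config = SimConfig(n_samples=500, n_genes=300, block_size=20, seed=42)
truth, expr, panel, clinical = generate_cohort(config)

print(f"cohort: {config.n_samples} samples x {config.n_genes} genes")
print("\ntrue biomarker prevalence (configured -> realized):")
for bm, p in config.biomarker_prevalence.items():
    print(f"  {bm:5}: {p:.2f} -> {truth[bm].mean():.3f}")
print("grade distribution:", truth["nhg"].value_counts(normalize=True).round(3).to_dict())

print(f"\nexpression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples (log2 scale)")
print("ESR1 mean in ER+ vs ER-: "
      f"{expr.loc['ESR1', truth['er'] == 1].mean():.2f} vs "
      f"{expr.loc['ESR1', truth['er'] == 0].mean():.2f} "
      f"(planted shift {config.marker_effect['er']} log2 units)")

print(f"\nrating panel: {len(panel)} calls "
      f"({config.n_raters} raters x 5 biomarkers x {config.n_samples} samples)")
print("treatment arms:", clinical["treatment"].value_counts().to_dict())
print(f"deaths within {config.censor_horizon:.0f} months: {clinical['event'].sum()} "
      f"({clinical['event'].mean():.1%} of the cohort)")
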