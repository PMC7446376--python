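"""Inter-pathologist agreement and consensus labels.

Average pairwise overall agreement and Cohen's kappa over all rater
pairs, per biomarker, with the Viera-Garrett interpretation band; then
majority-vote consensus labels (the classifier training targets).
"""

from bcmarkers import SimConfig, generate_cohort, interpret_kappa
from bcmarkers.agreement import consensus_table, panel_agreement

config = SimConfig(n_samples=2000, n_genes=104, seed=7)
truth, expr, panel, _ = generate_cohort(config)

print("average pairwise agreement over the 3-rater panel:")
print(f"{'biomarker':>9}  {'OA%':>6}  {'Akappa':>6}  band")
for bm in ("er", "pgr", "her2", "ki67", "nhg"):
    res = panel_agreement(panel, bm, n_boot=100, seed=0)
    kap = res["average_kappa"]
    print(f"{bm:>9}  {100 * res['average_overall_agreement']:6.1f}  {kap:6.3f}  {interpret_kappa(kap)}")

consensus, ties = consensus_table(panel)
print("\nmajority-consensus labels (ties left unresolved):")
for bm in consensus.columns:
    n_tie = ties[bm]["n_ties"]
    print(f"  {bm:5}: {consensus[bm].notna().sum()} labeled, {n_tie} tied")
print("\nThe hormone receptors agree almost perfectly between raters;")
print("Ki67 and grade are noticeably noisier - the same ordering the")
print("consensus-label quality inherits.")
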