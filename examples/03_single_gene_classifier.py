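"""Single-gene classifier (SGC): one expression threshold per biomarker.

Trains the ESR1 threshold for ER status against consensus pathology and
applies it to an independent cohort.
"""

from bcmarkers import SimConfig, generate_cohort, predict_sgc, train_sgc
from bcmarkers.agreement import agreement_report, consensus_table

train_cfg = SimConfig(n_samples=400, n_genes=150, block_size=10, seed=1)
truth, expr, panel, _ = generate_cohort(train_cfg)
consensus, _ = consensus_table(panel)

model = train_sgc(expr.loc["ESR1"], consensus["er"])
print(f"trained rule: ER-positive iff ESR1 > {model.threshold:.3f} (log2)")
print(f"training concordance {model.training_concordance:.3f}, kappa {model.training_kappa:.3f}")

test_cfg = SimConfig(n_samples=1000, n_genes=150, block_size=10, seed=2)
truth_te, expr_te, panel_te, _ = generate_cohort(test_cfg)
calls = predict_sgc(model, expr_te.loc["ESR1"])
truth_labels = truth_te["er"].map({1: "pos", 0: "neg"})
rep = agreement_report(truth_labels, calls, n_boot=500, seed=0)
print(f"\nindependent cohort vs true ER state (n={rep.n}):")
print(f"  overall agreement {rep.overall_agreement:.3f} "
      f"(95% CI {rep.overall_agreement_ci[0]:.3f}-{rep.overall_agreement_ci[1]:.3f})")
print(f"  kappa {rep.kappa:.3f}, positive agreement "
      f"{rep.per_category_agreement['pos']:.3f}, negative agreement "
      f"{rep.per_category_agreement['neg']:.3f}")
print("\nA single well-chosen gene carries most of the ER signal; the")
print("threshold sits in the gap between the two expression modes.")
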