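"""Synthetic cohort generator: determinism, planted effect sizes,
rater-noise calibration, clinical/survival structure, config validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcmarkers import SimConfig, generate_cohort, simulate_clinical, simulate_raters
from bcmarkers.agreement import consensus_table, panel_agreement
from bcmarkers.calibration import (
    error_for_kappa,
    expected_pairwise_kappa,
    pairwise_agreement_stats,
    binary_read_matrix,
)
from bcmarkers.config import ConfigError
from bcmarkers.simulate import replicate_expression


def small_cfg(**kw):
    kw.setdefault("n_samples", 200)
    kw.setdefault("n_genes", 120)
    kw.setdefault("block_size", 10)
    kw.setdefault("seed", 5)
    return SimConfig(**kw)


# ------------------------------------------------------------- determinism


def test_identical_config_reproduces_identical_cohort():
    a = generate_cohort(small_cfg())
    b = generate_cohort(small_cfg())
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)


def test_different_seed_changes_cohort():
    t1, *_ = generate_cohort(small_cfg(seed=1))
    t2, *_ = generate_cohort(small_cfg(seed=2))
    assert not t1.equals(t2)


# ----------------------------------------------------------- configuration


@pytest.mark.parametrize(
    "kw",
    [
        {"n_samples": 0},
        {"biomarker_prevalence": {"er": 1.2, "pgr": 0.7, "her2": 0.1, "ki67": 0.3}},
        {"block_correlation": 1.0},
        {"noise_sd": 0.0},
        {"n_genes": 30, "block_size": 10},
        {"censor_horizon": -1.0},
        {"rater_error": {"er": 0.6}},
        {"grade_probs": (0.5, 0.5, 0.5)},
    ],
)
def test_invalid_config_names_field(kw):
    with pytest.raises(ConfigError):
        small_cfg(**kw)


def test_config_roundtrip(tmp_path):
    from bcmarkers.config import load_sim_config, save_config

    cfg = small_cfg()
    p = tmp_path / "cfg.yaml"
    save_config(cfg, p)
    assert load_sim_config(p) == cfg


# ------------------------------------------------------------- expression


def test_no_signal_marker_gene_null_t_statistic():
    cfg = SimConfig(
        n_samples=500,
        n_genes=120,
        block_size=10,
        marker_effect={"er": 0.0, "pgr": 0.0, "her2": 0.0, "ki67": 0.0, "nhg": 0.0},
        noise_sd=1.0,
        seed=21,
    )
    truth, expr, _, _ = generate_cohort(cfg)
    x = expr.loc["ESR1"]
    t, _ = stats.ttest_ind(x[truth["er"] == 1], x[truth["er"] == 0])
    assert abs(t) < 4


def test_marker_effect_recovered_at_large_n():
    cfg = SimConfig(
        n_samples=2000,
        n_genes=120,
        block_size=10,
        biomarker_prevalence={"er": 0.85, "pgr": 0.72, "her2": 0.13, "ki67": 0.33},
        marker_effect={"er": 4.0, "pgr": 3.0, "her2": 3.0, "ki67": 2.0, "nhg": 1.5},
        noise_sd=1.0,
        seed=8,
    )
    truth, expr, _, _ = generate_cohort(cfg)
    x = expr.loc["ESR1"]
    diff = x[truth["er"] == 1].mean() - x[truth["er"] == 0].mean()
    assert diff == pytest.approx(4.0, abs=0.2)


def test_block_correlation_structure():
    cfg = small_cfg(n_samples=1000, block_correlation=0.5, seed=13)
    truth, expr, _, _ = generate_cohort(cfg)
    block = expr.loc[[f"ER_SIG_{i:03d}" for i in range(1, 11)]]
    resid = block.loc[:, truth["er"] == 1]  # constant signal within group
    corr = np.corrcoef(resid.to_numpy())
    off = corr[np.triu_indices_from(corr, k=1)]
    assert off.mean() == pytest.approx(0.5, abs=0.08)


def test_marginal_prevalence_within_binomial_ci():
    cfg = small_cfg(n_samples=2000, seed=3)
    truth, *_ = generate_cohort(cfg)
    for bm, p in cfg.biomarker_prevalence.items():
        se = np.sqrt(p * (1 - p) / len(truth))
        assert abs(truth[bm].mean() - p) < 3.5 * se
    g = truth["nhg"].value_counts(normalize=True)
    for grade, p in zip(("G1", "G2", "G3"), cfg.grade_probs):
        assert abs(g.get(grade, 0.0) - p) < 4 * np.sqrt(p * (1 - p) / len(truth))


def test_latent_fraction_consistent_with_state():
    cfg = small_cfg()
    truth, *_ = generate_cohort(cfg)
    for bm in ("er", "pgr", "her2", "ki67"):
        cut = cfg.cutoff_for(bm)
        pos = truth[bm] == 1
        assert (truth.loc[pos, f"frac_{bm}"] >= cut).all()
        assert (truth.loc[~pos, f"frac_{bm}"] < cut).all()


def test_replicate_expression_same_truth_new_noise():
    cfg = small_cfg()
    truth, expr, _, _ = generate_cohort(cfg)
    rep = replicate_expression(truth, cfg)
    assert rep.shape == expr.shape
    assert not np.allclose(rep.to_numpy(), expr.to_numpy())
    # same biology: per-gene means agree within measurement noise
    d = (rep.mean(axis=1) - expr.mean(axis=1)).abs()
    assert d.max() < 1.0


# ------------------------------------------------------------------ raters


def test_zero_error_raters_match_truth_exactly():
    cfg = small_cfg(rater_error={b: 0.0 for b in ("er", "pgr", "her2", "ki67", "nhg")})
    truth, _, panel, _ = generate_cohort(cfg)
    wide = panel.pivot_table(index="sample_id", columns=["biomarker", "rater_id"], values="call", aggfunc="first")
    for bm in ("er", "pgr", "her2", "ki67"):
        want = truth[bm].map({1: "pos", 0: "neg"})
        for r in ("R1", "R2", "R3"):
            assert (wide[(bm, r)] == want).all()
    for r in ("R1", "R2", "R3"):
        assert (wide[("nhg", r)] == truth["nhg"]).all()
    assert panel_agreement(panel, "er", n_boot=20)["average_kappa"] == pytest.approx(1.0)


def test_binary_agreement_matches_closed_form():
    """Two independent ε=0.05 reads agree with probability ε²+(1−ε)²."""
    cfg = SimConfig(
        n_samples=5000,
        n_genes=104,
        rater_error={b: 0.05 for b in ("er", "pgr", "her2", "ki67", "nhg")},
        seed=17,
    )
    truth, _, panel, _ = generate_cohort(cfg)
    res = panel_agreement(panel, "er", n_boot=20, seed=0)
    assert res["average_overall_agreement"] == pytest.approx(0.905, abs=0.01)


def test_default_rater_error_hits_kappa_targets():
    """The calibrated defaults reproduce the published panel kappas."""
    cfg = SimConfig(n_samples=5000, n_genes=104, seed=29)
    truth, _, panel, _ = generate_cohort(cfg)
    targets = {"er": 0.920, "pgr": 0.891, "her2": 0.899, "ki67": 0.734, "nhg": 0.581}
    for bm, target in targets.items():
        res = panel_agreement(panel, bm, n_boot=20, seed=1)
        assert res["average_kappa"] == pytest.approx(target, abs=0.03), bm


def test_error_for_kappa_inverts_closed_form():
    probs = [0.3, 0.7]
    for target in (0.9, 0.7, 0.5):
        eps = error_for_kappa(target, probs)
        assert expected_pairwise_kappa(eps, probs) == pytest.approx(target, abs=1e-9)
    e_nhg = error_for_kappa(0.581, [0.15, 0.55, 0.30], ordinal=True)
    assert expected_pairwise_kappa(e_nhg, [0.15, 0.55, 0.30], ordinal=True) == pytest.approx(
        0.581, abs=1e-9
    )


def test_closed_form_oa_for_flip_model():
    p_o, _ = pairwise_agreement_stats(np.array([0.5, 0.5]), binary_read_matrix(0.05))
    assert p_o == pytest.approx(0.05**2 + 0.95**2, abs=1e-15)


def test_raters_reject_half_error():
    cfg = small_cfg()
    truth, *_ = generate_cohort(cfg)
    cfg.rater_error["er"] = 0.5
    with pytest.raises(ValueError, match="rater_error"):
        simulate_raters(truth, cfg)


def test_stricter_ihc_cutoff_only_removes_positives():
    cfg = small_cfg(n_samples=500)
    truth, *_ = generate_cohort(cfg)
    base = simulate_raters(truth, cfg)
    strict = simulate_raters(truth, cfg, ihc_cutoff=0.10)
    for bm in ("er", "pgr"):
        b = base[base["biomarker"] == bm].set_index(["sample_id", "rater_id"])["call"]
        s = strict[strict["biomarker"] == bm].set_index(["sample_id", "rater_id"])["call"]
        # positive at 10% implies positive at 1%; some 1%-positives may drop
        assert ((s == "pos") <= (b == "pos")).all()


# ---------------------------------------------------------------- clinical


def test_clinical_missing_consensus_lists_samples():
    cfg = small_cfg()
    truth, _, panel, _ = generate_cohort(cfg)
    cons, _ = consensus_table(panel)
    cons.loc[cons.index[0], "er"] = None
    with pytest.raises(ValueError, match=str(cons.index[0])):
        simulate_clinical(truth, cons, cfg)


def test_zero_hazard_means_all_censored():
    cfg = small_cfg(hazard_baseline=0.0)
    *_, clin = generate_cohort(cfg)
    assert clin["event"].sum() == 0
    assert (clin["time"] == cfg.censor_horizon).all()


def test_clinical_invariants():
    cfg = small_cfg(n_samples=400, seed=2)
    *_, clin = generate_cohort(cfg)
    assert (clin["time"] > 0).all() and (clin["time"] <= cfg.censor_horizon).all()
    assert set(clin["event"].unique()) <= {0, 1}
    assert set(clin["treatment"].unique()) <= {"none", "endocrine_only", "chemo_containing"}


def test_null_discordance_effect_gives_uniform_logrank_p():
    from bcmarkers.evaluation import derive_hormone_responsive
    from bcmarkers.survival import logrank_test

    pvals = []
    for seed in range(12):
        cfg = SimConfig(
            n_samples=600,
            n_genes=104,
            discordant_log_hr=0.0,
            hazard_baseline=0.01,
            rater_error={"er": 0.15, "pgr": 0.15, "her2": 0.05, "ki67": 0.2, "nhg": 0.2},
            seed=100 + seed,
        )
        truth, _, panel, clin = generate_cohort(cfg)
        cons, _ = consensus_table(panel)
        rated = derive_hormone_responsive(cons["er"], cons["pgr"]) == "pos"
        true_resp = (truth["er"] == 1) & (truth["pgr"] == 1)
        disc = (rated & ~true_resp).to_numpy()
        if disc.sum() < 5 or (~disc).sum() < 5:
            continue
        _, p = logrank_test(clin["time"], clin["event"], disc)
        pvals.append(p)
    assert len(pvals) >= 8
    assert 0.25 < np.mean(pvals) < 0.75
    assert np.mean(np.array(pvals) < 0.05) <= 0.25


def test_planted_discordance_hazard_recovered_by_cox():
    """Cox on the true discordance indicator recovers the generating
    log-HR within Monte-Carlo error."""
    from bcmarkers.survival import cox_ph

    cfg = SimConfig(
        n_samples=3000,
        n_genes=104,
        rater_error={"er": 0.15, "pgr": 0.18, "her2": 0.05, "ki67": 0.2, "nhg": 0.2},
        hazard_baseline=0.02,
        discordant_log_hr=np.log(2.64),
        seed=77,
    )
    truth, _, panel, clin = generate_cohort(cfg)
    cons, _ = consensus_table(panel)
    rated = ((cons["er"] == "pos") & (cons["pgr"] == "pos")).to_numpy()
    true_resp = ((truth["er"] == 1) & (truth["pgr"] == 1)).to_numpy()
    disc = rated & ~true_resp
    fit = cox_ph(clin["time"], clin["event"], pd.DataFrame({"disc": disc.astype(float)}))
    assert fit.params["disc"] == pytest.approx(np.log(2.64), abs=0.15)
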