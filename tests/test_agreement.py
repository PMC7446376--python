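"""Agreement statistics: hand-worked values, brute-force equivalence,
interpretation bands, consensus voting, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

from bcmarkers.agreement import (
    ContingencyTable,
    agreement_report,
    cohens_kappa,
    consensus_table,
    interpret_kappa,
    majority_consensus,
    matthews_cc,
    overall_agreement,
    panel_agreement,
    specific_agreement,
)

# ---------------------------------------------------------------- oracles


def brute_overall(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


def brute_specific(a, b, c):
    """Pair-counting: agreements on c over all mentions of c."""
    both = sum(1 for x, y in zip(a, b) if x == c and y == c)
    mentions = sum(1 for x, y in zip(a, b) if x == c) + sum(
        1 for x, y in zip(a, b) if y == c
    )
    return 2 * both / mentions if mentions else float("nan")


def brute_kappa(a, b, cats):
    n = len(a)
    p_o = brute_overall(a, b)
    p_e = sum(
        (sum(x == c for x in a) / n) * (sum(y == c for y in b) / n) for c in cats
    )
    return (p_o - p_e) / (1 - p_e) if p_e < 1 else float("nan")


def table_to_calls(t: ContingencyTable):
    a, b = [], []
    for i, ci in enumerate(t.categories):
        for j, cj in enumerate(t.categories):
            a += [ci] * int(t.counts[i, j])
            b += [cj] * int(t.counts[i, j])
    return a, b


# ---------------------------------------------------------------- examples

HAND = ContingencyTable(("pos", "neg"), [[40, 5], [10, 45]])


def test_hand_worked_binary_table():
    assert overall_agreement(HAND) == pytest.approx(0.85)
    assert cohens_kappa(HAND) == pytest.approx(0.70)
    assert specific_agreement(HAND, "pos") == pytest.approx(80 / 95)
    assert specific_agreement(HAND, "neg") == pytest.approx(90 / 105)
    assert matthews_cc(HAND) == pytest.approx(1750 / np.sqrt(45 * 55 * 50 * 50))


def test_three_class_overall_agreement():
    t = ContingencyTable(
        ("G1", "G2", "G3"), [[10, 5, 5], [5, 20, 10], [10, 5, 30]]
    )
    assert overall_agreement(t) == pytest.approx(0.60)


def test_diagonal_table_is_perfect():
    t = ContingencyTable(("a", "b"), [[7, 0], [0, 3]])
    assert overall_agreement(t) == 1.0
    assert cohens_kappa(t) == pytest.approx(1.0)
    assert specific_agreement(t, "a") == 1.0
    assert matthews_cc(t) == pytest.approx(1.0)


def test_forced_disagreement_kappa_zero():
    # one party all-positive, the other all-negative: p_o = p_e = 0
    t = ContingencyTable(("neg", "pos"), [[0, 0], [10, 0]])
    assert overall_agreement(t) == 0.0
    assert cohens_kappa(t) == pytest.approx(0.0)


def test_constant_identical_parties_not_estimable():
    t = ContingencyTable(("neg", "pos"), [[10, 0], [0, 0]])
    assert np.isnan(cohens_kappa(t))
    assert interpret_kappa(cohens_kappa(t)) == "not estimable"


def test_never_called_category_not_estimable():
    t = ContingencyTable(("a", "b", "c"), [[5, 1, 0], [2, 4, 0], [0, 0, 0]])
    assert np.isnan(specific_agreement(t, "c"))


def test_mcc_rejects_non_binary():
    t = ContingencyTable(("a", "b", "c"), np.eye(3))
    with pytest.raises(ValueError):
        matthews_cc(t)


def test_empty_table_errors():
    t = ContingencyTable(("a", "b"), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        overall_agreement(t)


# ------------------------------------------------------- brute-force sweep


def test_all_statistics_match_bruteforce_on_random_tables(rng):
    """OA, specific agreement, kappa and MCC agree with independent
    pair-counting implementations (and sklearn) on random tables."""
    for _ in range(200):
        k = rng.integers(2, 4)
        cats = tuple("ABCD"[:k])
        counts = rng.integers(0, 20, size=(k, k))
        if counts.sum() == 0:
            continue
        t = ContingencyTable(cats, counts)
        a, b = table_to_calls(t)
        assert overall_agreement(t) == pytest.approx(brute_overall(a, b), abs=1e-12)
        bk = brute_kappa(a, b, cats)
        ck = cohens_kappa(t)
        if np.isnan(bk):
            assert np.isnan(ck)
        else:
            assert ck == pytest.approx(bk, abs=1e-12)
            assert ck == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)
        for c in cats:
            bs = brute_specific(a, b, c)
            ss = specific_agreement(t, c)
            if np.isnan(bs):
                assert np.isnan(ss)
            else:
                assert ss == pytest.approx(bs, abs=1e-12)
        if k == 2:
            ia = [int(x == cats[0]) for x in a]
            ib = [int(x == cats[0]) for x in b]
            if len(set(ia)) > 1 and len(set(ib)) > 1:
                assert matthews_cc(t) == pytest.approx(
                    matthews_corrcoef(ia, ib), abs=1e-9
                )


def test_mcc_equals_pearson_of_indicators(rng):
    for _ in range(50):
        a = rng.integers(0, 2, 60)
        b = rng.integers(0, 2, 60)
        if a.std() == 0 or b.std() == 0:
            continue
        t = ContingencyTable.from_calls(a.tolist(), b.tolist(), (0, 1))
        assert matthews_cc(t) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)


def test_mcc_null_mean_near_zero(rng):
    """Random independent labels: mean MCC over replicates ≈ 0."""
    vals = []
    for _ in range(1000):
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        t = ContingencyTable.from_calls(a.tolist(), b.tolist(), (0, 1))
        vals.append(matthews_cc(t))
    assert abs(np.mean(vals)) < 0.01


@settings(deadline=None, max_examples=30)
@given(st.permutations(["a", "b", "c"]), st.integers(0, 2**31 - 1))
def test_kappa_invariant_to_category_permutation(perm, seed):
    r = np.random.default_rng(seed)
    counts = r.integers(1, 10, size=(3, 3))
    t = ContingencyTable(("a", "b", "c"), counts)
    order = [["a", "b", "c"].index(p) for p in perm]
    t2 = ContingencyTable(tuple(perm), counts[np.ix_(order, order)])
    assert cohens_kappa(t) == pytest.approx(cohens_kappa(t2), abs=1e-12)


# ------------------------------------------------------------ full report


def test_report_band_and_ci_contains_estimate():
    a, b = table_to_calls(HAND)
    rep = agreement_report(a, b, n_boot=500, seed=1)
    assert rep.interpretation == "substantial"  # kappa 0.70
    assert rep.kappa_ci[0] <= rep.kappa <= rep.kappa_ci[1]
    assert rep.overall_agreement_ci[0] <= rep.overall_agreement <= rep.overall_agreement_ci[1]
    assert rep.mcc == pytest.approx(0.7035, abs=1e-4)


def test_ci_width_shrinks_with_sample_size(rng):
    def width(n):
        a = rng.integers(0, 2, n)
        flip = rng.random(n) < 0.1
        b = np.where(flip, 1 - a, a)
        rep = agreement_report(a.tolist(), b.tolist(), n_boot=400, seed=2)
        return rep.overall_agreement_ci[1] - rep.overall_agreement_ci[0]

    assert width(1600) < width(100) / 2.5  # ~1/sqrt(n) scaling


def test_missing_calls_dropped_and_counted():
    a = ["pos", "neg", None, "pos"]
    b = ["pos", None, "neg", "pos"]
    rep = agreement_report(a, b, n_boot=50, seed=0)
    assert rep.n == 2 and rep.n_dropped == 2
    assert rep.overall_agreement == 1.0


def test_report_requires_two_usable_pairs():
    with pytest.raises(ValueError):
        agreement_report(["pos", None], ["pos", "neg"], n_boot=10)


def test_identical_raters_average_kappa_one():
    panel = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"] * 3,
            "biomarker": "er",
            "rater_id": np.repeat(["R1", "R2", "R3"], 4),
            "call": ["pos", "neg", "pos", "neg"] * 3,
        }
    )
    res = panel_agreement(panel, "er", n_boot=50)
    assert res["average_kappa"] == pytest.approx(1.0)
    assert res["average_overall_agreement"] == 1.0
    for rep in res["pairwise"]:
        assert rep.overall_agreement_ci == (1.0, 1.0)


# ---------------------------------------------------------------- consensus


def test_majority_consensus_basic_and_ties():
    panel = pd.DataFrame(
        {
            "sample_id": ["s1"] * 3 + ["s2"] * 3,
            "biomarker": "nhg",
            "rater_id": ["R1", "R2", "R3"] * 2,
            "call": ["G1", "G2", "G3", "G2", "G2", "G1"],
        }
    )
    labels, ties = majority_consensus(panel, "nhg")
    assert labels["s2"] == "G2"
    assert pd.isna(labels["s1"])
    assert ties["n_ties"] == 1 and ties["tied_samples"] == ["s1"]


def test_majority_consensus_six_readings():
    # two stains × three readers: 4 pos vs 2 neg → pos
    panel = pd.DataFrame(
        {
            "sample_id": ["s1"] * 6,
            "biomarker": "er",
            "rater_id": [f"R{i}" for i in range(1, 7)],
            "call": ["pos"] * 4 + ["neg"] * 2,
        }
    )
    labels, ties = majority_consensus(panel, "er")
    assert labels["s1"] == "pos" and ties["n_ties"] == 0


def test_consensus_table_covers_all_biomarkers(small_cohort):
    _, _, _, panel, _ = small_cohort
    cons, ties = consensus_table(panel)
    assert set(cons.columns) == {"er", "pgr", "her2", "ki67", "nhg"}
    assert len(cons) == panel["sample_id"].nunique()
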