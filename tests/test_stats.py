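"""Effect sizes, group tests, mediation, chi-square, strata, baselines, DeLong."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sexnet.metrics import compute_metrics
from sexnet.stats import (
    GroupSummary,
    agreement_groups,
    baseline_classifiers,
    chi2_test,
    cohens_d,
    delong_test,
    misclassification_chi2,
    partial_mediation,
    per_stratum_accuracy,
    score_correlations,
    summarize,
    two_sample_t,
)

# published group summaries for the seven cognitive tests (F n=3895, M n=4249)
TABLE_ROWS = {
    "flanker": ((96.29, 13.37), (97.09, 14.39), 0.058, 0.001),
    "list_sorting": ((101.68, 14.08), (102.64, 14.68), 0.067, 0.001),
    "card_sort": ((98.89, 15.07), (97.44, 15.54), 0.095, 0.001),
    "oral_reading": ((104.45, 19.53), (103.65, 18.52), 0.042, 0.001),
    "pattern_comparison": ((96.70, 20.92), (93.72, 22.18), 0.140, 0.003),
    # printed to two decimals only, so checked at half a printed unit
    "picture_sequence": ((103.47, 16.47), (100.62, 15.81), 0.18, 0.005),
}


def test_cohens_d_zero_for_equal_means():
    a = GroupSummary(10, 5.0, 1.0)
    b = GroupSummary(12, 5.0, 2.0)
    assert cohens_d(a, b) == 0.0


@pytest.mark.parametrize("row", TABLE_ROWS.items(), ids=list(TABLE_ROWS))
def test_cohens_d_reproduces_published_cognitive_effect_sizes(row):
    name, ((mf, sf), (mm, sm_), expected, tol) = row
    d = cohens_d(GroupSummary(3895, mf, sf), GroupSummary(4249, mm, sm_))
    assert d == pytest.approx(expected, abs=tol)


def test_cohens_d_summary_matches_raw_computation(rng):
    a_raw = rng.normal(0.3, 1.2, 40)
    b_raw = rng.normal(-0.1, 0.8, 55)
    d = cohens_d(summarize(a_raw), summarize(b_raw))
    sp = np.sqrt((39 * a_raw.var(ddof=1) + 54 * b_raw.var(ddof=1)) / 93)
    assert d == pytest.approx(abs(b_raw.mean() - a_raw.mean()) / sp, rel=1e-12)


def test_group_summary_validation():
    with pytest.raises(ValueError):
        GroupSummary(1, 0.0, 1.0)
    with pytest.raises(ValueError):
        cohens_d(GroupSummary(5, 0.0, 0.0), GroupSummary(5, 1.0, 1.0))


def test_two_sample_t_identical_groups():
    g = GroupSummary(10, 1.0, 1.0)
    t, p = two_sample_t(g, g)
    assert t == 0.0 and p == 1.0


def test_two_sample_t_closed_form_oracle():
    t, p = two_sample_t(GroupSummary(10, 0.0, 1.0), GroupSummary(10, 2.0, 1.0))
    assert t == pytest.approx(-4.472, abs=0.001)
    # oracle: 2 * t_18.sf(4.4721) evaluated directly
    assert p == pytest.approx(2.946e-4, rel=1e-3)


def test_t_squared_equals_anova_f(rng):
    a = rng.normal(0, 1, 15)
    b = rng.normal(0.8, 1, 12)
    t, _ = two_sample_t(summarize(a), summarize(b))
    f_stat, _ = sps.f_oneway(a, b)
    assert t**2 == pytest.approx(f_stat, rel=1e-10)


def test_correlation_of_score_with_itself_and_affine_invariance(rng):
    s = rng.uniform(0, 1, 100)
    tests = pd.DataFrame({"same": s, "affine": 3.0 * s - 7.0, "noise": rng.normal(size=100)})
    out = score_correlations(s, tests).set_index("test")
    assert out.loc["same", "r"] == pytest.approx(1.0)
    assert out.loc["affine", "r"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        score_correlations(s, pd.DataFrame({"const": np.ones(100)}))


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _full_mediation_data(n: int, rng: np.random.Generator):
    latent = rng.normal(0, 1, n)
    sex = (latent > 0).astype(float)
    scores = latent + rng.normal(0, 1, n)
    mediator = latent + rng.normal(0, 1, n)
    return sex, scores, mediator


def test_constructed_mediation_is_detected(rng):
    sex, scores, mediator = _full_mediation_data(1000, rng)
    res = partial_mediation(sex, scores, mediator, n_perm=1000, seed=0)
    assert res.verdict
    assert res.condition3_p < 0.01


def test_mediation_permutation_p_is_bit_reproducible(rng):
    sex, scores, mediator = _full_mediation_data(300, rng)
    a = partial_mediation(sex, scores, mediator, n_perm=500, seed=9)
    b = partial_mediation(sex, scores, mediator, n_perm=500, seed=9)
    assert a.condition3_p == b.condition3_p
    assert a.statistic == b.statistic


def test_pre_permuted_mediator_is_not_extreme_in_its_own_null(rng):
    sex, scores, mediator = _full_mediation_data(400, rng)
    shuffled = rng.permutation(mediator)
    res = partial_mediation(sex, scores, shuffled, n_perm=1000, seed=1)
    assert 0.025 <= res.condition3_p  # not in the null's upper tail
    with pytest.raises(ValueError):
        partial_mediation(sex, scores, np.ones_like(scores))


# ---------------------------------------------------------------------------
# chi-square and strata
# ---------------------------------------------------------------------------


def test_chi2_hand_computed_contingency_oracle():
    chi2, p, dof = chi2_test(np.array([[30, 10], [10, 30]]))
    assert chi2 == pytest.approx(20.0, abs=1e-9)
    assert p == pytest.approx(7.7e-6, rel=0.05)
    assert dof == 1


def test_chi2_matches_textbook_formula_on_random_tables(rng):
    for _ in range(20):
        table = rng.integers(1, 40, size=(rng.integers(2, 5), 2)).astype(float)
        chi2, p, dof = chi2_test(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum(), rel=1e-12)
        ref_chi2, ref_p, ref_dof, _ = sps.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref_chi2, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-8)


def test_chi2_scaling_property():
    table = np.array([[12, 5], [7, 16]], dtype=float)
    c1, _, _ = chi2_test(table)
    c2, _, _ = chi2_test(2 * table)
    assert c2 == pytest.approx(2 * c1, rel=1e-12)


def test_identical_pds_distributions_give_null_chi2():
    rec = pd.DataFrame({"sex": [1] * 40 + [0] * 40, "pds_level": [1, 2] * 40})
    out = misclassification_chi2(rec, rec.copy())
    for grp in ("girls", "boys"):
        assert out[grp]["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out[grp]["p"] == pytest.approx(1.0)


def test_sparse_pds_levels_are_pooled():
    correct = pd.DataFrame({"sex": [1] * 60, "pds_level": [1] * 40 + [2] * 19 + [5]})
    wrong = pd.DataFrame({"sex": [1] * 6, "pds_level": [1, 1, 2, 2, 2, 2]})
    with pytest.warns(UserWarning, match="pooling"):
        out = misclassification_chi2(correct, wrong)
    assert np.isfinite(out["girls"]["chi2"])


def test_agreement_groups_and_misclassification_flow(rng):
    records = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(8)],
            "sex": [1, 1, 1, 1, 0, 0, 0, 0],
            "pds_level": [3, 3, 1, 1, 1, 1, 3, 3],
        }
    )
    run1 = pd.DataFrame({"subject_id": records.subject_id, "correct": [1, 1, 0, 0, 1, 1, 0, 0]})
    run2 = run1.copy()
    run2.loc[1, "correct"] = 0  # mixed outcome -> excluded from both groups
    good, bad = agreement_groups([run1, run2], records)
    assert list(good["subject_id"]) == ["s0", "s4", "s5"]
    assert list(bad["subject_id"]) == ["s2", "s3", "s6", "s7"]


def test_per_stratum_accuracy_counting_oracle():
    pred = pd.DataFrame(
        {
            "sex": [1] * 10 + [0] * 10 + [1] * 10 + [0] * 10,
            "pds_level": [1] * 20 + [2] * 20,
            "correct": [1] * 9 + [0] + [1] * 9 + [0] + [1] * 7 + [0] * 3 + [1] * 7 + [0] * 3,
        }
    )
    out = per_stratum_accuracy(pred, min_per_sex=5).set_index("stratum")
    assert out.loc[1, "accuracy"] == pytest.approx(0.9)
    assert out.loc[2, "accuracy"] == pytest.approx(0.7)


def test_stratum_with_one_sex_missing_is_excluded():
    pred = pd.DataFrame(
        {"sex": [1] * 12, "pds_level": [4] * 12, "correct": [1] * 12}
    )
    assert per_stratum_accuracy(pred, min_per_sex=5).empty


def test_all_correct_gives_unit_accuracy_everywhere():
    pred = pd.DataFrame(
        {"sex": [1, 0] * 10, "pds_level": [1] * 10 + [2] * 10, "correct": [1] * 20}
    )
    out = per_stratum_accuracy(pred, min_per_sex=2)
    assert (out["accuracy"] == 1.0).all()


# ---------------------------------------------------------------------------
# baselines and DeLong
# ---------------------------------------------------------------------------


def test_baselines_learn_a_separable_feature(rng):
    labels = np.array([1, 0] * 40)
    feats = labels[:, None] + rng.normal(0, 0.01, (80, 3))
    out = baseline_classifiers(feats, labels, k=5, seed=0)
    for name, (_, report) in out.items():
        assert report.balanced_accuracy > 0.99, name


def test_baselines_at_chance_under_permuted_labels(rng):
    labels = np.array([1, 0] * 60)
    feats = rng.normal(size=(120, 5))
    out = baseline_classifiers(feats, labels, k=5, seed=0)
    for name, (_, report) in out.items():
        assert abs(report.auc - 0.5) < 0.15, name


def test_constant_feature_columns_are_dropped(rng):
    labels = np.array([1, 0] * 30)
    feats = np.column_stack([labels + rng.normal(0, 0.01, 60), np.full(60, 3.0)])
    with pytest.warns(UserWarning, match="constant"):
        out = baseline_classifiers(feats, labels, k=3, seed=0, methods=("logistic_regression",))
    assert out["logistic_regression"][1].balanced_accuracy > 0.9


def test_delong_identical_scores_is_exact_null(rng):
    labels = np.array([1, 0] * 15)
    s = rng.uniform(0, 1, 30)
    z, p = delong_test(s, s.copy(), labels)
    assert z == 0.0 and p == 1.0


def test_delong_detects_a_clearly_better_model(rng):
    labels = np.array([1, 0] * 50)
    good = labels + rng.normal(0, 0.3, 100)
    bad = rng.normal(size=100)
    z, p = delong_test(good, bad, labels)
    assert z > 0 and p < 1e-4


def test_delong_auc_is_consistent_with_metrics(rng):
    labels = np.array([1, 0] * 20)
    a = rng.uniform(0, 1, 40)
    b = rng.uniform(0, 1, 40)
    # swapping the arguments flips the sign but keeps the magnitude
    z_ab, p_ab = delong_test(a, b, labels)
    z_ba, p_ba = delong_test(b, a, labels)
    assert z_ab == pytest.approx(-z_ba, rel=1e-12)
    assert p_ab == pytest.approx(p_ba, rel=1e-12)
    rep_a = compute_metrics(a, labels)
    rep_b = compute_metrics(b, labels)
    # z must have the sign of the AUC difference computed by the metrics path
    assert np.sign(z_ab) == np.sign(rep_a.auc - rep_b.auc)
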