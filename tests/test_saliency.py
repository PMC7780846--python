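"""GLM screening, masked-gradient saliency, ROI statistics, thresholding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import sexnet as sx
from sexnet.model import ModelConfig, SexNet
from sexnet.saliency import (
    CONFOUNDERS,
    SaliencyMap,
    ScreenResult,
    cohort_pattern,
    compute_saliency,
    roi_statistics,
    saliency_maps,
    screen_predictors,
    threshold_pattern,
)
from sexnet.types import Atlas


def _linear_toy(classifier_weights: np.ndarray) -> SexNet:
    """A model whose logit is an exact average-pool linear functional.

    The single conv kernel is an identity (centre tap 1), so with positive
    input each predictor is the mean of its 2^3 cell and the logit is
    sum_c w_c * P_c.  The input gradient is then w_c / 8 at every voxel of
    cell c -- an analytic oracle.
    """
    cfg = ModelConfig(grid=8, conv_channels=(1,), predictor_channels=1, hidden=(), seed=0)
    model = SexNet(cfg)
    conv = model.extractor.layers[0]
    conv.w[...] = 0.0
    conv.w[0, 0, 1, 1, 1] = 1.0
    conv.b[...] = 0.0
    model.predictor_layer.w[...] = 1.0
    model.predictor_layer.b[...] = 0.0
    clf = model.classifier.layers[-1]
    clf.w[...] = classifier_weights.reshape(-1, 1).astype(np.float32)
    clf.b[...] = 0.0
    return model


def _cell_of_voxel(i: int, j: int, k: int) -> int:
    return (i // 2) * 16 + (j // 2) * 4 + (k // 2)


def test_linear_toy_gradient_matches_analytic_weights(rng):
    w = rng.normal(size=64).astype(np.float32)
    model = _linear_toy(w)
    x = rng.uniform(0.5, 1.5, size=(1, 8, 8, 8)).astype(np.float32)  # positive
    grad = model.input_gradient(x)
    for _ in range(20):
        i, j, k = rng.integers(0, 8, 3)
        assert grad[0, i, j, k] == pytest.approx(w[_cell_of_voxel(i, j, k)] / 8.0, rel=1e-4)


def test_masking_predictors_zeroes_their_receptive_fields(rng):
    w = rng.uniform(0.5, 1.0, size=64).astype(np.float32)
    model = _linear_toy(w)
    x = rng.uniform(0.5, 1.5, size=(1, 8, 8, 8)).astype(np.float32)
    mask = np.zeros(64, dtype=bool)
    mask[:32] = True  # cells in the lower half of the LR axis
    grad = model.input_gradient(x, predictor_mask=mask)
    assert np.all(grad[0, 4:] == 0.0)  # excluded branch contributes nothing
    assert np.all(np.abs(grad[0, :4]) > 0.0)


def test_mask_union_never_shrinks_total_saliency(rng):
    # non-negative weights and positive input give non-negative path products
    w = rng.uniform(0.1, 1.0, size=64).astype(np.float32)
    model = _linear_toy(w)
    x = rng.uniform(0.5, 1.5, size=(1, 8, 8, 8)).astype(np.float32)
    mask_a = np.zeros(64, dtype=bool)
    mask_a[:16] = True
    mask_ab = mask_a.copy()
    mask_ab[16:32] = True
    tot_a = np.abs(model.input_gradient(x, mask_a)).sum()
    tot_ab = np.abs(model.input_gradient(x, mask_ab)).sum()
    assert tot_ab >= tot_a


def test_saliency_of_symmetric_input_is_mirror_symmetric():
    # per-subject maps average native and mirrored-back flipped gradients,
    # so a mirror-symmetric input yields a mirror-symmetric map
    model = SexNet(ModelConfig(grid=16, seed=1))
    from sexnet.synthetic import make_template

    sal = saliency_maps(model, make_template(16)[None])[0]
    np.testing.assert_allclose(sal, np.flip(sal, axis=0), atol=1e-5)


def test_maps_are_minmax_scaled_or_zero():
    model = SexNet(ModelConfig(grid=16, seed=2))
    x = np.random.default_rng(0).normal(size=(4, 16, 16, 16)).astype(np.float32)
    maps = saliency_maps(model, x)
    for m in maps:
        assert m.min() == 0.0 and m.max() == pytest.approx(1.0)
    # constant map (all classifier weights zero -> zero gradient) becomes all zeros
    zero_model = SexNet(ModelConfig(grid=16, seed=3))
    for layer in zero_model.classifier.layers:
        for p in layer.params:
            p[...] = 0.0
    zmaps = saliency_maps(zero_model, x[:1])
    assert np.all(zmaps == 0.0)


def test_compute_saliency_rejects_empty_mask(trained_tiny_model, sex_effect_cohort):
    with pytest.raises(ValueError):
        compute_saliency(
            trained_tiny_model,
            sex_effect_cohort.volumes[0],
            predictor_mask=np.zeros(trained_tiny_model.m, dtype=bool),
        )


# ---------------------------------------------------------------------------
# GLM screen
# ---------------------------------------------------------------------------


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "z_pds": rng.normal(size=n),
            "z_age": rng.normal(size=n),
            "z_ses": rng.normal(size=n),
        }
    )


def test_screen_flags_an_age_driven_predictor(rng):
    n = 500
    cov = _covariates(n, rng)
    s = rng.uniform(0, 1, n)
    p_conf = 2.0 * cov["z_age"].to_numpy() + rng.normal(0, 0.1, n)
    p_clean = rng.normal(size=n)
    res = screen_predictors(np.column_stack([p_conf, p_clean]), s, cov)
    assert res.confounded[0]
    assert res.pvalues[0, CONFOUNDERS.index("age")] < 1e-10
    assert res.attribution[0] == "age"


def test_screen_does_not_flag_a_pure_score_predictor(rng):
    n = 500
    cov = _covariates(n, rng)
    s = rng.uniform(0, 1, n)
    res = screen_predictors(s[:, None].copy(), s, cov)
    assert not res.confounded[0]
    assert res.beta[0, 1] == pytest.approx(1.0, abs=1e-6)  # coefficient on S


def test_screen_agrees_with_statsmodels_ols(rng):
    n = 120
    cov = _covariates(n, rng)
    s = rng.uniform(0, 1, n)
    p = rng.normal(size=(n, 3))
    res = screen_predictors(p, s, cov)
    design = sm.add_constant(
        np.column_stack([s, cov["z_pds"], cov["z_age"], cov["z_ses"]])
    )
    for j in range(3):
        fit = sm.OLS(p[:, j], design).fit()
        np.testing.assert_allclose(res.beta[j], fit.params, rtol=1e-8)
        np.testing.assert_allclose(res.pvalues[j], fit.pvalues[2:], rtol=1e-8)


def test_screen_rejects_degenerate_designs(rng):
    cov = _covariates(50, rng)
    cov["z_ses"] = 0.0
    with pytest.raises(np.linalg.LinAlgError, match="z_ses"):
        screen_predictors(rng.normal(size=(50, 2)), rng.uniform(0, 1, 50), cov)
    with pytest.raises(ValueError):
        screen_predictors(rng.normal(size=(4, 2)), rng.uniform(0, 1, 4), _covariates(4, rng))


def test_screen_result_frame_roundtrip(rng):
    cov = _covariates(60, rng)
    res = screen_predictors(rng.normal(size=(60, 4)), rng.uniform(0, 1, 60), cov)
    frame = res.to_frame()
    assert len(frame) == 4
    assert (frame["confounded"] == res.confounded).all()


def test_all_flagged_gives_diagnostic_error(trained_tiny_model, sex_effect_cohort):
    m = trained_tiny_model.m
    screen = ScreenResult(
        beta=np.zeros((m, 5)),
        pvalues=np.full((m, 3), 1e-6),
        confounded=np.ones(m, dtype=bool),
        attribution=np.array(["pds"] * m),
        alpha=0.05,
    )
    with pytest.raises(ValueError, match="confounder-free"):
        cohort_pattern(
            trained_tiny_model, sex_effect_cohort.volumes[:4], screen, "confounder_free"
        )
    with pytest.raises(ValueError):
        cohort_pattern(
            trained_tiny_model, sex_effect_cohort.volumes[:4], screen, "not_a_mode"
        )


def test_free_and_all_predictor_patterns_agree_without_confounding():
    """With only a sex effect simulated, the confounder-free pattern and the
    unmasked (all-predictor) pattern are nearly identical; chance flags at
    the lenient alpha perturb the correlation slightly below unity."""
    import sexnet as sx
    from sexnet.model import cohort_predictors, fit_full, subject_scores

    cohort = sx.generate_cohort(
        n=200, grid=16, effects=[sx.EffectSpec(1, "intensity_shift", "sex", 5.0)], seed=50
    )
    cfg = sx.ModelConfig(grid=16, epochs=6, seed=50)
    model = fit_full(cohort, cfg)
    scores = subject_scores(model, cohort.volumes)["score"].to_numpy()
    screen = screen_predictors(
        cohort_predictors(model, cohort.volumes), scores, cohort.records
    )
    free = cohort_pattern(model, cohort.volumes, screen, mode="confounder_free").data
    unmasked = saliency_maps(model, cohort.volumes, None).mean(axis=0)
    r = np.corrcoef(free.ravel(), unmasked.ravel())[0, 1]
    assert r > 0.9


# ---------------------------------------------------------------------------
# ROI statistics and thresholding
# ---------------------------------------------------------------------------


def test_identical_maps_give_null_roi_table():
    atlas = sx.make_atlas(16)
    maps = np.tile(np.random.default_rng(0).uniform(size=(16, 16, 16)), (10, 1, 1, 1))
    sex = np.array([1] * 5 + [0] * 5)
    table = roi_statistics(maps, atlas, sex)
    assert (table["t"] == 0.0).all()
    assert (table["p_bonferroni"] == 1.0).all()


def test_injected_group_difference_found_only_in_target_roi(rng):
    atlas = sx.make_atlas(16)
    n = 200
    sex = np.array([1, 0] * (n // 2))
    maps = rng.normal(0.5, 0.05, size=(n, 16, 16, 16)).astype(np.float32)
    roi2 = atlas.labels == 2
    maps[sex == 1] += 0.3 * roi2  # girls carry extra saliency in ROI 2
    table = roi_statistics(maps, atlas, sex).set_index("roi")
    assert table.loc[2, "p_bonferroni"] < 0.05
    others = table.drop(index=2)
    assert (others["p_bonferroni"] > 0.05).all()
    assert table["rank"].loc[2] == 1  # ROI 2 also tops the saliency ranking


def test_bonferroni_is_min_of_one_and_raw_times_n(rng):
    atlas = sx.make_atlas(16)
    maps = rng.uniform(size=(12, 16, 16, 16))
    sex = np.array([1, 0] * 6)
    table = roi_statistics(maps, atlas, sex)
    np.testing.assert_allclose(
        table["p_bonferroni"], np.minimum(1.0, table["p_raw"] * len(table))
    )


def test_empty_roi_is_excluded_with_warning():
    atlas = sx.make_atlas(16)
    regions = dict(atlas.regions)
    regions[9] = ([], 1.0)  # declared but has no voxels
    bad = Atlas(labels=atlas.labels, regions=regions)
    maps = np.random.default_rng(0).uniform(size=(6, 16, 16, 16))
    sex = np.array([1, 0, 1, 0, 1, 0])
    with pytest.warns(UserWarning, match="ROI 9"):
        table = roi_statistics(maps, bad, sex)
    assert 9 not in set(table["roi"])


def test_threshold_pattern_limits():
    data = np.random.default_rng(0).uniform(size=(8, 8, 8)).astype(np.float32)
    pattern = SaliencyMap(data=data)
    assert threshold_pattern(pattern, 0.0).sum() == (data > 0).sum()
    assert threshold_pattern(pattern, 1.0).sum() == 0
    uniform = SaliencyMap(data=np.full((8, 8, 8), 0.5, dtype=np.float32))
    assert threshold_pattern(uniform, 0.1).sum() == 8**3
    with pytest.raises(ValueError):
        threshold_pattern(pattern, 1.5)
    with pytest.raises(ValueError):
        threshold_pattern(np.array([[[2.0]]]), 0.5)
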