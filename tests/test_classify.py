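import numpy as np
import pytest

from netmig import (
    ModelSpec,
    SynthConfig,
    aggregate_by_network,
    crossval_classify,
    directional_importance,
    generate_cohort,
    tune_hyperparameters,
)
from netmig.classify import (
    FeatureImportanceTable,
    build_feature_matrix,
    fit_full_model,
    shap_attributions,
)
from netmig.connectivity import N_PAIR_FEATURES
from netmig.errors import StratificationError, RegionLookupError, ValidationError

FAST = ModelSpec(learning_rate=0.3, max_tree_depth=2, n_estimators=10, seed=0)


@pytest.fixture(scope="module")
def planted_cohort(atlas):
    """Strong within-Language planted pair effect at default noise: the
    planted pair is the single dominant separating feature."""
    cfg = SynthConfig(
        n_patients=14, n_controls=10, n_timepoints=120,
        fc_effects=[("L_45", "L_44", -0.8)], include_structural=False, seed=31,
    )
    return generate_cohort(cfg, atlas)


def test_feature_matrix_shape_and_sex_column(small_cohort):
    X, y, ids = build_feature_matrix(small_cohort)
    assert X.shape == (14, N_PAIR_FEATURES + 1)
    assert set(np.unique(X[:, -1])) <= {0.0, 1.0}
    assert y.sum() == 8  # patients coded 1
    assert len(ids) == 14


def test_crossval_uses_five_stratified_folds(small_cohort):
    res = crossval_classify(small_cohort, FAST)
    assert len(res.fold_aucs) == 5
    assert res.mean_auc == pytest.approx(np.mean(res.fold_aucs))
    # folds partition the subjects exactly once
    all_test = np.concatenate(res.fold_test_indices)
    assert sorted(all_test) == list(range(14))


def test_crossval_deterministic(small_cohort):
    a = crossval_classify(small_cohort, FAST)
    b = crossval_classify(small_cohort, FAST)
    np.testing.assert_array_equal(a.fold_aucs, b.fold_aucs)


def test_stratification_error_when_class_too_small(atlas):
    cfg = SynthConfig(n_patients=8, n_controls=3, n_timepoints=20,
                      include_structural=False, seed=1)
    ds = generate_cohort(cfg, atlas)
    with pytest.raises((StratificationError, ValueError)):
        crossval_classify(ds, FAST)


def test_separable_planted_effect_yields_high_auc(atlas):
    """A strong planted effect with quiet noise at the study's sample
    size is nearly separable: mean CV AUC reaches 0.95."""
    aucs = []
    for seed in (0, 1):
        cfg = SynthConfig(
            noise_sd=0.3, fc_effects=[("L_45", "L_44", -0.8)],
            include_structural=False, seed=seed,
        )
        ds = generate_cohort(cfg, atlas)
        aucs.append(crossval_classify(ds).mean_auc)
    assert np.mean(aucs) >= 0.95


def test_tune_singleton_grid_returns_it(small_cohort):
    out = tune_hyperparameters(small_cohort, [FAST], default_spec=FAST)
    assert out.best_spec == FAST
    assert out.best_result.mean_auc == out.default_result.mean_auc


def test_tune_grid_with_default_never_worse(small_cohort):
    grid = [FAST, ModelSpec(learning_rate=0.1, max_tree_depth=3, n_estimators=10, seed=1)]
    out = tune_hyperparameters(small_cohort, grid, default_spec=FAST)
    assert out.best_result.mean_auc >= out.default_result.mean_auc


def test_tune_deterministic(small_cohort):
    grid = [FAST, ModelSpec(learning_rate=0.05, max_tree_depth=2, n_estimators=10, seed=2)]
    a = tune_hyperparameters(small_cohort, grid)
    b = tune_hyperparameters(small_cohort, grid)
    assert a.best_spec == b.best_spec
    np.testing.assert_array_equal(a.best_result.fold_aucs, b.best_result.fold_aucs)


def test_empty_grid_rejected(small_cohort):
    with pytest.raises(ValidationError):
        tune_hyperparameters(small_cohort, [])


def test_attribution_additivity(planted_cohort):
    """Per-subject attributions sum to the model margin (base included)."""
    import xgboost as xgb

    booster, X, y, _ = fit_full_model(planted_cohort, FAST)
    contribs = shap_attributions(booster, X)
    margins = booster.predict(xgb.DMatrix(X), output_margin=True)
    np.testing.assert_allclose(contribs.sum(axis=1), margins, atol=1e-4)


def test_directional_importance_top20_and_planted_pair(planted_cohort):
    imp = directional_importance(planted_cohort, FAST)
    top = imp.top()
    assert len(top) == 20
    assert top.iloc[0].magnitude == imp.magnitudes.max()
    # the planted pair dominates, with the negative direction of a
    # lowered-in-patients coupling
    row = top.iloc[0]
    assert {row.region_a, row.region_b} == {"L_44", "L_45"}
    assert row.direction == -1
    with pytest.raises(ValidationError):
        imp.top(N_PAIR_FEATURES + 1)


def test_network_aggregation_rules(atlas):
    ia_names = ["L_45", "L_45", "L_V1"]
    ib_names = ["L_44", "L_23c", "R_V1"]
    imp = FeatureImportanceTable(
        magnitudes=np.array([2.0, 1.0, 0.5]),
        directions=np.array([-1, -1, 1], dtype=np.int8),
        region_a=ia_names,
        region_b=ib_names,
        sex_magnitude=0.0,
        base_value=0.0,
    )
    table = aggregate_by_network(imp, atlas).table
    # each feature credits both endpoints in full; network value is the
    # mean over member regions
    langs = table.set_index("network")["mean_importance"]
    assert langs["Language"] == pytest.approx((2.0 + 2.0 + 1.0) / 15)
    assert langs["Salience"] == pytest.approx(1.0 / 26)
    assert langs["Visual"] == pytest.approx((0.5 + 0.5) / 48)
    assert langs["DMN"] == 0.0


def test_network_aggregation_zero_case(atlas):
    from netmig.connectivity import pair_names

    ra, rb = pair_names(atlas)
    imp = FeatureImportanceTable(
        magnitudes=np.zeros(N_PAIR_FEATURES),
        directions=np.zeros(N_PAIR_FEATURES, dtype=np.int8),
        region_a=ra,
        region_b=rb,
        sex_magnitude=0.0,
        base_value=0.0,
    )
    table = aggregate_by_network(imp, atlas).table
    assert (table["mean_importance"] == 0).all()


def test_network_aggregation_unknown_region(atlas):
    imp = FeatureImportanceTable(
        magnitudes=np.array([1.0]),
        directions=np.array([1], dtype=np.int8),
        region_a=["L_Atlantis"],
        region_b=["L_45"],
        sex_magnitude=0.0,
        base_value=0.0,
    )
    with pytest.raises(RegionLookupError):
        aggregate_by_network(imp, atlas)


def test_planted_language_pair_tops_network_table(planted_cohort, atlas):
    imp = directional_importance(planted_cohort, FAST)
    net = aggregate_by_network(imp, atlas)
    assert net.top_network() == "Language"
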