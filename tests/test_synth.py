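import numpy as np
import pytest

from netmig import (
    SynthConfig,
    expected_pair_correlation,
    generate_cohort,
    generate_structural_connectome,
    read_cohort,
    write_cohort,
)
from netmig.errors import ValidationError


def test_default_cohort_counts_and_sex_split(atlas):
    ds = generate_cohort(SynthConfig(n_timepoints=20, include_structural=False), atlas)
    patients, controls = ds.patients, ds.controls
    assert (len(patients), len(controls)) == (31, 17)
    assert sum(1 for s in patients if s.sex == "F") == 26
    assert sum(1 for s in controls if s.sex == "F") == 8


def test_same_seed_bit_identical(atlas):
    cfg = dict(n_patients=3, n_controls=3, n_timepoints=30, seed=5)
    a = generate_cohort(SynthConfig(**cfg), atlas)
    b = generate_cohort(SynthConfig(**cfg), atlas)
    for sa, sb in zip(a.subjects, b.subjects):
        np.testing.assert_array_equal(sa.timeseries, sb.timeseries)
        np.testing.assert_array_equal(sa.structural.weights, sb.structural.weights)
        assert (sa.sex, sa.age_years) == (sb.sex, sb.age_years)


def test_group_substreams_independent(atlas):
    """Growing one group never changes the other group's draws."""
    small = generate_cohort(
        SynthConfig(n_patients=2, n_controls=3, n_timepoints=30, seed=9,
                    include_structural=False), atlas,
    )
    big = generate_cohort(
        SynthConfig(n_patients=6, n_controls=3, n_timepoints=30, seed=9,
                    include_structural=False), atlas,
    )
    for sa, sb in zip(small.controls, big.controls):
        np.testing.assert_array_equal(sa.timeseries, sb.timeseries)


def test_unknown_effect_region_rejected(atlas):
    cfg = SynthConfig(fc_effects=[("L_45", "L_NotReal", -0.4)])
    with pytest.raises(Exception):
        generate_cohort(cfg, atlas)


def test_nonpositive_hub_factor_rejected():
    with pytest.raises(ValidationError):
        SynthConfig(hub_effects=[("R_Amygdala", 0.0)])


def test_planted_fc_effect_matches_analytic_oracle(atlas):
    """Group-mean FC at the planted pair tracks the model's closed form.

    Monte-Carlo estimate over 200 subjects per group against the analytic
    correlation of the generative model.
    """
    cfg = SynthConfig(
        n_patients=200, n_controls=200, n_timepoints=240,
        fc_effects=[("L_45", "L_23c", -0.4)], include_structural=False, seed=21,
    )
    ds = generate_cohort(cfg, atlas)
    ia, ib = atlas.index_of("L_45"), atlas.index_of("L_23c")

    def mean_r(subjects):
        rs = [np.corrcoef(s.timeseries[:, ia], s.timeseries[:, ib])[0, 1]
              for s in subjects]
        return float(np.mean(rs))

    pat, ctl = mean_r(ds.patients), mean_r(ds.controls)
    exp_pat = expected_pair_correlation(cfg, atlas, "L_45", "L_23c", "patient")
    exp_ctl = expected_pair_correlation(cfg, atlas, "L_45", "L_23c", "control")
    assert exp_pat == pytest.approx(-0.4 / 2.04, abs=1e-12)
    assert exp_ctl == 0.0
    assert pat == pytest.approx(exp_pat, abs=0.02)
    assert ctl == pytest.approx(exp_ctl, abs=0.02)
    assert pat < ctl


def test_effect_monotonicity(atlas):
    """Larger |delta| widens the group FC gap at the planted pair."""
    gaps = []
    for delta in (-0.2, -0.4, -0.8):
        cfg = SynthConfig(
            n_patients=40, n_controls=40, n_timepoints=120,
            fc_effects=[("L_45", "L_23c", delta)], include_structural=False, seed=3,
        )
        ds = generate_cohort(cfg, atlas)
        ia, ib = atlas.index_of("L_45"), atlas.index_of("L_23c")

        def mean_r(subjects):
            return np.mean([
                np.corrcoef(s.timeseries[:, ia], s.timeseries[:, ib])[0, 1]
                for s in subjects
            ])

        gaps.append(abs(mean_r(ds.patients) - mean_r(ds.controls)))
    assert gaps[0] < gaps[1] < gaps[2]


def test_null_cohort_group_difference_is_exchangeable(atlas):
    """Without planted effects the group-mean FC difference looks like a
    label permutation draw (within the central 95% of the null)."""
    cfg = SynthConfig(n_patients=12, n_controls=12, n_timepoints=60,
                      include_structural=False, seed=17)
    ds = generate_cohort(cfg, atlas)
    ia, ib = atlas.index_of("L_45"), atlas.index_of("L_23c")
    rs = np.array([
        np.corrcoef(s.timeseries[:, ia], s.timeseries[:, ib])[0, 1]
        for s in ds.subjects
    ])
    labels = np.array([s.group == "patient" for s in ds.subjects])
    observed = rs[labels].mean() - rs[~labels].mean()
    rng = np.random.default_rng(0)
    null = np.array([
        rs[p].mean() - rs[~p].mean()
        for p in (rng.permutation(labels) for _ in range(500))
    ])
    lo, hi = np.percentile(null, [2.5, 97.5])
    assert lo <= observed <= hi


def test_structural_connectome_invariants(atlas):
    cfg = SynthConfig(seed=2)
    sc = generate_structural_connectome(cfg, "control", atlas)
    w = sc.weights
    assert w.shape == (379, 379)
    np.testing.assert_array_equal(w, w.T)
    assert (np.diag(w) == 0).all()
    assert (w >= 0).all()
    assert w.sum() % 1 == 0  # integer streamline counts
    # apportioned rounding keeps the unique-pair total exact, well inside
    # the +/-379 rounding slack the contract allows
    assert sc.total_streamlines == 300_000


def test_hub_effect_raises_node_strength(atlas):
    """Planted 1.5x boost lifts the region's expected patient strength.

    Monte-Carlo over 100 draws per group.
    """
    cfg = SynthConfig(hub_effects=[("R_Amygdala", 1.5)], seed=4)
    i = atlas.index_of("R_Amygdala")
    pat = np.mean([
        generate_structural_connectome(cfg, "patient", atlas, k).node_strength()[i]
        for k in range(100)
    ])
    ctl = np.mean([
        generate_structural_connectome(cfg, "control", atlas, k).node_strength()[i]
        for k in range(100)
    ])
    assert pat > ctl * 1.1


def test_cohort_io_roundtrip(atlas, tmp_path):
    cfg = SynthConfig(n_patients=2, n_controls=2, n_timepoints=20, seed=8)
    ds = generate_cohort(cfg, atlas)
    write_cohort(ds, tmp_path / "cohort")
    back = read_cohort(tmp_path / "cohort")
    assert back.atlas == atlas
    assert [s.subject_id for s in back.subjects] == [s.subject_id for s in ds.subjects]
    for sa, sb in zip(ds.subjects, back.subjects):
        np.testing.assert_allclose(sb.timeseries, sa.timeseries, atol=1e-8)
        np.testing.assert_array_equal(sb.structural.weights, sa.structural.weights)
        assert (sa.sex, sa.age_years, sa.group) == (sb.sex, sb.age_years, sb.group)


def test_config_yaml_roundtrip(tmp_path):
    cfg = SynthConfig(fc_effects=[("L_45", "L_23c", -0.4)],
                      hub_effects=[("R_Amygdala", 1.5)], seed=77)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert SynthConfig.from_yaml(path) == cfg
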