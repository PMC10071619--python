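import json

import numpy as np
import pytest

from netmig import ModelSpec, RunConfig, SynthConfig, demographics_table, generate_cohort, run_pipeline
from netmig.errors import PipelineStageError, ValidationError
from netmig.synth import CohortDataset, SubjectRecord


def _subject(i, group, sex, age):
    return SubjectRecord(subject_id=f"{group}{i}", group=group, sex=sex, age_years=age)


def test_sex_chi_squared_matches_expected_counts_oracle(atlas):
    """26F/5M vs 8F/9M: the uncorrected statistic equals the explicit
    (O-E)^2/E computation on the 2x2 table."""
    subjects = (
        [_subject(i, "patient", "F", 25) for i in range(26)]
        + [_subject(i + 26, "patient", "M", 25) for i in range(5)]
        + [_subject(i, "control", "F", 26) for i in range(8)]
        + [_subject(i + 8, "control", "M", 26) for i in range(9)]
    )
    table = demographics_table(CohortDataset(subjects=subjects, atlas=atlas))
    obs = np.array([[26, 5], [8, 9]], dtype=float)
    row, col, n = obs.sum(1), obs.sum(0), obs.sum()
    expected = np.outer(row, col) / n
    chi2 = ((obs - expected) ** 2 / expected).sum()
    got = table[table["test"] == "chi-squared (uncorrected)"].iloc[0]
    assert got["statistic"] == pytest.approx(chi2, abs=1e-10)
    yates = table[table["test"] == "chi-squared (Yates-corrected)"].iloc[0]
    chi2_yates = (((np.abs(obs - expected) - 0.5) ** 2) / expected).sum()
    assert yates["statistic"] == pytest.approx(chi2_yates, abs=1e-10)
    assert yates["statistic"] < got["statistic"]


def test_identical_age_distributions_null_p(atlas):
    ages = [20, 22, 24, 26, 28, 30]
    subjects = [_subject(i, "patient", "F", a) for i, a in enumerate(ages)] + [
        _subject(i, "control", "M", a) for i, a in enumerate(ages)
    ]
    table = demographics_table(CohortDataset(subjects=subjects, atlas=atlas))
    age_row = table[table["variable"] == "age_years"].iloc[0]
    assert age_row["p_value"] > 0.9


def test_constant_variable_skipped_with_notice(atlas):
    subjects = [_subject(i, "patient", "F", 25) for i in range(4)] + [
        _subject(i, "control", "F", 25) for i in range(4)
    ]
    table = demographics_table(CohortDataset(subjects=subjects, atlas=atlas))
    age_row = table[table["variable"] == "age_years"].iloc[0]
    assert "skipped" in age_row["note"]


def test_empty_group_rejected(atlas):
    subjects = [_subject(i, "patient", "F", 25) for i in range(4)]
    with pytest.raises(ValidationError):
        demographics_table(CohortDataset(subjects=subjects, atlas=atlas))


def _tiny_run_config(tmp_path, **kwargs):
    synth = SynthConfig(
        n_patients=8, n_controls=6, n_timepoints=40,
        fc_effects=[("L_45", "L_44", -0.8)],
        include_structural=kwargs.pop("include_structural", True),
        seed=0,
    )
    fast = ModelSpec(learning_rate=0.3, max_tree_depth=2, n_estimators=10, seed=0)
    return RunConfig(
        out_dir=tmp_path,
        seed=5,
        synth=synth,
        grid=[fast],
        untuned_spec=fast,
        **kwargs,
    )


def test_run_pipeline_writes_outputs_and_manifest(tmp_path):
    cfg = _tiny_run_config(tmp_path / "out")
    bundle = run_pipeline(cfg)
    out = bundle.out_dir
    for name in (
        "demographics.csv", "classification.json", "feature_importance_top20.csv",
        "network_importance.csv", "anomaly_counts.csv", "anomaly_summary.csv",
        "pagerank_flags.csv", "pagerank_heatmap.csv", "manifest.json",
    ):
        assert (out / name).exists(), name
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["seed"] == 5
    assert set(manifest["files"]) >= {"demographics.csv", "classification.json"}
    # checksums describe the files actually on disk
    import hashlib

    for name, digest in manifest["files"].items():
        assert hashlib.sha256((out / name).read_bytes()).hexdigest() == digest


def test_run_pipeline_requires_exactly_one_source(tmp_path):
    with pytest.raises(ValidationError):
        RunConfig(out_dir=tmp_path, cohort_dir=None, synth=None)
    with pytest.raises(ValidationError):
        RunConfig(out_dir=tmp_path, cohort_dir="x", synth=SynthConfig())


def test_centrality_without_structural_raises_stage_error(tmp_path):
    cfg = _tiny_run_config(tmp_path / "out", include_structural=False)
    with pytest.raises(PipelineStageError) as exc:
        run_pipeline(cfg)
    assert exc.value.stage == "pagerank"


def test_runconfig_yaml_roundtrip(tmp_path):
    yaml_text = """
seed: 3
out_dir: {out}
synth:
  n_patients: 4
  n_controls: 4
  n_timepoints: 20
  include_structural: false
  fc_effects: [["L_45", "L_23c", -0.5]]
grid:
  - {{learning_rate: 0.3, max_tree_depth: 2, n_estimators: 5, seed: 0}}
run_centrality: false
""".format(out=tmp_path / "o")
    path = tmp_path / "run.yaml"
    path.write_text(yaml_text)
    cfg = RunConfig.from_yaml(path)
    assert cfg.seed == 3
    assert cfg.synth.n_patients == 4
    assert cfg.synth.fc_effects == [("L_45", "L_23c", -0.5)]
    assert cfg.grid[0].n_estimators == 5
    assert cfg.run_centrality is False
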