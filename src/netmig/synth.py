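"""Synthetic two-group cohorts with controllable planted connectivity effects.

Stands in for the study's non-public data: per-subject regional BOLD-like
time series, per-subject structural connectomes (streamline counts), and a
subject manifest (group, sex, age).

Generative model for the time series of a subject
-------------------------------------------------
Each large-scale network k carries one latent Gaussian AR(1) factor
``f_k(t)`` with lag-1 coefficient ``ar_coeff`` and unit stationary
variance.  A region i affiliated with network k observes

    x_i(t) = latent_coupling * f_k(t) + noise_sd * eps_i(t)

with iid standard-normal noise; ``Unassigned`` regions carry no shared
factor and are pure noise.  This produces block-structured within-network
correlation ``c^2 / (c^2 + s^2)`` (c = latent_coupling, s = noise_sd) and
zero expected cross-network correlation, with two interpretable knobs.

A planted FC effect ``(a, b, delta)`` adds a pair-specific shared AR(1)
component z(t) to patients only:

    x_a += w z,   x_b += sign(delta) * w z,   w = sqrt(|delta|)

so the pair covariance moves by ``delta`` *before* normalisation and the
effect passes through the genuine Pearson pipeline.  The implied
population correlation is analytic (see ``expected_pair_correlation``)
and serves as the oracle in tests.

Structural connectomes are symmetric integer streamline-count matrices:
iid log-normal edge weights (heavy-tailed like empirical streamline
counts), patient-side hub effects multiply a region's row/column before
the matrix is rescaled so the unique-pair total equals
``total_streamlines`` up to rounding.

Reproducibility: one global seed; every subject / stream draws from a
named `numpy` SeedSequence substream keyed by (stream, group, subject
index), so e.g. adding patients never changes control data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasRegistry, N_REGIONS, build_default_atlas, load_affiliation_table, write_affiliation_table
from .centrality import StructuralConnectome
from .errors import ValidationError

_GROUP_CODE = {"control": 0, "patient": 1}
_STREAM_TS = 0
_STREAM_STRUCT = 1
_STREAM_DEMOG = 2
_STREAM_PROPENSITY = 3


@dataclass
class SynthConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults emulate the study conditions: 31 patients vs 17 controls,
    TR 2.0 s, ~300,000 streamlines per brain, and the observed sex split
    (26/31 vs 8/17 female).
    """

    n_patients: int = 31
    n_controls: int = 17
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    latent_coupling: float = 0.8
    noise_sd: float = 1.0
    ar_coeff: float = 0.3
    fc_effects: list = field(default_factory=list)  # (region_a, region_b, delta)
    hub_effects: list = field(default_factory=list)  # (region, factor)
    female_fraction_patients: float = 26 / 31
    female_fraction_controls: float = 8 / 17
    age_range: tuple = (20, 35)
    total_streamlines: int = 300_000
    lognormal_mu: float = 2.0
    lognormal_sigma: float = 1.0
    hub_propensity_sigma: float = 0.5
    include_structural: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "n_controls", "n_timepoints", "total_streamlines"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("female_fraction_patients", "female_fraction_controls"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise ValidationError("ar_coeff must lie in [0, 1)")
        for _, factor in self.hub_effects:
            if factor <= 0:
                raise ValidationError("hub effect factors must be positive")

    def validate_against(self, atlas: AtlasRegistry) -> None:
        """Every region named by an effect must resolve in the atlas."""
        for a, b, _ in self.fc_effects:
            ia, ib = atlas.index_of(a), atlas.index_of(b)
            if ia == ib:
                raise ValidationError(f"fc_effect pair ({a}, {b}) is a self-pair")
        for r, _ in self.hub_effects:
            atlas.index_of(r)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        d["fc_effects"] = [list(e) for e in self.fc_effects]
        d["hub_effects"] = [list(e) for e in self.hub_effects]
        d["age_range"] = list(self.age_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["fc_effects"] = [tuple(e) for e in d.get("fc_effects", [])]
        d["hub_effects"] = [tuple(e) for e in d.get("hub_effects", [])]
        d["age_range"] = tuple(d.get("age_range", (20, 35)))
        return cls(**d)


@dataclass
class SubjectRecord:
    """One subject: label, covariates, time series, optional connectome."""

    subject_id: str
    group: str  # "patient" | "control"
    sex: str  # "F" | "M"
    age_years: int
    timeseries: Optional[np.ndarray] = None  # T x 379
    structural: Optional[StructuralConnectome] = None

    def __post_init__(self):
        if self.group not in _GROUP_CODE:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.timeseries is not None:
            ts = np.asarray(self.timeseries)
            if ts.ndim != 2 or ts.shape[1] != N_REGIONS:
                raise ValidationError("timeseries must be T x 379")
            if not np.all(np.isfinite(ts)):
                raise ValidationError("timeseries contains non-finite values")


@dataclass
class CohortDataset:
    """A cohort plus the registry its matrices are indexed by."""

    subjects: list
    atlas: AtlasRegistry

    def group(self, label: str) -> list:
        return [s for s in self.subjects if s.group == label]

    @property
    def patients(self) -> list:
        return self.group("patient")

    @property
    def controls(self) -> list:
        return self.group("control")

    def require_two_per_group(self) -> None:
        for label in ("patient", "control"):
            if len(self.group(label)) < 2:
                raise ValidationError(
                    f"group comparison needs >= 2 subjects per group; "
                    f"group {label!r} has {len(self.group(label))}"
                )


def _substream(seed: int, stream: int, group: str, index: int) -> np.random.Generator:
    key = (stream, _GROUP_CODE[group], index)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-stationary-variance AR(1) series of length n."""
    innov = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def expected_pair_correlation(
    config: SynthConfig, atlas: AtlasRegistry, region_a, region_b, group: str
) -> float:
    """Population Pearson correlation implied by the generative model.

    The closed form used as the oracle in recovery tests: with coupling c,
    noise s, and planted covariance shift d on the pair (patients only),

        corr = (c_ab + d) / sqrt((v_a + |d_a|)(v_b + |d_b|))

    where c_ab = c^2 if the regions share a network latent else 0, and
    v_i = c^2 + s^2 (or s^2 for Unassigned regions).
    """
    ra, rb = atlas.region(region_a), atlas.region(region_b)
    c2 = config.latent_coupling**2
    var_a = (c2 if ra.network != "Unassigned" else 0.0) + config.noise_sd**2
    var_b = (c2 if rb.network != "Unassigned" else 0.0) + config.noise_sd**2
    cov = c2 if (ra.network == rb.network and ra.network != "Unassigned") else 0.0
    if group == "patient":
        for a, b, delta in config.fc_effects:
            ia, ib = atlas.index_of(a), atlas.index_of(b)
            pair = {ia, ib}
            if atlas.index_of(region_a) in pair:
                var_a += abs(delta)
            if atlas.index_of(region_b) in pair:
                var_b += abs(delta)
            if pair == {atlas.index_of(region_a), atlas.index_of(region_b)}:
                cov += delta
    return cov / np.sqrt(var_a * var_b)


def _subject_timeseries(
    config: SynthConfig, atlas: AtlasRegistry, group: str, index: int
) -> np.ndarray:
    rng = _substream(config.seed, _STREAM_TS, group, index)
    T = config.n_timepoints
    networks = atlas.networks
    latent_names = sorted({n for n in networks if n != "Unassigned"})
    latents = {name: _ar1(rng, T, config.ar_coeff) for name in latent_names}
    x = config.noise_sd * rng.standard_normal((T, N_REGIONS))
    for i, net in enumerate(networks):
        if net != "Unassigned":
            x[:, i] += config.latent_coupling * latents[net]
    if group == "patient":
        for a, b, delta in config.fc_effects:
            ia, ib = atlas.index_of(a), atlas.index_of(b)
            z = _ar1(rng, T, config.ar_coeff)
            w = np.sqrt(abs(delta))
            x[:, ia] += w * z
            x[:, ib] += np.sign(delta) * w * z
    return x


def generate_structural_connectome(
    config: SynthConfig,
    group: str,
    atlas: AtlasRegistry,
    subject_index: int = 0,
) -> StructuralConnectome:
    """One symmetric integer streamline-count matrix.

    Patients get each ``hub_effects`` region's row/column multiplied by its
    strength factor before the matrix is rescaled to ``total_streamlines``
    (sum over unique pairs) and integer-rounded.
    """
    if group not in _GROUP_CODE:
        raise ValidationError(f"unknown group {group!r}")
    config.validate_against(atlas)
    rng = _substream(config.seed, _STREAM_STRUCT, group, subject_index)
    n = N_REGIONS
    # Persistent hub structure: a fixed log-normal per-region propensity
    # (shared by both groups and every subject of a cohort) multiplies
    # edge weights, so centrality rank order is reproducible across
    # subjects as in empirical connectomes; subject-level edge noise is
    # the log-normal(mu, sigma) factor.
    prop_rng = _substream(config.seed, _STREAM_PROPENSITY, "control", 0)
    u = prop_rng.lognormal(mean=0.0, sigma=config.hub_propensity_sigma, size=n)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = (
        u[iu[0]] * u[iu[1]]
        * rng.lognormal(mean=config.lognormal_mu, sigma=config.lognormal_sigma, size=iu[0].size)
    )
    w = w + w.T
    if group == "patient":
        for region, factor in config.hub_effects:
            i = atlas.index_of(region)
            w[i, :] *= factor
            w[:, i] *= factor
    np.fill_diagonal(w, 0.0)
    # largest-remainder apportionment: integer streamline counts whose
    # unique-pair total equals total_streamlines exactly
    scaled = w[iu] * (config.total_streamlines / w[iu].sum())
    upper = np.floor(scaled)
    shortfall = int(round(config.total_streamlines - upper.sum()))
    if shortfall > 0:
        frac = scaled - upper
        top = np.argsort(-frac, kind="stable")[:shortfall]
        upper[top] += 1
    out = np.zeros((n, n))
    out[iu] = upper
    out = out + out.T
    return StructuralConnectome(out)


def generate_cohort(config: SynthConfig, atlas: Optional[AtlasRegistry] = None) -> CohortDataset:
    """Draw a full two-group cohort, reproducible from ``config.seed``."""
    if atlas is None:
        atlas = build_default_atlas()
    config.validate_against(atlas)
    subjects = []
    for group, n, frac in (
        ("patient", config.n_patients, config.female_fraction_patients),
        ("control", config.n_controls, config.female_fraction_controls),
    ):
        demog = _substream(config.seed, _STREAM_DEMOG, group, 0)
        n_female = int(round(frac * n))
        sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
        demog.shuffle(sexes)
        lo, hi = config.age_range
        ages = demog.integers(lo, hi + 1, size=n)
        for i in range(n):
            ts = _subject_timeseries(config, atlas, group, i)
            structural = (
                generate_structural_connectome(config, group, atlas, subject_index=i)
                if config.include_structural
                else None
            )
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}_{i + 1:02d}",
                    group=group,
                    sex=str(sexes[i]),
                    age_years=int(ages[i]),
                    timeseries=ts,
                    structural=structural,
                )
            )
    return CohortDataset(subjects=subjects, atlas=atlas)


# -- cohort directory I/O ------------------------------------------------


def write_cohort(dataset: CohortDataset, directory: Union[str, Path]) -> None:
    """Manifest CSV + per-subject plain-text TSV matrices + atlas CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.subjects:
        rows.append(
            {"subject_id": s.subject_id, "group": s.group, "sex": s.sex, "age_years": s.age_years}
        )
        if s.timeseries is not None:
            np.savetxt(directory / f"{s.subject_id}_timeseries.tsv", s.timeseries, fmt="%.10g", delimiter="\t")
        if s.structural is not None:
            np.savetxt(directory / f"{s.subject_id}_structural.tsv", s.structural.weights, fmt="%d", delimiter="\t")
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    write_affiliation_table(dataset.atlas, directory / "atlas.csv")


def read_cohort(directory: Union[str, Path]) -> CohortDataset:
    directory = Path(directory)
    atlas = load_affiliation_table(directory / "atlas.csv")
    manifest = pd.read_csv(directory / "manifest.csv")
    subjects = []
    for row in manifest.itertuples(index=False):
        ts_path = directory / f"{row.subject_id}_timeseries.tsv"
        st_path = directory / f"{row.subject_id}_structural.tsv"
        ts = np.loadtxt(ts_path, delimiter="\t") if ts_path.exists() else None
        structural = (
            StructuralConnectome(np.loadtxt(st_path, delimiter="\t"))
            if st_path.exists()
            else None
        )
        subjects.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                sex=row.sex,
                age_years=int(row.age_years),
                timeseries=ts,
                structural=structural,
            )
        )
    return CohortDataset(subjects=subjects, atlas=atlas)
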