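"""Control-referenced MAD outlier detection and per-network anomaly counts.

For every FC pair feature the healthy-control cohort supplies a median
and a median absolute deviation (MAD, no consistency constant).  A
patient's feature is an anomaly when its absolute deviation from the
control median reaches 3 MAD or more (threshold inclusive).  Each
anomalous pair increments the tally of each endpoint's network: a
within-network pair adds one to that network, a cross-network pair adds
one to each of its two networks.  Reported per patient and as the mean
over patients per network.

Features whose control MAD is zero (possible with small control samples
and ties) are excluded from counting rather than treated as automatically
anomalous.  Optional variants: the 1.4826 normal-consistency scaling of
the MAD, and half-credit (0.5 to each network) for cross-network pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasRegistry
from .connectivity import FeatureVector, N_PAIR_FEATURES
from .errors import AlignmentError, ValidationError

MAD_THRESHOLD = 3.0
NORMAL_CONSISTENCY = 1.4826


@dataclass
class MADReference:
    """Per-feature control median and MAD; ``evaluable`` is MAD > 0."""

    control_median: np.ndarray
    control_mad: np.ndarray
    n_controls: int
    scaled: bool = False

    @property
    def evaluable(self) -> np.ndarray:
        return self.control_mad > 0

    @property
    def n_evaluable(self) -> int:
        return int(self.evaluable.sum())


def control_reference(
    controls: Sequence[FeatureVector], scaled: bool = False
) -> MADReference:
    """Median and MAD per feature over the control cohort (>= 3 controls)."""
    if len(controls) < 3:
        raise ValidationError(
            f"MAD reference needs >= 3 controls, got {len(controls)}"
        )
    values = np.vstack([c.values for c in controls])
    med = np.median(values, axis=0)
    mad = np.median(np.abs(values - med), axis=0)
    if scaled:
        mad = NORMAL_CONSISTENCY * mad
    return MADReference(
        control_median=med, control_mad=mad, n_controls=len(controls), scaled=scaled
    )


def anomaly_mask(patient: FeatureVector, ref: MADReference) -> np.ndarray:
    """Boolean per-feature anomaly indicator (non-evaluable -> False)."""
    if patient.values.shape != ref.control_median.shape:
        raise AlignmentError("patient features do not align with the MAD reference")
    ok = ref.evaluable
    mask = np.zeros(patient.values.shape, dtype=bool)
    dev = np.abs(patient.values[ok] - ref.control_median[ok])
    # tiny relative slack keeps the inclusive threshold inclusive under
    # floating-point round-off (e.g. 0.15/0.05 evaluating to 2.999...)
    mask[ok] = dev / ref.control_mad[ok] >= MAD_THRESHOLD * (1.0 - 1e-12)
    return mask


def count_anomalies(
    patient: FeatureVector,
    ref: MADReference,
    atlas: AtlasRegistry,
    half_credit: bool = False,
) -> pd.Series:
    """Per-network anomaly count for one patient.

    With ``half_credit`` a cross-network anomaly contributes 0.5 to each
    endpoint network instead of 1 (the within-network contribution stays
    1 either way).
    """
    mask = anomaly_mask(patient, ref)
    ia, ib = FeatureVector.pair_index()
    networks = np.asarray(atlas.networks)
    net_a, net_b = networks[ia], networks[ib]
    labels = sorted(set(networks))
    counts = {}
    weight = 0.5 if half_credit else 1.0
    cross = net_a != net_b
    for net in labels:
        within = mask & (net_a == net) & (net_b == net)
        touching = mask & cross & ((net_a == net) | (net_b == net))
        counts[net] = float(within.sum() + weight * touching.sum())
        if not half_credit:
            counts[net] = int(counts[net])
    return pd.Series(counts, name="anomaly_count")


@dataclass
class AnomalyReport:
    """Patients x networks anomaly counts with per-network means."""

    counts: pd.DataFrame  # index: patient ids, columns: networks
    ref: MADReference

    @property
    def network_means(self) -> pd.Series:
        return self.counts.mean(axis=0)

    def top_network(self) -> str:
        means = self.network_means
        return str(means.sort_index().idxmax())  # deterministic tie-break


def anomaly_report(
    patients: Sequence,
    ref: MADReference,
    atlas: AtlasRegistry,
    features: Sequence[FeatureVector],
    half_credit: bool = False,
) -> AnomalyReport:
    """Counts for a patient cohort; ``features`` aligns with ``patients``."""
    if len(patients) != len(features):
        raise AlignmentError("patients and feature vectors differ in length")
    rows = {}
    for subj, fv in zip(patients, features):
        sid = getattr(subj, "subject_id", str(subj))
        rows[sid] = count_anomalies(fv, ref, atlas, half_credit=half_credit)
    return AnomalyReport(counts=pd.DataFrame(rows).T, ref=ref)
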