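"""Weighted PageRank hubness analysis on streamline-count connectomes.

PageRank centrality scores each brain region by the stationary probability
of a damped random walk on the weighted structural graph: a region with
many strong connections to other influential regions scores high, while
terminal (dangling) connections are biased against.  Scores are converted
to ranks (1 = most central, 379 = least), the per-region median rank in
the control cohort defines the listing order, and patient-vs-control
median-rank shifts beyond a threshold are flagged as hub deviations.

Symmetric streamline matrices are treated as bidirectional directed
graphs: each undirected edge contributes two directed edges of equal
weight.  The damping factor is not a fitted quantity; the conventional
0.85 is the default and is exposed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import AlignmentError, ConvergenceError, ValidationError

DEFAULT_DAMPING = 0.85
DEFAULT_RANK_SHIFT_THRESHOLD = 20


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric nonnegative streamline-count matrix, zero diagonal."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("connectome must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValidationError("connectome weights must be finite")
        if np.any(w < 0):
            raise ValidationError("connectome weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValidationError("connectome must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValidationError("connectome diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def total_streamlines(self) -> float:
        """Sum over unique pairs (each undirected edge counted once)."""
        return float(np.triu(self.weights, k=1).sum())

    def node_strength(self) -> np.ndarray:
        return self.weights.sum(axis=1)


def weighted_pagerank(
    connectome: StructuralConnectome,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Stationary vector of the damped weighted random walk.

    Out-edge transition probabilities are proportional to edge weight;
    all-zero rows (dangling regions) teleport uniformly.  Power iteration
    runs to an L1 tolerance of ``tol``; the result sums to 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValidationError("damping must lie strictly between 0 and 1")
    w = connectome.weights
    n = w.shape[0]
    out = w.sum(axis=1)
    dangling = out == 0
    # row-stochastic transition matrix on non-dangling rows
    p = np.zeros_like(w)
    nz = ~dangling
    p[nz] = w[nz] / out[nz, None]
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        dangling_mass = x[dangling].sum()
        x_new = damping * (p.T @ x + dangling_mass / n) + teleport
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise ConvergenceError(
            f"PageRank did not reach L1 tolerance {tol} in {max_iter} iterations"
        )
    return x / x.sum()


def pagerank_dense_solve(
    connectome: StructuralConnectome, damping: float = DEFAULT_DAMPING
) -> np.ndarray:
    """Direct linear-system solution of the same stationary equations.

    Solves (I - d M^T) x = (1-d)/n with M the dangling-patched transition
    matrix; used as the independent oracle for the power iteration.
    """
    if not 0.0 < damping < 1.0:
        raise ValidationError("damping must lie strictly between 0 and 1")
    w = connectome.weights
    n = w.shape[0]
    out = w.sum(axis=1)
    m = np.full((n, n), 1.0 / n)
    nz = out > 0
    m[nz] = w[nz] / out[nz, None]
    x = np.linalg.solve(np.eye(n) - damping * m.T, np.full(n, (1.0 - damping) / n))
    return x / x.sum()


def rank_centralities(scores: np.ndarray) -> np.ndarray:
    """Descending-score ranks 1..n; ties broken by ascending region id."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.size
    order = np.lexsort((np.arange(n), -scores))  # stable: id ascends in ties
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


@dataclass
class DeviationReport:
    """Control-ordered rank table plus flagged hub shifts.

    ``table`` lists every region in ascending control-median-rank order
    with both group medians; ``flags`` holds regions whose patient-vs-
    control median-rank shift meets the threshold, with direction
    "higher" (patient median rank numerically smaller = more central) or
    "lower".  ``subject_outliers`` marks subjects whose whole rank vector
    is unusually discordant with the control median ordering (Spearman
    rho an outlier on the 3-MAD rule); purely descriptive.
    """

    table: pd.DataFrame
    flags: pd.DataFrame
    heatmap: pd.DataFrame
    subject_outliers: list
    threshold: int


def rank_deviation(
    patient_ranks: Sequence[np.ndarray],
    control_ranks: Sequence[np.ndarray],
    region_names: Sequence[str],
    threshold: int = DEFAULT_RANK_SHIFT_THRESHOLD,
    subject_ids: Optional[Sequence[str]] = None,
) -> DeviationReport:
    """Compare patient rank vectors to the control median ordering."""
    if len(patient_ranks) < 3 or len(control_ranks) < 3:
        raise ValidationError("need >= 3 subjects per group")
    n = len(region_names)
    pr = np.asarray(patient_ranks)
    cr = np.asarray(control_ranks)
    if pr.shape[1] != n or cr.shape[1] != n:
        raise AlignmentError("rank vectors do not match the region set")
    control_median = np.median(cr, axis=0)
    patient_median = np.median(pr, axis=0)
    shift = patient_median - control_median  # negative => more central
    order = np.lexsort((np.arange(n), control_median))
    table = pd.DataFrame(
        {
            "region": np.asarray(region_names)[order],
            "control_median_rank": control_median[order],
            "patient_median_rank": patient_median[order],
            "shift": shift[order],
        }
    )
    flagged = np.abs(shift) >= threshold
    direction = np.where(shift < 0, "higher", "lower")
    flags = pd.DataFrame(
        {
            "region": np.asarray(region_names)[flagged],
            "control_median_rank": control_median[flagged],
            "patient_median_rank": patient_median[flagged],
            "direction": direction[flagged],
        }
    ).sort_values("control_median_rank", kind="stable").reset_index(drop=True)

    all_ranks = np.vstack([pr, cr])
    if subject_ids is None:
        subject_ids = [f"patient_{i + 1:02d}" for i in range(len(pr))] + [
            f"control_{i + 1:02d}" for i in range(len(cr))
        ]
    heatmap = pd.DataFrame(
        all_ranks[:, order], index=list(subject_ids), columns=table["region"].tolist()
    )
    rhos = np.array([spearmanr(r, control_median).statistic for r in all_ranks])
    med = np.median(rhos)
    mad = np.median(np.abs(rhos - med))
    if mad > 0:
        outlier_mask = np.abs(rhos - med) / mad >= 3
    else:
        outlier_mask = np.zeros(len(rhos), dtype=bool)
    subject_outliers = [sid for sid, bad in zip(subject_ids, outlier_mask) if bad]
    return DeviationReport(
        table=table,
        flags=flags,
        heatmap=heatmap,
        subject_outliers=subject_outliers,
        threshold=threshold,
    )


def cohort_rank_vectors(subjects, damping: float = DEFAULT_DAMPING) -> list[np.ndarray]:
    """PageRank rank vectors for every subject carrying a connectome."""
    ranks = []
    for s in subjects:
        if s.structural is None:
            raise ValidationError(f"subject {s.subject_id} has no structural matrix")
        ranks.append(rank_centralities(weighted_pagerank(s.structural, damping=damping)))
    return ranks
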