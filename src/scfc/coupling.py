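"""Structure-function coupling statistics.

Two complementary views of how structural (FA) and functional (AECc)
edge weights relate:

* between-subject: each subject is reduced to a mean SC and a mean FC
  over an edge class; the two per-subject means are correlated across
  the subjects of a group, giving one Pearson coefficient per group.
* within-subject: the SC and FC edge-weight vectors of a single subject
  are correlated over the same edges, giving one coupling value per
  subject that can then be compared between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CouplingResult",
    "GroupCorrelationResult",
    "within_subject_coupling",
    "between_subject_correlation",
    "cross_range_correlation",
]

MIN_EDGES = 3
MIN_SUBJECTS = 3


@dataclass
class CouplingResult:
    """Per-subject structure-function coupling for one edge class/band."""

    subject_id: str
    edge_class: str
    band: str
    r: float
    n_edges: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


@dataclass
class GroupCorrelationResult:
    """Between-subject Pearson correlation of mean SC vs mean FC."""

    group: str
    edge_class: str
    band: str
    r: float
    p: float
    n_subjects: int


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the exact t transform (df = n - 2)."""
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def within_subject_coupling(
    sc_vector: np.ndarray,
    fc_vector: np.ndarray,
    subject_id: str = "",
    edge_class: str = "whole",
    band: str = "",
    min_edges: int = MIN_EDGES,
) -> CouplingResult:
    """Pearson correlation of one subject's SC and FC edge vectors.

    Both vectors must come from the identical edge ordering (row-major
    upper triangle restricted to the same class mask).  With fewer than
    ``min_edges`` edges the coupling is undefined and reported as NaN
    with a warning, to be excluded listwise downstream; a constant
    vector raises, naming the offending side.
    """
    sc_vector = np.asarray(sc_vector, dtype=float)
    fc_vector = np.asarray(fc_vector, dtype=float)
    if sc_vector.shape != fc_vector.shape or sc_vector.ndim != 1:
        raise ValueError("SC and FC edge vectors must be 1-d with equal length")
    n = sc_vector.size
    if n < min_edges:
        warnings.warn(
            f"subject {subject_id!r}: only {n} edges in class {edge_class!r} "
            f"(minimum {min_edges}); coupling undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return CouplingResult(subject_id, edge_class, band, float("nan"), n)
    if np.ptp(sc_vector) == 0.0:
        raise ValueError(f"SC edge vector is constant for subject {subject_id!r}")
    if np.ptp(fc_vector) == 0.0:
        raise ValueError(f"FC edge vector is constant for subject {subject_id!r}")
    r, _ = _pearson_with_p(sc_vector, fc_vector)
    return CouplingResult(subject_id, edge_class, band, r, n)


def between_subject_correlation(
    mean_sc: np.ndarray,
    mean_fc: np.ndarray,
    group: str = "",
    edge_class: str = "whole",
    band: str = "",
) -> GroupCorrelationResult:
    """Correlate per-subject mean SC against mean FC across subjects.

    Indicates whether individual differences in global structural
    connectivity track individual differences in global functional
    connectivity within a group.
    """
    mean_sc = np.asarray(mean_sc, dtype=float)
    mean_fc = np.asarray(mean_fc, dtype=float)
    if mean_sc.shape != mean_fc.shape or mean_sc.ndim != 1:
        raise ValueError("mean SC and mean FC must be 1-d with equal length")
    n = mean_sc.size
    if n < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {n}")
    if np.ptp(mean_sc) == 0.0 or np.ptp(mean_fc) == 0.0:
        side = "SC" if np.ptp(mean_sc) == 0.0 else "FC"
        raise ValueError(f"zero variance in per-subject mean {side} averages")
    r, p = _pearson_with_p(mean_sc, mean_fc)
    return GroupCorrelationResult(group, edge_class, band, r, p, n)


def cross_range_correlation(
    mean_sc: np.ndarray,
    mean_fc: np.ndarray,
    sc_class: str,
    fc_class: str,
    group: str = "",
    band: str = "",
) -> GroupCorrelationResult:
    """Between-subject correlation across edge classes.

    Mean SC is taken over one class (e.g. long-range) and mean FC over
    another (e.g. short-range), probing whether the two classes carry
    distinct structure-function information.  With ``sc_class ==
    fc_class`` this reduces to :func:`between_subject_correlation`.
    """
    res = between_subject_correlation(
        mean_sc, mean_fc, group=group, edge_class=f"sc:{sc_class}|fc:{fc_class}", band=band
    )
    if sc_class == fc_class:
        res.edge_class = sc_class
    return res
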