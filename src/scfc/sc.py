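"""Structural connectomes: FA matrices, tract lengths, edge stratification.

A structural connectome here is a pair of symmetric node-by-node
matrices: mean fractional anisotropy (FA) per reconstructed tract, and
tract length in millimetres.  Edges are stratified into short- and
long-range classes using quartile thresholds of the pooled
healthy-control tract-length distribution, and functional connections
are masked by structural presence before any coupling statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc import FCMatrix

__all__ = [
    "StructuralConnectome",
    "RangeThresholds",
    "EdgeClassMask",
    "read_connectome",
    "write_connectome",
    "sparsity",
    "mean_sc",
    "quartile_thresholds",
    "classify_edges",
    "count_range_connections",
    "mask_fc_by_structure",
]

EDGE_CLASSES = ("short", "long", "whole")


def _upper(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle indices — the fixed edge ordering."""
    return np.triu_indices(n, k=1)


@dataclass
class StructuralConnectome:
    """Mean-FA and tract-length matrices over labelled cortical nodes.

    ``fa`` is 0 where no tract was reconstructed; lengths must be
    positive wherever ``fa`` is positive.  Matrices are unthresholded:
    every reconstructed tract is kept regardless of weight.
    """

    fa: np.ndarray
    lengths: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.fa.shape[0]
        for name, m in (("fa", self.fa), ("lengths", self.lengths)):
            if m.ndim != 2 or m.shape != (n, n):
                raise ValueError(f"{name} matrix must be square with matching size")
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValueError(f"{name} matrix is not symmetric")
            if not np.allclose(np.diag(m), 0.0):
                raise ValueError(f"{name} matrix must have a zero diagonal")
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match matrix size")
        bad = np.argwhere((self.fa < 0) | (self.fa > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"FA out of [0, 1] at ({self.node_labels[i]}, {self.node_labels[j]}): "
                f"{self.fa[i, j]}"
            )
        if np.any(self.lengths < 0):
            raise ValueError("tract lengths must be non-negative")
        present = self.fa > 0
        if np.any(present & (self.lengths <= 0)):
            raise ValueError("present edges (fa > 0) must have positive tract length")

    @property
    def n_nodes(self) -> int:
        return self.fa.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def present_edges(self, presence_floor: float = 0.0) -> np.ndarray:
        """Boolean upper-triangle vector: edge has a structural tract."""
        iu = _upper(self.n_nodes)
        return self.fa[iu] > presence_floor

    def edge_fa(self) -> np.ndarray:
        return self.fa[_upper(self.n_nodes)]

    def edge_lengths(self) -> np.ndarray:
        return self.lengths[_upper(self.n_nodes)]


@dataclass(frozen=True)
class RangeThresholds:
    """Tract-length quartile thresholds (mm) separating edge classes."""

    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.q3:
            raise ValueError(f"q1 ({self.q1}) must not exceed q3 ({self.q3})")


@dataclass
class EdgeClassMask:
    """Boolean upper-triangle indicators for edge classes of one subject.

    ``short_mask`` and ``long_mask`` are disjoint subsets of
    ``present_mask``; edges whose length falls between the thresholds
    (inclusive) belong to neither class but still count as present.
    """

    short_mask: np.ndarray
    long_mask: np.ndarray
    present_mask: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        for name in ("short_mask", "long_mask", "present_mask"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (len(self.short_mask) == len(self.long_mask) == len(self.present_mask)):
            raise ValueError("mask vectors must have equal length")
        if np.any(self.short_mask & self.long_mask):
            raise ValueError("an edge cannot be both short- and long-range")
        if np.any(self.short_mask & ~self.present_mask) or np.any(
            self.long_mask & ~self.present_mask
        ):
            raise ValueError("classified edges must be structurally present")

    def mask_for(self, which: str) -> np.ndarray:
        if which == "short":
            return self.short_mask
        if which == "long":
            return self.long_mask
        if which == "whole":
            return self.present_mask
        raise ValueError(f"unknown edge class {which!r}; expected one of {EDGE_CLASSES}")

    def to_edge_list(self) -> pd.DataFrame:
        """Three-column edge list (node_i, node_j, class) for export."""
        n = len(self.node_labels)
        iu = _upper(n)
        cls = np.where(
            self.short_mask, "short", np.where(self.long_mask, "long", "mid")
        )
        keep = self.present_mask
        return pd.DataFrame(
            {
                "node_i": np.asarray(self.node_labels)[iu[0]][keep],
                "node_j": np.asarray(self.node_labels)[iu[1]][keep],
                "class": cls[keep],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def _read_square(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape})")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return df


def read_connectome(fa_path, lengths_path) -> StructuralConnectome:
    """Load a connectome from two square tab-delimited matrices.

    Both files carry the node labels as header row and index column and
    must agree on them.  Slightly asymmetric input (beyond 1e-9) is
    symmetrized by averaging with a warning; grossly invalid values
    raise descriptive errors.
    """
    fa_df = _read_square(fa_path)
    len_df = _read_square(lengths_path)
    if list(fa_df.columns) != list(len_df.columns):
        raise ValueError(
            f"node labels differ between {fa_path} and {lengths_path}"
        )
    mats = []
    for name, df, path in (("FA", fa_df, fa_path), ("lengths", len_df, lengths_path)):
        m = df.to_numpy(dtype=float)
        asym = np.max(np.abs(m - m.T)) if m.size else 0.0
        if asym > 1e-9:
            warnings.warn(
                f"{path}: {name} matrix asymmetric (max |A - A^T| = {asym:.3g}); "
                "symmetrizing by averaging",
                RuntimeWarning,
                stacklevel=2,
            )
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        mats.append(m)
    return StructuralConnectome(fa=mats[0], lengths=mats[1], node_labels=list(fa_df.columns))


def write_connectome(sc: StructuralConnectome, fa_path, lengths_path) -> None:
    for m, path in ((sc.fa, fa_path), (sc.lengths, lengths_path)):
        pd.DataFrame(m, index=sc.node_labels, columns=sc.node_labels).to_csv(
            path, sep="\t"
        )


# ---------------------------------------------------------------------------
# per-subject summaries


def sparsity(sc: StructuralConnectome, presence_floor: float = 0.0) -> float:
    """Fraction of possible edges with no structural connection."""
    present = sc.present_edges(presence_floor)
    return float(1.0 - present.mean())


def mean_sc(
    sc: StructuralConnectome,
    mask: np.ndarray | None = None,
    present_only: bool = True,
    presence_floor: float = 0.0,
) -> float:
    """Mean FA over selected edges.

    With no mask, averages over present edges (absent tracts are not
    counted as zeros, consistent with FA being a per-tract mean); set
    ``present_only=False`` to average over all node pairs instead.
    """
    fa = sc.edge_fa()
    if mask is None:
        mask = (
            sc.present_edges(presence_floor)
            if present_only
            else np.ones_like(fa, dtype=bool)
        )
    if not np.any(mask):
        raise ValueError("no edges selected for mean SC")
    return float(fa[mask].mean())


# ---------------------------------------------------------------------------
# tract-length stratification


def quartile_thresholds(
    hc_connectomes: list[StructuralConnectome],
    presence_floor: float = 0.0,
) -> RangeThresholds:
    """Q1/Q3 tract-length thresholds from pooled healthy-control edges.

    All present-edge lengths of all HC subjects are pooled into one
    sample; the 25th and 75th percentiles are taken with linear
    interpolation between order statistics.
    """
    if not hc_connectomes:
        raise ValueError("at least one healthy-control connectome is required")
    pooled = np.concatenate(
        [sc.edge_lengths()[sc.present_edges(presence_floor)] for sc in hc_connectomes]
    )
    if pooled.size == 0:
        raise ValueError("no present edges in the pooled healthy-control sample")
    q1, q3 = np.quantile(pooled, [0.25, 0.75], method="linear")
    return RangeThresholds(q1=float(q1), q3=float(q3))


def classify_edges(
    sc: StructuralConnectome,
    thr: RangeThresholds,
    presence_floor: float = 0.0,
) -> EdgeClassMask:
    """Assign present edges to short (< q1) / long (> q3) classes.

    Inequalities are strict, so an edge whose length equals a threshold
    is left unclassified (present but neither short nor long).
    """
    present = sc.present_edges(presence_floor)
    lengths = sc.edge_lengths()
    return EdgeClassMask(
        short_mask=present & (lengths < thr.q1),
        long_mask=present & (lengths > thr.q3),
        present_mask=present,
        node_labels=list(sc.node_labels),
    )


def count_range_connections(mask: EdgeClassMask) -> tuple[int, int]:
    """Number of short- and long-range connections of one subject."""
    return int(mask.short_mask.sum()), int(mask.long_mask.sum())


def mask_fc_by_structure(fc: FCMatrix, mask: EdgeClassMask, which: str) -> np.ndarray:
    """FC values at structurally present edges of the requested class.

    Only functional connections with a direct underlying structural
    connection are considered; ``which='whole'`` selects all present
    edges.  The edge ordering is the fixed row-major upper triangle.
    """
    if mask.node_labels and fc.node_labels and mask.node_labels != fc.node_labels:
        raise ValueError("FC matrix and edge mask refer to different node sets")
    n = fc.n_nodes
    if len(mask.present_mask) != n * (n - 1) // 2:
        raise ValueError("edge mask size does not match FC matrix")
    sel = mask.mask_for(which)
    if not np.any(sel):
        raise ValueError(
            f"no edges in class {which!r}: downstream correlation undefined"
        )
    return fc.values[_upper(n)][sel]
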