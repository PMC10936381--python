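"""Radius-based neighbor counting over planar cell maps.

A local neighborhood is the closed Euclidean disk of radius ``d`` around a
cell: a neighbor at exactly distance ``d`` counts (boundary-inclusive). The
focal cell never counts itself, by identity rather than by coordinates, so two
distinct cells at identical positions do count each other. No edge correction
is applied at the tissue boundary: counts near the border are naturally
smaller, and the permutation nulls in :mod:`netqc.enrichment` inherit the same
geometry, which is what compensates for it.

Counting goes through a k-d tree; the test suite holds it to exact agreement
with an O(n^2) brute-force double loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io_tables import CellTable


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Neighborhood definition: radius ``d`` in the coordinates' length units.

    The boundary rule (inclusive, <= d) and self-exclusion are fixed.
    """

    radius: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValidationError(f"neighborhood radius must be a positive finite real, got {self.radius}")


def mean_neighbor_count_at_positions(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    cfg: NeighborhoodConfig,
    *,
    same_points: bool = False,
) -> float:
    """Average number of B points within ``cfg.radius`` of each A point.

    ``same_points=True`` declares that the two arrays are the *same cells*
    (the A = B case), in which case each point's trivial self-pair is removed.
    """
    pos_a = np.asarray(positions_a, dtype=float).reshape(-1, 2)
    pos_b = np.asarray(positions_b, dtype=float).reshape(-1, 2)
    if len(pos_a) == 0:
        raise ValidationError("focal position set is empty")
    if not np.all(np.isfinite(pos_a)) or not np.all(np.isfinite(pos_b)):
        raise ValidationError("positions must be finite")
    if len(pos_b) == 0:
        return 0.0
    total = cKDTree(pos_a).count_neighbors(cKDTree(pos_b), cfg.radius)
    if same_points:
        total -= len(pos_a)
    return float(total) / len(pos_a)


def neighbor_counts(
    positions_query: np.ndarray, positions_source: np.ndarray, cfg: NeighborhoodConfig
) -> np.ndarray:
    """Per-query-point count of source points within the radius (no exclusion)."""
    pos_q = np.asarray(positions_query, dtype=float).reshape(-1, 2)
    pos_s = np.asarray(positions_source, dtype=float).reshape(-1, 2)
    if len(pos_s) == 0:
        return np.zeros(len(pos_q), dtype=np.int64)
    tree = cKDTree(pos_s)
    return np.asarray(
        tree.query_ball_point(pos_q, cfg.radius, return_length=True), dtype=np.int64
    )


def mean_neighbor_count(
    cells: CellTable, focal: str, query: str, cfg: NeighborhoodConfig
) -> float:
    """Average number of ``query``-type cells within ``d`` of each ``focal`` cell.

    This is the observed statistic of the enrichment test: for focal type A and
    query type B, (1/n_A) * sum over A cells of |{B cells within distance d}|,
    with the focal cell itself excluded when A = B.
    """
    for label in (focal, query):
        if label not in cells.class_set:
            raise ValidationError(f"unknown class label: {label!r}")
    pos_a = cells.positions_of(focal)
    pos_b = cells.positions_of(query)
    if len(pos_a) == 0:
        raise ValidationError(f"no cells of focal type {focal!r}")
    return mean_neighbor_count_at_positions(pos_a, pos_b, cfg, same_points=focal == query)
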