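"""Minority-class nearest neighbors and the visible-neighbor filter.

Classic SMOTE interpolates between a minority point ``x`` and any of its k
nearest minority neighbors.  When the minority class occupies a nonconvex
region, the segment from ``x`` to a far neighbor can cross majority
territory.  The *visible neighbor* criterion removes exactly those
neighbors: ``y`` in ``KNN(x)`` is visible from ``x`` iff

    <x - z, y - z> >= 0   for every z in KNN(x),

i.e. no third neighbor ``z`` sits at an obtuse angle between ``x`` and
``y`` (equivalently, no ``z`` lies strictly inside the sphere with
diameter ``xy``).  The check at ``z = y`` is an inner product with the
zero vector and never disqualifies; boundary cases (inner product exactly
zero, including exact duplicate points) count as visible.

A useful consequence: the *nearest* neighbor is always visible — if some
``z`` separated it, the obtuse angle at ``z`` would force ``z`` to be
strictly closer than the nearest neighbor.  Visible sets are therefore
never empty, which the resampler relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import LabeledDataset
from .exceptions import ConfigurationError

__all__ = ["NeighborIndex", "VisibleSet", "knn_minority", "is_visible", "visible_neighbors"]


@dataclass(frozen=True)
class NeighborIndex:
    """k nearest minority neighbors of each minority point.

    ``anchor_indices[i]`` is the original dataset row of the i-th minority
    point; ``neighbor_indices[i]`` are the rows of its k nearest minority
    neighbors in ascending distance order (ties broken by ascending row
    index); ``distances[i]`` the matching Euclidean distances.
    """

    anchor_indices: np.ndarray  # (m,)
    neighbor_indices: np.ndarray  # (m, k) original row indices
    distances: np.ndarray  # (m, k)

    @property
    def k(self) -> int:
        return self.neighbor_indices.shape[1]

    def eligible_lists(self) -> list[np.ndarray]:
        """Per-anchor candidate-neighbor rows, for the sampler."""
        return [self.neighbor_indices[i] for i in range(len(self.anchor_indices))]


@dataclass(frozen=True)
class VisibleSet:
    """Per-anchor subset of the neighbor lists passing the visibility test.

    ``visible[i]`` preserves the ascending-distance order of the
    corresponding :class:`NeighborIndex` row and is never empty.
    """

    anchor_indices: np.ndarray
    visible: list  # list of 1-D arrays of original row indices

    def eligible_lists(self) -> list[np.ndarray]:
        return self.visible


def knn_minority(ds: LabeledDataset, k: int) -> NeighborIndex:
    """k nearest neighbors of every minority point, within the minority class.

    Distances are Euclidean; a point is never its own neighbor; exact
    distance ties are broken by ascending row index so results are
    deterministic.

    Raises
    ------
    ConfigurationError
        If ``k < 1``, ``k >= minority_count`` or the minority class has
        fewer than two members.
    """
    minority_rows = ds.minority_indices
    m = len(minority_rows)
    if m < 2:
        raise ConfigurationError("minority class needs >= 2 samples for KNN")
    if not 1 <= k < m:
        raise ConfigurationError(f"k must satisfy 1 <= k < minority_count={m}, got {k}")

    X = ds.features[minority_rows]
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)  # exclude the anchor itself
    # stable sort on distance keeps ascending local (= ascending row) index on ties
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    rows = np.arange(m)[:, None]
    return NeighborIndex(
        anchor_indices=minority_rows,
        neighbor_indices=minority_rows[order],
        distances=dist[rows, order],
    )


def is_visible(x, y, knn_points) -> bool:
    """Direct evaluation of the visibility condition for one pair.

    True iff ``<x - z, y - z> >= 0`` for every ``z`` in ``knn_points``
    (``y`` itself contributes a zero inner product).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(knn_points, dtype=float))
    return bool(np.all(np.einsum("ij,ij->i", x - Z, y - Z) >= 0.0))


def _visible_mask(anchor: np.ndarray, nbrs: np.ndarray) -> np.ndarray:
    """Boolean visibility of each of ``nbrs`` from ``anchor``.

    With ``U = nbrs - anchor`` and Gram matrix ``G = U U^T``,
    ``<x - z_a, y_b - z_a> = G[a,a] - G[a,b]``; neighbor b is visible iff
    the minimum over a is >= 0.  One matmul per anchor replaces the
    naive triple loop.
    """
    U = nbrs - anchor
    G = U @ U.T
    return (np.diag(G)[:, None] - G).min(axis=0) >= 0.0


def visible_neighbors(ni: NeighborIndex, ds: LabeledDataset) -> VisibleSet:
    """Filter each neighbor list down to its visible members.

    Output order preserves the ascending-distance order of ``ni``.  By the
    nearest-neighbor argument in the module docstring every returned list
    is non-empty.
    """
    visible: list[np.ndarray] = []
    for i, anchor_row in enumerate(ni.anchor_indices):
        nbr_rows = ni.neighbor_indices[i]
        mask = _visible_mask(ds.features[anchor_row], ds.features[nbr_rows])
        visible.append(nbr_rows[mask])
    return VisibleSet(anchor_indices=ni.anchor_indices, visible=visible)
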