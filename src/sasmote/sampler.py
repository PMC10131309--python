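"""Candidate synthetic-point generation by segment interpolation.

Each candidate lies on the closed segment between a minority *parent* and
one of its eligible neighbors: ``point = parent + u * (neighbor - parent)``
with ``u`` uniform on the unit interval.  Eligible neighbors are either
the visible set (adaptive mode) or the plain k-nearest list (classic
SMOTE behaviour).  Every candidate carries full provenance so it can be
reconstructed, audited and traced back through inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .exceptions import DataFormatError

__all__ = ["SyntheticBatch", "interpolate", "generate_batch"]


@dataclass(frozen=True)
class SyntheticBatch:
    """Generated minority candidates with per-point provenance.

    ``points[j] == features[parent_index[j]] + u[j] *
    (features[neighbor_index[j]] - features[parent_index[j]])`` exactly up
    to floating rounding; indices are original dataset row positions.
    """

    points: np.ndarray  # (m, n_features)
    parent_index: np.ndarray  # (m,) int
    neighbor_index: np.ndarray  # (m,) int
    u: np.ndarray  # (m,) float in [0, 1]
    round_index: np.ndarray  # (m,) int generation round

    def __len__(self) -> int:
        return self.points.shape[0]

    def take(self, sel: np.ndarray) -> "SyntheticBatch":
        """Subset by boolean mask or index array, preserving order."""
        return SyntheticBatch(
            self.points[sel],
            self.parent_index[sel],
            self.neighbor_index[sel],
            self.u[sel],
            self.round_index[sel],
        )

    @staticmethod
    def empty(n_features: int) -> "SyntheticBatch":
        z = np.zeros(0, dtype=int)
        return SyntheticBatch(
            np.zeros((0, n_features)), z, z, np.zeros(0), z.copy()
        )

    @staticmethod
    def concat(batches: list["SyntheticBatch"]) -> "SyntheticBatch":
        return SyntheticBatch(
            np.concatenate([b.points for b in batches], axis=0),
            np.concatenate([b.parent_index for b in batches]),
            np.concatenate([b.neighbor_index for b in batches]),
            np.concatenate([b.u for b in batches]),
            np.concatenate([b.round_index for b in batches]),
        )

    def provenance_frame(self) -> pd.DataFrame:
        """Provenance as a DataFrame (CSV-exportable)."""
        return pd.DataFrame(
            {
                "parent_index": self.parent_index,
                "neighbor_index": self.neighbor_index,
                "u": self.u,
                "round": self.round_index,
            }
        )


def interpolate(parent, neighbor, u: float) -> np.ndarray:
    """Point at fraction ``u`` along the segment from parent to neighbor."""
    parent = np.asarray(parent, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if parent.shape != neighbor.shape:
        raise DataFormatError(
            f"dimension mismatch: {parent.shape} vs {neighbor.shape}"
        )
    return parent + u * (neighbor - parent)


def generate_batch(
    ds: LabeledDataset,
    eligible,
    n_per_point: int,
    rng: np.random.Generator,
    round_index: int = 0,
) -> SyntheticBatch:
    """Generate ``n_per_point`` candidates per minority point.

    Parameters
    ----------
    eligible
        A :class:`~sasmote.neighbors.VisibleSet` or
        :class:`~sasmote.neighbors.NeighborIndex`; anything exposing
        ``anchor_indices`` and ``eligible_lists()``.
    n_per_point
        Candidates generated from each minority parent (the N parameter).
    rng
        Source of randomness; the neighbor for each draw is chosen
        uniformly with replacement from the parent's eligible list and
        ``u`` uniformly from the unit interval.

    Notes
    -----
    Each draw picks its neighbor independently, so the N candidates of one
    parent may span several neighbors even when N exceeds the eligible
    list length.
    """
    anchors = np.asarray(eligible.anchor_indices)
    lists = eligible.eligible_lists()
    parents, nbrs = [], []
    for a, lst in zip(anchors, lists):
        lst = np.asarray(lst)
        if lst.size == 0:
            raise RuntimeError(f"empty eligible neighbor set for row {a}")
        parents.append(np.full(n_per_point, a))
        nbrs.append(lst[rng.integers(0, lst.size, size=n_per_point)])
    parent_index = np.concatenate(parents)
    neighbor_index = np.concatenate(nbrs)
    u = rng.random(len(parent_index))
    P = ds.features[parent_index]
    Q = ds.features[neighbor_index]
    points = P + u[:, None] * (Q - P)
    return SyntheticBatch(
        points=points,
        parent_index=parent_index,
        neighbor_index=neighbor_index,
        u=u,
        round_index=np.full(len(parent_index), round_index, dtype=int),
    )
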