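"""Global feature stream: saliency masking of deep descriptors.

The observation behind the stream is that a spatial position where many
channels fire at once is likely to lie on the salient object.  Summing the
activation tensor over channels gives the h x w *aggregation map* ``A``;
its mean value δ is the saliency threshold.  Positions with ``A[i,j] > δ``
(strictly) form the mask map, the largest connected component of the mask is
taken as the object region, and the global feature ``fG`` is the
concatenation of per-channel max-pooling and average-pooling restricted to
that region — a 2d-dimensional vector.

Degenerate inputs (constant maps, empty masks) fall back to pooling over the
whole grid, which is exactly unselected full-grid pooling, with a logged
warning.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from typing import Iterable

import numpy as np

from .features import ActivationTensor, flat_index

logger = logging.getLogger(__name__)

__all__ = [
    "AggregationMap",
    "MaskMap",
    "Region",
    "StreamFeature",
    "EmptyMaskError",
    "compute_aggregation_map",
    "threshold_mask",
    "connected_components",
    "largest_component",
    "pool_region",
    "full_grid_region",
    "global_feature",
]


class EmptyMaskError(ValueError):
    """The mask selected no position; callers apply the full-grid fallback."""


@dataclasses.dataclass(frozen=True)
class AggregationMap:
    """Per-position channel sums and their mean δ."""

    values: np.ndarray  # h x w
    mean: float


@dataclasses.dataclass(frozen=True)
class MaskMap:
    """Binary map of positions whose aggregate response strictly exceeds δ."""

    values: np.ndarray  # h x w, uint8 in {0, 1}

    @property
    def h(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass(frozen=True)
class Region:
    """A set of mutually connected selected positions."""

    positions: frozenset[tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.positions)


@dataclasses.dataclass(frozen=True)
class StreamFeature:
    """A 2d-dim pooled feature: max-pool half first, then avg-pool half."""

    vector: np.ndarray
    stream: str  # "global" | "local" | "original"


def compute_aggregation_map(tensor: ActivationTensor) -> AggregationMap:
    """Sum the tensor over the channel axis and record the grid mean δ."""
    values = tensor.values.sum(axis=2)
    return AggregationMap(values=values, mean=float(values.mean()))


def threshold_mask(agg: AggregationMap) -> MaskMap:
    """Mark positions strictly above the mean δ.

    Strictness matters: a constant map produces an all-zero mask rather than
    an all-one mask, which the fallback then degrades to full-grid pooling.
    """
    return MaskMap(values=(agg.values > agg.mean).astype(np.uint8))


_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def connected_components(mask: MaskMap, connectivity: int = 8) -> list[Region]:
    """All connected components of the mask's 1-cells, by BFS flood fill."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    h, w = mask.values.shape
    seen = np.zeros((h, w), dtype=bool)
    components: list[Region] = []
    for r in range(h):
        for c in range(w):
            if mask.values[r, c] == 0 or seen[r, c]:
                continue
            queue = deque([(r, c)])
            seen[r, c] = True
            member: list[tuple[int, int]] = []
            while queue:
                rr, cc = queue.popleft()
                member.append((rr, cc))
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask.values[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            components.append(Region(frozenset(member)))
    return components


def largest_component(mask: MaskMap, connectivity: int = 8) -> Region:
    """Maximum-cardinality component; ties go to the one holding the
    smallest row-major flat id, for determinism."""
    components = connected_components(mask, connectivity)
    if not components:
        raise EmptyMaskError("mask selects no position")
    w = mask.w
    return max(
        components,
        key=lambda reg: (reg.size, -min(flat_index(r, c, w) for r, c in reg.positions)),
    )


def full_grid_region(tensor: ActivationTensor) -> Region:
    return Region(frozenset((r, c) for r in range(tensor.h) for c in range(tensor.w)))


def pool_region(tensor: ActivationTensor, region: Region, stream: str = "global") -> StreamFeature:
    """Concatenate per-channel max then per-channel mean over the region."""
    if region.size == 0:
        raise ValueError("cannot pool an empty region; apply the fallback first")
    rows, cols = zip(*sorted(region.positions))
    descriptors = tensor.values[np.array(rows), np.array(cols), :]  # k x d
    vector = np.concatenate([descriptors.max(axis=0), descriptors.mean(axis=0)])
    return StreamFeature(vector=vector, stream=stream)


def global_feature(tensor: ActivationTensor, connectivity: int = 8) -> StreamFeature:
    """fG: pool the largest connected component of the saliency mask.

    Falls back to full-grid pooling (with a warning) when the mask is empty,
    e.g. for a constant aggregation map.
    """
    agg = compute_aggregation_map(tensor)
    mask = threshold_mask(agg)
    try:
        region = largest_component(mask, connectivity)
    except EmptyMaskError:
        logger.warning("empty saliency mask; falling back to full-grid pooling")
        region = full_grid_region(tensor)
    return pool_region(tensor, region, stream="global")
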