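"""Synthetic activation tensors with planted, bookkept structure.

Real activation tensors of a rectified convolutional layer are sparse and
non-negative: a salient object raises the channel-sum at its footprint well
above the grid mean, and recurring object parts co-activate the same spatial
positions across many channels.  The generator emulates exactly those two
statistics with full ground truth:

* a **blob plant** writes a high, connected footprint into a set of
  dedicated channels, so the channel-sum mask recovers the footprint;
* a **part plant** writes a position set S into s dedicated channels (and
  nothing else into them), so each of those channels binarizes to exactly S
  and the itemset S has support exactly s;
* **noise channels** activate a few random positions each, with bookkeeping
  that caps every noise item's total support, so planted-pattern recovery
  tests are exact rather than probabilistic.

Channel sets of the plants must be disjoint, part positions must not sit
wholly inside the blob footprint, and noise avoids part positions — the
validation rejects specs whose ground truth would otherwise be ambiguous.

The module also hosts the brute-force frequent-itemset enumerator used as
the independent oracle for the FP-growth miner.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np

from .features import ActivationTensor, flat_index, position_of
from .local_stream import FrequentPattern, PatternSet, TransactionDB, filter_maximal

__all__ = [
    "BlobPlant",
    "PartPlant",
    "NoiseSpec",
    "SceneSpec",
    "SyntheticCorpus",
    "SceneSpecError",
    "generate_tensor",
    "generate_corpus",
    "brute_force_patterns",
]


class SceneSpecError(ValueError):
    """A scene spec plants contradictory or infeasible structure."""


@dataclasses.dataclass(frozen=True)
class BlobPlant:
    """A connected salient footprint written into dedicated channels."""

    footprint: frozenset[tuple[int, int]]
    channels: tuple[int, ...]
    level: float = 3.0


@dataclasses.dataclass(frozen=True)
class PartPlant:
    """A co-activated position set S planted into s dedicated channels."""

    positions: frozenset[int]  # flat ids
    channels: tuple[int, ...]
    level: float = 5.0

    @property
    def planted_support(self) -> int:
        return len(self.channels)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Random sparse activations with a hard per-item support cap.

    With ``jitter`` the per-item amplitude is drawn uniformly from
    ``[0.2*level, level]`` instead of being the constant ``level``, emulating
    clutter channels whose strongest response varies image to image.
    """

    channels: tuple[int, ...]
    items_per_channel: int = 3
    level: float = 1.0
    max_item_support: int = 1
    jitter: bool = False


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    h: int
    w: int
    d: int
    blob: BlobPlant | None = None
    parts: tuple[PartPlant, ...] = ()
    noise: NoiseSpec | None = None
    background: float = 0.0  # dense low-level noise on blob channels, < mask mean
    seed: int = 0

    def __post_init__(self) -> None:
        used: set[int] = set()
        groups: list[tuple[int, ...]] = []
        if self.blob is not None:
            groups.append(self.blob.channels)
            for r, c in self.blob.footprint:
                if not (0 <= r < self.h and 0 <= c < self.w):
                    raise SceneSpecError(f"blob position {(r, c)} outside {self.h}x{self.w}")
        for part in self.parts:
            groups.append(part.channels)
            if not part.positions:
                raise SceneSpecError("empty part position set")
            for i in part.positions:
                if not (0 <= i < self.h * self.w):
                    raise SceneSpecError(f"part flat id {i} outside grid")
            blob_flats = self._blob_flats()
            if blob_flats is not None and part.positions <= blob_flats:
                raise SceneSpecError(
                    "part positions wholly inside the blob footprint would "
                    "inflate the planted support"
                )
        if self.noise is not None:
            groups.append(self.noise.channels)
        for channels in groups:
            if not channels:
                raise SceneSpecError("a plant needs at least one channel")
            if any(not (0 <= ch < self.d) for ch in channels):
                raise SceneSpecError("plant channel outside tensor depth")
            if used & set(channels):
                raise SceneSpecError("plants share channels; ground truth would be ambiguous")
            used |= set(channels)

    def _blob_flats(self) -> frozenset[int] | None:
        if self.blob is None:
            return None
        return frozenset(flat_index(r, c, self.w) for r, c in self.blob.footprint)


@dataclasses.dataclass(frozen=True)
class SyntheticCorpus:
    tensors: dict[str, ActivationTensor]
    labels: dict[str, str]
    class_specs: dict[str, tuple[SceneSpec, ...]]


def generate_tensor(spec: SceneSpec) -> ActivationTensor:
    """Deterministic (seeded) tensor realizing every plant in the spec."""
    rng = np.random.default_rng(spec.seed)
    values = np.zeros((spec.h, spec.w, spec.d))

    if spec.blob is not None:
        rows, cols = zip(*sorted(spec.blob.footprint))
        for ch in spec.blob.channels:
            values[np.array(rows), np.array(cols), ch] = spec.blob.level
            if spec.background > 0:
                # dense low-level clutter kept strictly below the plant level
                values[:, :, ch] += rng.uniform(0, spec.background, (spec.h, spec.w))

    for part in spec.parts:
        coords = [position_of(i, spec.w) for i in sorted(part.positions)]
        rows, cols = zip(*coords)
        for ch in part.channels:
            values[np.array(rows), np.array(cols), ch] = part.level

    if spec.noise is not None:
        # Noise is background clutter: it never overwrites planted structure,
        # so a plant's recorded ground truth stays exact.
        planted: set[int] = set()
        for part in spec.parts:
            planted |= part.positions
        blob_flats = spec._blob_flats()
        if blob_flats is not None:
            planted |= blob_flats
        eligible = [i for i in range(spec.h * spec.w) if i not in planted]
        item_counts: dict[int, int] = {}
        for ch in spec.noise.channels:
            open_items = [
                i for i in eligible
                if item_counts.get(i, 0) < spec.noise.max_item_support
            ]
            take = min(spec.noise.items_per_channel, len(open_items))
            if take == 0:
                continue
            chosen = rng.choice(open_items, size=take, replace=False)
            for i in chosen:
                r, c = position_of(int(i), spec.w)
                if spec.noise.jitter:
                    values[r, c, ch] = rng.uniform(0.2 * spec.noise.level, spec.noise.level)
                else:
                    values[r, c, ch] = spec.noise.level
                item_counts[int(i)] = item_counts.get(int(i), 0) + 1

    return ActivationTensor(values)


def _rect_footprint(r0: int, c0: int, hh: int, ww: int) -> frozenset[tuple[int, int]]:
    return frozenset((r, c) for r in range(r0, r0 + hh) for c in range(c0, c0 + ww))


def generate_corpus(
    n_classes: int = 4,
    n_per_class: int = 5,
    shape: tuple[int, int, int] = (7, 7, 64),
    seed: int = 0,
    part_size: int = 3,
    part_channels: int = 6,
    blob_channels: int = 12,
    noise_channels: int = 28,
) -> SyntheticCorpus:
    """A labeled corpus whose classes differ only by their planted part sets.

    The construction realizes the fine-grained premise — small interclass
    distinction, large intraclass variance — in controllable form.  Every
    class shares the same blob statistics (a 3x3 footprint jittered per
    image within the upper rows, with per-image amplitude variation).  Each
    class owns a distinct position set in the bottom rows and a distinct
    channel block for its part plant, at activation levels comparable to the
    blob's: the interclass signal is carried purely by co-activation
    structure and is deliberately modest.  Clutter channels resample per
    image, each firing one strong (but sub-threshold in the channel-sum
    aggregate) item away from all planted structure — intraclass variance
    that full-grid pooling absorbs and region-restricted pooling never sees.
    """
    if n_classes < 2 or n_per_class < 2:
        raise SceneSpecError("need at least 2 classes and 2 images per class")
    h, w, d = shape
    part_rows = 2  # bottom rows reserved for part positions
    blob_h = blob_w = 3
    if h < blob_h + part_rows or w < blob_w:
        raise SceneSpecError(f"grid {h}x{w} too small for blob plus part rows")
    pool = [flat_index(r, c, w) for r in range(h - part_rows, h) for c in range(w)]
    if n_classes * part_size > len(pool):
        raise SceneSpecError(
            f"cannot pack {n_classes} disjoint part sets of size {part_size} "
            f"into {len(pool)} bottom-row positions"
        )
    need = blob_channels + n_classes * part_channels + noise_channels
    if need > d:
        raise SceneSpecError(f"channel budget {need} exceeds depth {d}")

    master = np.random.default_rng(seed)
    shuffled = master.permutation(pool)
    class_positions = [
        frozenset(int(i) for i in shuffled[k * part_size : (k + 1) * part_size])
        for k in range(n_classes)
    ]
    blob_chs = tuple(range(blob_channels))
    noise_chs = tuple(range(d - noise_channels, d)) if noise_channels else ()

    tensors: dict[str, ActivationTensor] = {}
    labels: dict[str, str] = {}
    class_specs: dict[str, tuple[SceneSpec, ...]] = {}
    for k in range(n_classes):
        label = f"class{k}"
        part_chs = tuple(range(blob_channels + k * part_channels,
                               blob_channels + (k + 1) * part_channels))
        specs = []
        for j in range(n_per_class):
            img_rng = np.random.default_rng(master.integers(2**31))
            r0 = int(img_rng.integers(0, h - part_rows - blob_h + 1))
            c0 = int(img_rng.integers(0, w - blob_w + 1))
            blob = BlobPlant(
                footprint=_rect_footprint(r0, c0, blob_h, blob_w),
                channels=blob_chs,
                level=float(img_rng.uniform(2.4, 3.6)),
            )
            part = PartPlant(
                positions=class_positions[k],
                channels=part_chs,
                level=float(img_rng.uniform(2.8, 3.6)),
            )
            noise = (
                NoiseSpec(channels=noise_chs, items_per_channel=1, level=10.0,
                          max_item_support=1, jitter=True)
                if noise_chs else None
            )
            spec = SceneSpec(
                h=h, w=w, d=d, blob=blob, parts=(part,), noise=noise,
                background=0.3, seed=int(img_rng.integers(2**31)),
            )
            specs.append(spec)
            key = f"c{k}_i{j}"
            tensors[key] = generate_tensor(spec)
            labels[key] = label
        class_specs[label] = tuple(specs)
    return SyntheticCorpus(tensors=tensors, labels=labels, class_specs=class_specs)


# ---------------------------------------------------------------------------
# brute-force mining oracle
# ---------------------------------------------------------------------------


def brute_force_patterns(db: TransactionDB, minsupp: int, mode: str = "all") -> PatternSet:
    """Exhaustive enumeration of every non-empty frequent itemset.

    Ground truth for the FP-growth miner on small universes; refuses more
    than 20 items (2^n blowup).
    """
    universe = sorted(db.item_universe)
    if len(universe) > 20:
        raise ValueError(f"brute force refuses {len(universe)} items (> 20)")
    found = []
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            items = frozenset(combo)
            supp = sum(1 for t in db.transactions if items <= t.items)
            if supp >= minsupp:
                found.append(FrequentPattern(items, supp))
    if mode == "maximal":
        found = filter_maximal(found)
    ordered = tuple(sorted(found, key=lambda p: (-p.support, tuple(sorted(p.items)))))
    return PatternSet(patterns=ordered, mode=mode)
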