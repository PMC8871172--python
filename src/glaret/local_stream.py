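"""Local feature stream: frequent-pattern mining of co-activated positions.

Each of the ``d`` feature maps of an activation tensor is binarized at its
own mean: positions strictly above the mean are *activated*.  A feature map
then becomes a *transaction* whose *items* are its activated positions
(row-major flat ids), giving a transaction database with ``m = d``
transactions over at most ``h*w`` items.  The support of an itemset is the
number of transactions containing it (an absolute count); itemsets with
support >= ``minsupp`` are frequent.  Mining uses an FP-tree — a prefix
tree over transactions with items sorted by decreasing support — and the
FP-growth recursion over conditional pattern bases.

Spatial positions that recur together across many channels are co-activated
object parts; the union of positions appearing in the maximal frequent
patterns (the *support mask*) is pooled — per-channel max then mean — into
the local feature ``fL``.  Unioning all frequent patterns instead of only
maximal ones yields the same mask, since every frequent item is itself a
singleton frequent pattern contained in some maximal one.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

from .features import ActivationTensor, position_of
from .global_stream import Region, StreamFeature, full_grid_region, pool_region

logger = logging.getLogger(__name__)

__all__ = [
    "Transaction",
    "TransactionDB",
    "FPNode",
    "FPTree",
    "FrequentPattern",
    "PatternSet",
    "MiningExplosionError",
    "binarize_feature_map",
    "build_transactions",
    "support",
    "build_fp_tree",
    "fp_growth",
    "mine_patterns",
    "filter_maximal",
    "local_feature",
    "read_transactions",
    "write_transactions",
    "write_patterns",
]

DEFAULT_PATTERN_CAP = 1_000_000


class MiningExplosionError(RuntimeError):
    """The number of frequent patterns exceeded the configured cap."""


@dataclasses.dataclass(frozen=True)
class Transaction:
    map_index: int
    items: frozenset[int]


@dataclasses.dataclass(frozen=True)
class TransactionDB:
    """m transactions (one per feature map) over the activated-position items.

    Empty transactions are retained: they count toward m but can never
    contribute to a pattern.
    """

    transactions: tuple[Transaction, ...]

    @property
    def m(self) -> int:
        return len(self.transactions)

    @property
    def item_universe(self) -> frozenset[int]:
        out: set[int] = set()
        for t in self.transactions:
            out |= t.items
        return frozenset(out)

    @classmethod
    def from_itemsets(cls, itemsets: Iterable[Iterable[int]]) -> "TransactionDB":
        return cls(
            transactions=tuple(
                Transaction(i, frozenset(items)) for i, items in enumerate(itemsets)
            )
        )


@dataclasses.dataclass(frozen=True)
class FrequentPattern:
    items: frozenset[int]
    support: int


@dataclasses.dataclass(frozen=True)
class PatternSet:
    """Mined patterns in canonical order plus the pooled-position mask."""

    patterns: tuple[FrequentPattern, ...]
    mode: str  # "all" | "maximal"

    @property
    def support_mask(self) -> frozenset[int]:
        out: set[int] = set()
        for p in self.patterns:
            out |= p.items
        return frozenset(out)


def binarize_feature_map(tensor: ActivationTensor, channel: int) -> frozenset[int]:
    """Flat ids of positions whose response strictly exceeds the channel mean."""
    fmap = tensor.values[:, :, channel]
    active = np.flatnonzero(fmap > fmap.mean())
    return frozenset(int(i) for i in active)


def build_transactions(tensor: ActivationTensor) -> TransactionDB:
    """One transaction per feature map; items are its activated positions."""
    return TransactionDB(
        transactions=tuple(
            Transaction(ch, binarize_feature_map(tensor, ch)) for ch in range(tensor.d)
        )
    )


def support(items: Iterable[int], db: TransactionDB) -> int:
    """Number of transactions containing every item (Σ over t of [items ⊆ t])."""
    itemset = frozenset(items)
    return sum(1 for t in db.transactions if itemset <= t.items)


# ---------------------------------------------------------------------------
# FP-tree
# ---------------------------------------------------------------------------


class FPNode:
    """One prefix-tree node: an item label, a routed-transaction count,
    parent/children links, and a node-link chaining same-label nodes."""

    __slots__ = ("label", "count", "parent", "children", "link")

    def __init__(self, label: int | None, parent: "FPNode | None") -> None:
        self.label = label
        self.count = 0
        self.parent = parent
        self.children: dict[int, FPNode] = {}
        self.link: FPNode | None = None


class FPTree:
    """Prefix tree over support-sorted transactions with per-item header chains."""

    def __init__(self, minsupp: int) -> None:
        self.minsupp = minsupp
        self.root = FPNode(None, None)
        self.header: dict[int, FPNode] = {}
        self._header_tail: dict[int, FPNode] = {}
        self.item_support: dict[int, int] = {}
        self.item_order: list[int] = []

    @classmethod
    def from_weighted(
        cls, itemsets: Sequence[tuple[frozenset[int], int]], minsupp: int
    ) -> "FPTree":
        """Build from (itemset, weight) pairs: count item supports, drop
        infrequent items, sort survivors by decreasing support (ties by
        ascending item id), and insert shared prefixes with merged counts."""
        tree = cls(minsupp)
        counts: dict[int, int] = {}
        for items, weight in itemsets:
            for item in items:
                counts[item] = counts.get(item, 0) + weight
        tree.item_support = {i: s for i, s in counts.items() if s >= minsupp}
        tree.item_order = sorted(tree.item_support, key=lambda i: (-tree.item_support[i], i))
        rank = {item: k for k, item in enumerate(tree.item_order)}
        for items, weight in itemsets:
            kept = sorted((i for i in items if i in rank), key=rank.__getitem__)
            tree._insert(kept, weight)
        return tree

    def _insert(self, items: Sequence[int], weight: int) -> None:
        node = self.root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                if item in self.header:
                    self._header_tail[item].link = child
                else:
                    self.header[item] = child
                self._header_tail[item] = child
            child.count += weight
            node = child

    def header_chain(self, item: int) -> Iterable[FPNode]:
        node = self.header.get(item)
        while node is not None:
            yield node
            node = node.link

    def prefix_path(self, node: FPNode) -> frozenset[int]:
        """Items on the path from the node's parent up to (not incl.) the root."""
        items: list[int] = []
        cur = node.parent
        while cur is not None and cur.label is not None:
            items.append(cur.label)
            cur = cur.parent
        return frozenset(items)


def build_fp_tree(db: TransactionDB, minsupp: int) -> FPTree:
    if minsupp < 1:
        raise ValueError("minsupp must be >= 1 to build an FP-tree")
    return FPTree.from_weighted([(t.items, 1) for t in db.transactions], minsupp)


# ---------------------------------------------------------------------------
# FP-growth
# ---------------------------------------------------------------------------


def _grow(
    tree: FPTree,
    suffix: frozenset[int],
    minsupp: int,
    out: list[FrequentPattern],
    cap: int,
) -> None:
    # Visit items least-frequent first, the classic bottom-up order.
    for item in reversed(tree.item_order):
        pattern = suffix | {item}
        out.append(FrequentPattern(pattern, tree.item_support[item]))
        if len(out) > cap:
            raise MiningExplosionError(
                f"more than {cap} frequent patterns at minsupp={minsupp}; "
                "raise minsupp or the pattern cap"
            )
        base = [(tree.prefix_path(node), node.count) for node in tree.header_chain(item)]
        cond = FPTree.from_weighted(base, minsupp)
        if cond.item_order:
            _grow(cond, pattern, minsupp, out, cap)


def fp_growth(
    tree: FPTree,
    minsupp: int,
    mode: str = "all",
    pattern_cap: int = DEFAULT_PATTERN_CAP,
) -> PatternSet:
    """Mine all frequent itemsets (with exact supports) from an FP-tree.

    ``mode="maximal"`` retains only subset-maximal itemsets.  Output is
    canonically ordered by descending support, then lexicographic item
    tuples, so repeated runs are bit-identical.
    """
    if mode not in ("all", "maximal"):
        raise ValueError(f"mode must be 'all' or 'maximal', got {mode!r}")
    found: list[FrequentPattern] = []
    _grow(tree, frozenset(), minsupp, found, pattern_cap)
    if mode == "maximal":
        found = filter_maximal(found)
    ordered = tuple(sorted(found, key=lambda p: (-p.support, tuple(sorted(p.items)))))
    return PatternSet(patterns=ordered, mode=mode)


def filter_maximal(patterns: Sequence[FrequentPattern]) -> list[FrequentPattern]:
    """Drop every itemset that is a subset of another mined itemset."""
    by_size = sorted(patterns, key=lambda p: -len(p.items))
    kept: list[FrequentPattern] = []
    for p in by_size:
        if not any(p.items < q.items for q in kept):
            kept.append(p)
    return kept


def mine_patterns(
    db: TransactionDB,
    minsupp: int,
    mode: str = "maximal",
    pattern_cap: int = DEFAULT_PATTERN_CAP,
) -> PatternSet:
    """Convenience: FP-tree construction followed by FP-growth.

    ``minsupp=0`` is clamped to 1 with a warning — a support >= 0 constraint
    is vacuous and would enumerate the power set.
    """
    if minsupp < 1:
        logger.warning("minsupp=%d is vacuous; clamping to 1", minsupp)
        minsupp = 1
    return fp_growth(build_fp_tree(db, minsupp), minsupp, mode=mode, pattern_cap=pattern_cap)


def local_feature(
    tensor: ActivationTensor,
    minsupp: int = 2,
    mode: str = "maximal",
    pattern_cap: int = DEFAULT_PATTERN_CAP,
) -> StreamFeature:
    """fL: pool the union of positions in the mined frequent patterns.

    Falls back to full-grid pooling (with a warning) when nothing is
    frequent, mirroring the global stream's degenerate-input behaviour.
    """
    db = build_transactions(tensor)
    patterns = mine_patterns(db, minsupp, mode=mode, pattern_cap=pattern_cap)
    mask = patterns.support_mask
    if not mask:
        logger.warning(
            "no frequent pattern at minsupp=%d; falling back to full-grid pooling", minsupp
        )
        region = full_grid_region(tensor)
    else:
        region = Region(frozenset(position_of(i, tensor.w) for i in mask))
    return pool_region(tensor, region, stream="local")


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------


def write_transactions(db: TransactionDB, path) -> None:
    """One transaction per line, whitespace-separated integer item ids
    (the de-facto FIMI format); empty transactions become empty lines."""
    with open(path, "w") as fh:
        for t in db.transactions:
            fh.write(" ".join(str(i) for i in sorted(t.items)) + "\n")


def read_transactions(path) -> TransactionDB:
    with open(path) as fh:
        itemsets = [[int(tok) for tok in line.split()] for line in fh]
    return TransactionDB.from_itemsets(itemsets)


def write_patterns(patterns: PatternSet, path) -> None:
    """TSV pattern report: space-joined items, support; canonical order."""
    with open(path, "w") as fh:
        fh.write("items\tsupport\n")
        for p in patterns.patterns:
            fh.write(" ".join(str(i) for i in sorted(p.items)) + f"\t{p.support}\n")
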