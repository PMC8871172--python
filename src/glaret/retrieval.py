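"""Feature aggregation, cosine ranking, and mAP evaluation.

The two stream features are combined as F = fG + α·fL, where α weighs the
local evidence against the global one (α = 0 recovers the pure global
representation).  Query/database relevance is plain cosine similarity

    S(F_Q, F_D) = F_Q·F_D / (|F_Q| |F_D|),

and retrieval quality is measured by mean average precision over a
leave-one-out protocol: every corpus image queries the remaining ones, the
query's own entry is excluded from its ranking, and

    AP = (1/R) Σ_k p(k)·rel(k),        mAP = (1/Q) Σ_q AP(q),

with R the number of relevant (same-label) database images, p(k) the
precision among the top k results and rel(k) the 0/1 relevance at rank k.
AP sums over the full ranked database; the display cutoff K never caps
evaluation.

Features are not normalized before aggregation by default (the literal
aggregation rule); ``normalize=True`` L2-normalizes fG and fL first, a
documented deviation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import h5py
import numpy as np

from .features import ActivationTensor
from .global_stream import StreamFeature, full_grid_region, global_feature, pool_region
from .local_stream import DEFAULT_PATTERN_CAP, local_feature

logger = logging.getLogger(__name__)

__all__ = [
    "AggregatedFeature",
    "IndexEntry",
    "RankedList",
    "EvalReport",
    "MODES",
    "aggregate",
    "similarity",
    "rank",
    "average_precision",
    "mean_average_precision",
    "original_feature",
    "compute_feature",
    "build_index",
    "evaluate_index",
    "run_ablation",
    "save_index",
    "load_index",
]

MODES = ("original", "global", "local", "global_local")


@dataclasses.dataclass(frozen=True)
class AggregatedFeature:
    vector: np.ndarray
    alpha: float


@dataclasses.dataclass(frozen=True)
class IndexEntry:
    id: str
    feature: AggregatedFeature
    label: str | None = None


@dataclasses.dataclass(frozen=True)
class RankedList:
    query_id: str
    entries: tuple[tuple[str, float], ...]  # (id, score), scores non-increasing
    K: int


@dataclasses.dataclass(frozen=True)
class EvalReport:
    per_query_ap: dict[str, float]
    map_score: float
    Q: int
    skipped: tuple[str, ...] = ()


def aggregate(fG: StreamFeature, fL: StreamFeature, alpha: float) -> AggregatedFeature:
    """F = fG + α·fL, elementwise."""
    if fG.vector.shape != fL.vector.shape:
        raise ValueError(
            f"stream feature length mismatch: {fG.vector.shape} vs {fL.vector.shape}"
        )
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return AggregatedFeature(vector=fG.vector + alpha * fL.vector, alpha=alpha)


def similarity(fq: AggregatedFeature, fd: AggregatedFeature) -> float:
    """Cosine similarity; a zero-norm vector scores 0 with a warning."""
    nq = float(np.linalg.norm(fq.vector))
    nd = float(np.linalg.norm(fd.vector))
    if nq == 0.0 or nd == 0.0:
        logger.warning("zero-norm feature in similarity; scoring 0")
        return 0.0
    return float(np.dot(fq.vector, fd.vector) / (nq * nd))


def rank(
    query: AggregatedFeature,
    query_id: str,
    index: Sequence[IndexEntry],
    K: int | None = None,
) -> RankedList:
    """Score the index, sort descending (ties by ascending id), drop self."""
    if not index:
        raise ValueError("cannot rank against an empty index")
    scored = [
        (entry.id, similarity(query, entry.feature))
        for entry in index
        if entry.id != query_id
    ]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    cutoff = len(scored) if K is None else max(1, K)
    return RankedList(query_id=query_id, entries=tuple(scored[:cutoff]), K=cutoff)


def average_precision(ranked: RankedList, relevant_ids: frozenset | set) -> float:
    """AP = (1/R) Σ p(k)·rel(k) over the whole ranked list."""
    listed = [rid for rid, _ in ranked.entries]
    R = len(relevant_ids & set(listed))
    if R == 0:
        raise ValueError(f"query {ranked.query_id!r} has no relevant database image")
    hits = 0
    total = 0.0
    for k, rid in enumerate(listed, start=1):
        if rid in relevant_ids:
            hits += 1
            total += hits / k
    return total / R


def mean_average_precision(aps: Sequence[float]) -> float:
    if not aps:
        raise ValueError("mAP over zero queries is undefined")
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# feature computation per ablation mode
# ---------------------------------------------------------------------------


def original_feature(tensor: ActivationTensor) -> StreamFeature:
    """Full-grid max+avg pooling with no descriptor selection at all."""
    return pool_region(tensor, full_grid_region(tensor), stream="original")


def _maybe_normalize(feat: StreamFeature, normalize: bool) -> StreamFeature:
    if not normalize:
        return feat
    norm = np.linalg.norm(feat.vector)
    if norm == 0:
        return feat
    return StreamFeature(vector=feat.vector / norm, stream=feat.stream)


def compute_feature(
    tensor: ActivationTensor,
    mode: str = "global_local",
    minsupp: int = 2,
    alpha: float = 1.0,
    connectivity: int = 8,
    normalize: bool = False,
    pattern_cap: int = DEFAULT_PATTERN_CAP,
) -> AggregatedFeature:
    """The representation one ablation arm assigns to a tensor."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "original":
        return AggregatedFeature(vector=original_feature(tensor).vector, alpha=0.0)
    if mode == "global":
        fG = _maybe_normalize(global_feature(tensor, connectivity), normalize)
        return AggregatedFeature(vector=fG.vector, alpha=0.0)
    if mode == "local":
        fL = _maybe_normalize(local_feature(tensor, minsupp, pattern_cap=pattern_cap), normalize)
        return AggregatedFeature(vector=fL.vector, alpha=0.0)
    fG = _maybe_normalize(global_feature(tensor, connectivity), normalize)
    fL = _maybe_normalize(local_feature(tensor, minsupp, pattern_cap=pattern_cap), normalize)
    return aggregate(fG, fL, alpha)


def build_index(
    tensors: Mapping[str, ActivationTensor],
    labels: Mapping[str, str] | None = None,
    mode: str = "global_local",
    minsupp: int = 2,
    alpha: float = 1.0,
    connectivity: int = 8,
    normalize: bool = False,
) -> list[IndexEntry]:
    """One IndexEntry per tensor, in sorted-id order."""
    entries = []
    for key in sorted(tensors):
        feature = compute_feature(
            tensors[key], mode=mode, minsupp=minsupp, alpha=alpha,
            connectivity=connectivity, normalize=normalize,
        )
        entries.append(
            IndexEntry(id=key, feature=feature, label=None if labels is None else labels[key])
        )
    return entries


def evaluate_index(index: Sequence[IndexEntry]) -> EvalReport:
    """Leave-one-out mAP: each entry queries all the others; relevance is
    label equality.  Queries with no same-label database image are skipped
    with a warning and recorded in the report."""
    if any(entry.label is None for entry in index):
        raise ValueError("every index entry needs a label for evaluation")
    per_query: dict[str, float] = {}
    skipped: list[str] = []
    for entry in index:
        relevant = {e.id for e in index if e.id != entry.id and e.label == entry.label}
        if not relevant:
            logger.warning("query %r has no relevant image; skipping", entry.id)
            skipped.append(entry.id)
            continue
        ranked = rank(entry.feature, entry.id, index)
        per_query[entry.id] = average_precision(ranked, relevant)
    if not per_query:
        raise ValueError("no valid query (every image is its class's only member)")
    return EvalReport(
        per_query_ap=per_query,
        map_score=mean_average_precision(list(per_query.values())),
        Q=len(per_query),
        skipped=tuple(skipped),
    )


def run_ablation(
    tensors: Mapping[str, ActivationTensor],
    labels: Mapping[str, str],
    minsupp: int = 2,
    alpha: float = 1.0,
    connectivity: int = 8,
    normalize: bool = False,
) -> dict[str, float]:
    """Leave-one-out mAP for each of the four representation arms
    (no selection / global stream / local stream / aggregated), on the same
    query-database split."""
    n_labels = len(set(labels.values()))
    if n_labels < 2:
        logger.warning("single-class corpus: every mAP is trivially 1")
    out: dict[str, float] = {}
    for mode in MODES:
        index = build_index(
            tensors, labels, mode=mode, minsupp=minsupp, alpha=alpha,
            connectivity=connectivity, normalize=normalize,
        )
        out[mode] = evaluate_index(index).map_score
    return out


# ---------------------------------------------------------------------------
# index persistence: HDF5 features + TSV (id, label) sidecar
# ---------------------------------------------------------------------------


def save_index(index: Sequence[IndexEntry], h5_path, labels_path=None) -> None:
    with h5py.File(h5_path, "w") as f:
        for entry in index:
            ds = f.create_dataset(entry.id, data=entry.feature.vector)
            ds.attrs["alpha"] = entry.feature.alpha
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for entry in index:
                fh.write(f"{entry.id}\t{entry.label if entry.label is not None else ''}\n")


def load_index(h5_path, labels_path=None) -> list[IndexEntry]:
    labels: dict[str, str] = {}
    if labels_path is not None:
        with open(labels_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line:
                    key, label = line.split("\t")
                    labels[key] = label
    entries = []
    with h5py.File(h5_path, "r") as f:
        for key in sorted(f.keys()):
            feature = AggregatedFeature(
                vector=f[key][()], alpha=float(f[key].attrs.get("alpha", 0.0))
            )
            entries.append(IndexEntry(id=key, feature=feature, label=labels.get(key)))
    return entries
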