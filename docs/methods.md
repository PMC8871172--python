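# Methods

## Model

The package represents an image by statistics of a rectified convolutional
activation tensor `T ∈ R^{h×w×d}` (non-negative, finite; enforced at the
`ActivationTensor` boundary and assumed downstream). `T` is viewed both as
`d` feature maps of size `h×w` and as `h·w` deep descriptors of dimension
`d`. Two selection mechanisms produce complementary features, both pooled
the same way: per-channel maximum concatenated with per-channel mean over a
set of spatial positions, giving a `2d`-dimensional vector (max half first).

**Global stream.** The aggregation map `A_{ij} = Σ_c T_{ijc}` scores how
many channels fire at a position; its mean `δ` is the saliency threshold.
The mask keeps positions with `A_{ij} > δ` — strictly, so a constant map
yields an *empty* mask rather than an all-one mask. BFS flood fill labels
the mask's connected components and the largest is the object region
(`f_G` pools it). Defaults and edge rules:

* **Connectivity** defaults to 8-neighborhood (configurable to 4): on
  coarse grids such as 7×7 the more inclusive neighborhood avoids splitting
  an object across a diagonal step.
* **Ties** between equal-size components go to the component containing the
  smallest row-major flat index — an arbitrary but deterministic rule.
* **Empty mask or region** falls back to pooling over all `h·w` positions
  with a logged warning; the representation then degrades gracefully to
  plain unselected pooling rather than failing.
* Pooling is **region-restricted** (only descriptors at region positions
  enter the max/mean), not masked-full-grid pooling; the two differ for the
  average half, and region restriction is the reading under which a
  single-position region behaves sensibly. The alternative was considered
  and rejected rather than made a silent default.

**Local stream.** Each feature map is binarized at its own mean (strict
inequality again); the map becomes a transaction whose items are its
activated positions (0-based row-major flat ids). Over the `m = d`
transactions, the support of an itemset is the number of transactions
containing it — an **absolute count**, not a fraction; `minsupp` is
likewise a count. Empty transactions stay in `m` but never enter the tree.
Mining is exact FP-growth:

* The FP-tree inserts each transaction with infrequent items removed and
  the rest sorted by decreasing support, ties broken by ascending item id
  (deterministic tree shape). Per-item header chains link same-label nodes;
  the chain's count sum equals the item's support (asserted as a test
  invariant).
* FP-growth recurses over conditional pattern bases, visiting items
  least-frequent first. Output is canonically ordered (descending support,
  then lexicographic items). A pattern-count guard (default 10⁶) raises a
  descriptive error instead of stalling when `minsupp` admits exponentially
  many itemsets.
* `minsupp = 0` is clamped to 1 with a warning — support ≥ 0 is vacuous.

The bridge from patterns to a feature: `f_L` pools the union of positions
appearing in **maximal** frequent patterns (the support mask). Unioning all
frequent patterns gives the identical mask — every frequent item is a
frequent singleton contained in some maximal pattern — so the choice
affects only which patterns are reported, never `f_L`; this equality is
asserted as a test. An empty mask (nothing frequent) falls back to
full-grid pooling, mirroring the global stream.

The two streams are computed independently: positions inside or outside
the global region are equally eligible as items.

**Retrieval.** `F = f_G + α·f_L` with `α ≥ 0`; `α = 0` recovers the global
representation exactly. Streams are *not* normalized before aggregation by
default (the literal rule); `normalize=True` L2-normalizes each stream
first, a documented deviation. Similarity is cosine; a zero-norm vector
scores 0 with a warning rather than dividing by zero. Rankings sort by
descending score with ties broken by ascending id, and a query drawn from
the database is excluded from its own ranking (leave-one-out). AP sums over
the full ranked database — the display cutoff `K` never caps evaluation —
and queries whose class has no other member are skipped with a warning and
recorded. Hyperparameter defaults `minsupp = 2`, `α = 1` are exposed, not
tuned: sensible per-dataset values depend on activation statistics and are
meant to be searched (integer `minsupp` counts, `α` over a log-ish grid).

## Backbones

The backbone is an adapter interface (`ImageRecord -> ActivationTensor`
with fixed output shape). Shipped adapters: `identity` (a stored tensor is
its own activation — the primary test path uses precomputed tensors in an
HDF5 store) and `patchnet`, a weight-free deterministic filter bank:
per-cell block statistics (channel means and standard deviations, mean
gradient magnitudes) projected through a fixed random matrix seeded by a
stable digest of the spec, then rectified; a 224×224 input yields 7×7×512,
matching last-pooling-layer geometry. `patchnet` exercises the
image→tensor path end to end; it is not a learned feature extractor, and
retrieval quality with it on real photographs is not claimed. Adapters for
pretrained networks plug in via `register_backbone`; such an adapter should
follow its network's published preprocessing (resize, mean subtraction,
channel order). Image loading is plain bilinear resize to the square input
side without aspect-ratio preservation or cropping.

## Synthetic data: what it emulates, and what it does not

`SceneSpec`/`generate_tensor` plant three kinds of structure, all with
exact bookkeeping (validation rejects specs whose ground truth would be
ambiguous — plants sharing channels, part sets wholly inside the blob,
noise on planted positions):

* **Blob**: a connected footprint at a high level across dedicated
  channels, so the aggregation-map mask recovers the footprint exactly;
  optional dense background clutter stays strictly below the plant level.
* **Part set**: a position set `S` written into `s` dedicated channels that
  are otherwise zero, so each such channel binarizes to exactly `S` and
  `supp(S) = s` exactly.
* **Noise**: clutter channels firing a few items each, with a hard per-item
  support cap maintained during generation, so noise can never reach
  `minsupp` in recovery tests.

`generate_corpus` builds a labeled retrieval corpus on 7×7×64 tensors
realizing the fine-grained premise in controllable form. All classes share
blob statistics (3×3 footprint, jittered position and amplitude per image
— intraclass variance; this also makes the global arm deliberately
non-discriminative, unlike on real data where the salient object itself
carries class signal). Each class owns a disjoint bottom-row position set
(3 positions, 6 channels, level ≈ 3 — comparable to the blob, so the
interclass signal is modest) — the only interclass difference. 28 clutter
channels each fire one strong item (level ≤ 10, below the aggregate
threshold δ, off all planted structure, per-item support capped at 1) —
intraclass variance that full-grid pooling absorbs but region-restricted
pooling never sees. Consequently the synthetic ablation shows the ordering
`global_local ≥ original` and `global_local ≥ global` with `local` near
perfect; passing it demonstrates that the pipeline *exploits co-activation
structure when it is the discriminative signal*, not that these mAP values
transfer to photographic benchmarks. Real activation tensors additionally
have correlated channels, heavy-tailed levels, and class signal in the
global stream, none of which the generator models.

All generation is driven by `numpy.random.default_rng` with explicit
integer seeds; identical seeds give bit-identical tensors across runs and
platforms.

## Numerical and testing notes

* Everything is float64; pooling, cosine and AP involve no iterative
  numerics. The AP implementation is cross-checked against an independent
  cumulative-hit formulation to 1e-12 on random rankings.
* The miner is cross-checked against brute-force subset enumeration
  (refuses > 20 items) on random databases at every feasible `minsupp`;
  flood fill is cross-checked against scipy's label propagation on random
  masks at both connectivities.
* Problem sizes in tests and the acceptance script (corpora of 4×5 images
  at 7×7×64, databases with m ≤ 12, n ≤ 8, 200 masks, 500 rankings) keep
  the whole suite in seconds while leaving every check exact rather than
  sampled-tolerance.

## Known limitations

* No closed-pattern mode, association rules, or weighted transactions.
* No approximate nearest-neighbor index; ranking is exhaustive cosine.
* The four-arm ablation shares one query/database split by construction
  but does not bootstrap confidence intervals.
* `patchnet` is a deterministic stand-in; claims about photographic
  retrieval quality require a real pretrained backbone adapter.
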