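# Methods

## Model

A memory register is an `n × m` boolean table `R`. A discrete function
`f` (one value in `[1..m]` per attribute) is stored by marking its `n`
cells (`λ`, cell-wise OR), recognized iff all its cells are marked
(`η`, cell-wise implication), and retrieved, when recognized, by
sampling each attribute from the contiguous marked run around the
cue's value (`β`). The computational entropy
`e(R) = (1/n) Σ log₂ μᵢ` (with `μᵢ` the marked-cell count of column
`i`, and empty columns contributing 0) measures the indeterminacy of
the stored relation; the number of functions strictly recognized is
exactly `Π max(μᵢ, 1) = 2^{e·n}` for a register built from at least
one stored function.

Because `λ` only adds marks, acceptance, entropy and the stored count
are all monotone in the stored content; this is what makes the fill
sweeps exactly monotone in recall (see *Evaluation*).

A multi-class memory holds one register per class. A cue is routed to
all registers; among those that accept, the one with the smallest
entropy wins (the most determined memory makes the strongest claim);
if none accepts, the answer is the distinguished label `unknown`.
Entropies are computed on current contents at query time, not on a
hypothetical state with the cue added. Merged classes (e.g. a capital
and a lower-case letter sharing a register) are expressed by a routing
map from raw labels to register labels, applied at fit and scoring.

## Numerical and procedural choices

These choices fill gaps the model statement leaves open; each is
deterministic and testable.

- **Discrete triangular sampling.** The retrieval draw over
  `[v_l, v_u]` with mode `v_mode` uses weights
  `w(v) = 1 + span − |v − v_mode|`, `span = max(v_mode − v_l, v_u − v_mode)`,
  normalized. Every support point keeps strictly positive mass and the
  mode is the unique maximum; the closed form makes a chi-square
  goodness-of-fit test possible.
- **Relaxed recognition** counts failing *attributes* (columns): each
  cue has exactly one cell per column, so features and columns
  coincide. `k = 0` is the strict test; classification defaults to
  `k = 0` and the occlusion experiment passes `k ∈ {0,1,2,3}`
  explicitly.
- **Retrieval through a relaxed column** (cue cell off but the cue
  accepted at `k > 0`): the mode becomes the marked cell nearest to
  the cue value, distance ties resolved toward the smaller value, and
  the run around that cell is sampled. A column with no marks at all
  (possible only when relaxation admits a partial relation) echoes the
  cue's value and is flagged in `failed_columns`; retrieval never
  crashes.
- **Stored count of an empty register is 0**, not `2⁰ = 1`: the
  product formula presumes at least one stored function, and an empty
  memory recognizes nothing.
- **Entropy ties** between accepting registers resolve to the first
  label in the fixed (sorted) register order and are logged as a
  warning.
- **Quantization** is per-feature min–max: levels
  `clamp(⌊1 + (x−lo)/(hi−lo)·(m−1) + 0.5⌋, 1, m)` with `lo/hi` the
  calibration extremes, rounding half up for cross-platform
  determinism. Degenerate features map to the middle level;
  out-of-range test values clamp (test partitions legitimately exceed
  calibration extremes). Rounding and clamping happen in float space
  before the integer cast so near-degenerate spans cannot overflow.
- **Randomness** flows through explicitly passed
  `numpy.random.Generator` streams; there is no global state. All
  indices in external formats are 1-based.

## Analysis/synthesis codec

The memory never sees pixels. The shipped codec is a deterministic
block-mean pair: a 28×28 image is pooled over an 8×8 grid of blocks
(sizes 4 or 3 per axis, by even index partition — 28 does not divide
by 8) giving 64 features; decoding paints each feature back over its
block. It is exact on block-constant images and preserves block means
in general. It deliberately has none of the learned invariances of a
trained encoder; any neural codec can be attached through `CodecSpec`
without touching the memory core.

## Synthetic corpora

The fixture generator emulates the statistical structure the memory
experiments rely on — well-separated class prototypes in feature space
with bounded within-class dispersion — so every experiment runs with
no external data.

- **Feature corpus defaults:** 36 classes, 64 features, 64 levels, 300
  instances/class split 57% / 33% / 10% into train (quantizer
  calibration), remembered (register filling) and test partitions.
  Class prototypes are uniform on `[1, m]^n` with a minimum pairwise
  mean-L1 separation of 8 levels enforced by resampling; instances add
  zero-mean Gaussian noise of sd 1.0 level, clipped to `[1, m]`. The
  noise scale is what a well-functioning encoder would produce —
  within-class spread of a few quantization levels, an order of
  magnitude below the between-class separation. The remembered
  partition (99 instances/class) is roughly a ninefold scale-down of
  the register fillings the memory was designed around; entropy at
  full fill (~2.5 bits at 64 levels) is correspondingly lower than in
  a corpus with hundreds of instances per register.
- **Glyph corpus defaults:** 36 classes, 30 images/class. Each class
  has a deterministic bar-motif base glyph (a 4-px horizontal and a
  4-px vertical bar positioned on a 6×6 grid by the class index) with
  ±2 px translation jitter per instance. Base glyphs differ pairwise
  in well over 10 % of pixels.

What the synthetic corpora do **not** emulate: the manifold structure,
style variation and class overlap of real handwriting, or the learned
feature geometry of a trained encoder. Passing sweeps here demonstrate
the memory mechanics (monotonicity, the trade-off direction, occlusion
behaviour under relaxation), not the absolute precision/recall levels
reachable on real symbol corpora — on the clean synthetic classes
cross-class acceptances are essentially absent, so precision sits at
its ceiling where the realistic regime would show it degrading.

## Evaluation accounting

Per register (one-vs-rest): TP = own-class cues accepted, FP =
other-class cues accepted, FN = own-class cues rejected;
`precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`. Because it is not
stated whether per-register curves average ratios or pool counts, both
macro (mean of per-register ratios, undefined registers skipped) and
pooled (ratios of summed counts) variants are reported.

System level: a cue rejected by every register is a system FN; a cue
whose entropy-filter winner is the wrong class counts as an FP for the
accepting class *and* an FN for the true class (double-counted by
design); consequently `TP + FN = number of cues` always holds.

Sweeps: the row sweep runs table heights `2⁰..2⁹` with the quantizer
recalibrated per height; the fill sweep stores nested prefixes
(1, 2, 4, 8, 16, 32, 64, 100 %) of one seeded per-class shuffle, so
recall monotonicity across fractions is exact rather than statistical.
The occlusion experiment zeroes either the bottom half of each test
glyph (exactly 50 % of pixels) or periodic horizontal bars (default
3 px bar / 2 px gap: 18 of 28 rows, 64 %), then encodes, quantizes and
queries at relaxations 0–3, emitting a fraction × class table of
retrieved images with blanks for rejections.

Cross-validation is a single split by default; the fold count is a
scale choice, not part of the algorithm, and is configurable.

## Problem sizes

Default experiment sizes (36 × 300 feature corpus, 36 × 30 glyph
corpus) keep the full test suite under ~10 s and the sweeps under a
few seconds each on one core; all operations are vectorized per
register over cues. Larger corpora scale linearly in instances and in
the number of registers.

## Known limitations

- No cell reinforcement or probabilistic weighting of marks: columns
  are sets, not distributions. Registers can only grow; there is no
  forgetting.
- The entropy filter uses register-level entropy only; it ignores how
  well the cue fits within the accepting run structure.
- The toy codec's block means are translation-sensitive, so glyph
  jitter directly inflates register entropy — convenient for
  exercising the trade-off, unrepresentative of a trained encoder.
- `stored_count`/`capacity` return exact integers only while
  `Π μᵢ` fits in a float; for large `n·log μ` they are best read in
  log space via `entropy()`.
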