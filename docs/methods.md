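# Methods

## Model and procedure

The package quantifies transcription-factor co-occupancy one DNA base at
a time and aggregates the result into discrete zones. The input is a set
of TF binding regions (typically ChIP-seq narrow peaks): rows of
(chromosome, start, end, strand, TF name). All internal coordinates are
**1-based inclusive** — a region of length `n` covers bases `start`
through `end = start + n − 1` — because every formula and worked value in
the methodology is stated that way; BED-family input/output (0-based
half-open) is converted exactly once at the I/O boundary (`start + 1` on
read, `start − 1` on write). Strand is read and preserved but ignored by
all computations; duplicate identical rows are kept as distinct input
regions. Chromosome names are opaque labels; chromosomes are processed
independently and a window never spans them.

### Accumulation vector

For a base `b` and moving-window semi-width `w ≥ 0`, the neighborhood is
`[max(1, b − w), b + w]`. The lower side is clamped at base 1; the upper
side is unclamped because no chromosome length is assumed — the input
regions define the extent of the analysis. Three quantification
strategies:

- `tf` — number of distinct TFs with at least one region intersecting
  the neighborhood (overlapping regions of one TF count once);
- `region` — number of input regions intersecting the neighborhood
  (same-TF duplicates count separately);
- `base` — sum over regions of the intersection length with the
  neighborhood.

The window models the systematic underestimate of occupancy caused by
discarding multi-mapping reads: uni-read-supported peaks are sparser than
the true binding landscape, and a symmetric box neighborhood of semi-width
1000 bases (the package default in the CLI) smooths local discontinuities
without aggregating unrelated loci. `w = 0` disables it.

### Exact run-length representation

Tracks are stored as maximal constant runs `(start, end, value)` with
zeros implicit, canonical (adjacent runs differ in value) and computed
with integer arithmetic only:

- `region`: each region is expanded by ±w (clamped at 1) and a sorted
  event sweep (+1 at starts, −1 past ends) yields the depth runs.
- `tf`: per-TF expanded intervals are unioned first, then the same sweep
  counts TFs instead of regions.
- `base`: with the prefix sum `C(x) = Σ_r |r ∩ [1, x]|` of the raw
  coverage track, the value at `b` is `C(b + w) − C(max(1, b − w) − 1)`.
  As a function of `b` this is piecewise linear; breakpoints are placed
  wherever `b + w` or `b − w − 1` crosses a coverage-run boundary (plus
  the clamp release at `b = w`), constant pieces become single runs and
  linear ramps are materialized one base per run. Each ramp is checked
  for integer-exact linearity (divisibility of the endpoint difference
  and a midpoint collinearity test); a violation raises rather than
  silently approximating. For `w = 0` the base track *is* the coverage
  track and is returned directly.

The per-base ramp materialization means base-type tracks with large `w`
can hold many runs (one per base on every ramp); this is the price of
exactness and is linear in the windowed span, not in `w`.

A brute-force oracle (`fixtures.naive_accumulation`, with a vectorized
twin `naive_profile`) evaluates the three definitions literally, testing
every region (and every region base, for the `base` type) against the
neighborhood. The test suite asserts engine = oracle at every base over
a grid of random datasets, types, and `w ∈ {0, 1, 7, 250, 1000}`.

### Zone extraction

*Binding region* method: input regions sharing at least one base are
transitively merged (book-ended regions — `end + 1 = start` — stay
separate, since they share no base); each merged zone's accumulation
index is the number of distinct TFs with ≥ 1 region inside it. The
moving window is deliberately not applied here: the method is defined on
the original regions. The index therefore always dominates the maximum
per-base TF accumulation (w = 0) within the zone.

*Overlap* method: every maximal non-zero constant run of the chosen
track becomes a zone and inherits the run value as its index. Works for
any accumulation type and window; its HOT zones contain only bases at or
above the threshold, and at an equal threshold (tf accumulation, w = 0)
their bases always lie inside binding-region HOT zones.

### Thresholding

- `top_k_pct` (0 < k ≤ 100): sort zones by index descending, take
  `m = ⌈k/100 · N⌉` zones, threshold = minimum index among them. The
  ceiling (rather than floor) is pinned so that k > 0 always selects at
  least one zone; selection then reapplies `index ≥ threshold`, so tied
  zones are never split and the HOT set can exceed k% of N.
- `k_std` (k ≥ 0): threshold = `⌈mean + k·sd⌉` of the per-base
  accumulation over **non-zero** bases, each base weighted once, pooled
  across analyzed chromosomes; `sd` is the sample (n − 1) estimator —
  the conventional choice, pinned here because the source procedure does
  not name one. Degenerate statistics (no non-zero base) are an error.
- `absolute` (integer k ≥ 1): used as given.

HOT selection is **inclusive** (`index ≥ threshold`): the two method
definitions ("at least equal", "not lower than") govern over looser
phrasings. For the binding-region method with `k_std`, the per-base
statistics are taken from the **TF-accumulation track at the analysis
`w`** — the method scores zones by distinct-TF counts, so the TF vector
is the matching single-base quantity; this is a pinned choice where the
procedure is stated "regardless of accumulation type".

Thresholding pools zones and base statistics genome wide by default
(`per_chromosome=True` thresholds each chromosome independently), since
the procedure is defined to work on a single chromosome or the entire
genome alike.

### Zone statistics and comparisons

Zone sets report min/max/mean/median/sd of zone lengths (median of an
even count = mean of the two central values; sample sd, NaN below two
zones, serialized as null). Evaluation utilities use "overlap" to mean
≥ 1 shared base throughout, consistent with the merging rule: two-way
zone/feature overlap summaries, one-directional method concordance, and
a per-sample partition of zones into conserved (overlapping ≥ 1 zone of
*every* other sample), exclusive (overlapping none) and other. Interval
queries go through `intervaltree`; tests re-derive every count with an
all-pairs brute-force check.

## Synthetic data

`example_fixture()` returns a fixed ten-region, three-TF dataset whose
accumulation values are hand-checkable. Its coordinates are pinned to
satisfy the constraints the worked narrative states: the only same-TF
overlap is two Z regions intersecting exactly in `[4250, 4500]` (one of
them `[4250, 6000]`); a Y region covers that range; the window
`[2250, 4250]` around base 3250 intersects exactly four regions covering
all three TFs. All reported example values (2, 3, 3, 4) follow from
these constraints alone, so any coordinate assignment satisfying them
yields the same numbers.

`random_regions(SyntheticSpec(...))` generates seeded datasets: TF labels
uniform with every TF used at least once, starts uniform over the span,
lengths uniform in a range defaulting to 150–500 bp (typical narrow-peak
widths) over a 100 kb span — dense enough that a sizeable fraction of
regions overlap, which is what exercises the merging and same-TF logic.
Overlap density is controlled indirectly through `n_regions`, `span` and
`length_range` rather than by a target overlap fraction, keeping the
generator a plain uniform model. The generator emulates only interval
geometry and labels; it does not model peak shapes, signal strength,
binding-site sequence preference, chromosomal clustering of regulatory
elements, or inter-TF correlation. Passing tests therefore demonstrate
the correctness of the interval computations, not biological realism of
any particular HOT-zone call.

## Problem sizes and numerics

The test suite runs random instances of ≤ 100 regions on ≤ 10 kb spans
for per-base oracle comparisons (exhaustive, every base), and one
5-TF / 5000-region / 2 Mb dataset through both full pipelines for the
scaled analysis; the whole suite completes in seconds. All accumulation
arithmetic is integer-exact; the only floating point is in means,
standard deviations and length statistics. Empty inputs are defined
results, not errors (empty tracks, zero-count summaries), except where a
threshold is genuinely underivable: `top_k_pct` on an empty zone set and
`k_std` on all-zero accumulation raise.

## Known limitations

- Aligned reads (BAM/SAM) and peak calling are out of scope; input must
  already be binding regions.
- narrowPeak files carry no TF column; the TF must be supplied
  explicitly (flag or file-to-TF mapping) — no filename guessing.
- Only the uniform (box) window is provided; no other smoothing kernels.
- Base-type tracks at large `w` are exact but verbose (per-base runs on
  ramps); for genome-scale base-accumulation analyses, prefer the tf or
  region types or be prepared for large track objects.
- No built-in genome annotations: promoter/CpG-island comparisons take
  user-supplied interval files. Association testing (e.g. Fisher exact)
  and functional enrichment are out of scope.
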