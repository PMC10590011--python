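# hotzones

Identification of **high-occupancy-target (HOT) DNA zones** — genomic
regions bound by an unusually high number of distinct transcription
factors — from ChIP-seq-style TF binding regions.

Regulatory genomics studies repeatedly find loci where dozens of TFs
co-occur; calling these HOT zones reproducibly requires fixing three
choices that are usually left implicit: *how* binding is counted at each
base, *what* a candidate zone is, and *where* the density threshold comes
from. `hotzones` makes each choice explicit and composable:

**Per-base accumulation.** For every base *b*, with a symmetric moving
window of semi-width *w* (neighborhood `[max(1, b−w), b+w]`; *w* = 1000
is the suggested smoothing for real data, *w* = 0 disables it), one of
three counts:

- **TF accumulation** — distinct TFs with ≥ 1 region intersecting the
  neighborhood: `TF_acc(b) = |{ t : ∃ region of t ∩ [b−w, b+w] ≠ ∅ }|`
- **region accumulation** — input binding regions intersecting the
  neighborhood (same-TF duplicates counted separately):
  `BR_acc(b) = |{ r : r ∩ [b−w, b+w] ≠ ∅ }|`
- **base accumulation** — total region bases inside the neighborhood:
  `GB_acc(b) = Σ_r |r ∩ [b−w, b+w]|`

Always `TF_acc ≤ BR_acc ≤ GB_acc`, with equality of all three at *w* = 0
whenever no two regions of the same TF overlap. Tracks are exact
run-length-encoded integer vectors in 1-based inclusive coordinates
(BED input is converted at the boundary).

**Dense zones.** Two search methods: *binding region* (transitively merge
input regions sharing ≥ 1 base; index = distinct TFs in the merged zone)
or *overlap* (every maximal constant non-zero run of the track; index =
the run value). Overlap zones at an equal threshold are always contained
in the binding-region ones — narrower but more precise.

**Threshold.** *top k %* (minimum index among the top ⌈k/100·N⌉ zones),
*over k standard deviations* (⌈mean + k·sd⌉ of the per-base accumulation
over non-zero bases, sample sd), or an absolute integer. HOT zones are
the dense zones with index ≥ threshold.

## Worked example

The built-in ten-region, three-TF dataset (TFs X, Y, Z on one
chromosome) has one same-TF overlap: two Z regions sharing
`[4250, 4500]`.

```python
from hotzones import compute_accumulation, example_fixture

regions = example_fixture()
for acc_type in ("tf", "region", "base"):
    track = compute_accumulation(regions, acc_type, w=0)["chrE"]
    print(acc_type, track.value_at(4300))
print("tf, w=1000 @3250:", compute_accumulation(regions, "tf", 1000)["chrE"].value_at(3250))
print("region, w=1000 @3250:", compute_accumulation(regions, "region", 1000)["chrE"].value_at(3250))
```

prints

```
tf 2
region 3
base 3
tf, w=1000 @3250: 3
region, w=1000 @3250: 4
```

Inside the same-TF overlap the TF count is 2 (Y and Z — the two Z
regions count once) while region and base counts are 3 (three regions
cover each base). With a 1000-base window at base 3250 the neighborhood
`[2250, 4250]` reaches regions of all three TFs (TF accumulation 3, the
maximum possible here) and touches four input regions (region
accumulation 4 — the fourth starts exactly at the window edge).

The full pipeline is one call:

```python
from hotzones import ThresholdSpec, find_hot_zones

dense, hot, thr = find_hot_zones(regions, method="overlap", acc_type="tf",
                                 w=0, spec=ThresholdSpec("absolute", 2))
```

`examples/` contains short narrative scripts for each capability
(accumulation, HOT-zone search with both methods, cross-sample
conserved/exclusive comparison). The same operations are available from
the shell:

```sh
hotzones simulate --fig3 -o example.tsv
hotzones hotfind -i example.tsv -t tf -w 0 --threshold absolute -k 2 -o run
hotzones accumulate -i example.tsv -t region -w 1000 -o track
```

`hotfind` writes dense/HOT zone BED files, a JSON report with zone
counts, length statistics (min/max/mean/median/sd) and the resolved
threshold, and a provenance record of the full configuration.

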