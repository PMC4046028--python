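# Methods

## Problem and model

Array methylation profiles report, per CpG probe, a methylation fraction
β ∈ [0, 1]. Comparing two *unique* samples (no replicates) rules out
per-probe inference: a single β per probe per sample carries no error
estimate. `methpairs` therefore moves inference to the region level. Probes
on arrays such as the 450K are strongly clustered (islands, promoters), and
methylation within a cluster is locally coherent, so a probe-dense region
provides several quasi-replicate observations of one regional methylation
state per sample. Within a region, the probe-level values of one sample are
treated as a group, and groups are compared with rank tests.

Statistics are computed on M-values, M = log₂(β′/(1−β′)) with
β′ = clip(β, ε, 1−ε). The M scale is approximately variance-stabilised,
whereas β compresses differences near 0 and 1; β is kept for visualisation
and reported medians. ε defaults to 0.001 (configurable): logit of exactly
0 or 1 is infinite, and clipping bounds |M| at ≈ 9.97 without affecting any
β that the transform can represent faithfully. Whether clipping or dropping
infinite values is the better edge policy is genuinely open; clipping was
chosen because it keeps per-sample probe counts intact, which the region
filter depends on.

## Region discovery

For each analysis class independently, per chromosome, probes are scanned in
genomic order; maximal runs whose consecutive gaps are ≤ `d_min` are
candidate regions, and a run is kept when **every** sample has ≥ `n_min`
probes with a non-missing β inside it.

Choices that change counts, documented explicitly:

- **Gap rule is inclusive**: a pair at distance exactly `d_min` stays in one
  run. An off-by-one here alters region counts; the inclusive reading of
  "within" was fixed once and is asserted in tests.
- **`n_min` is per sample, over non-missing values.** This guarantees every
  test has at least `n_min` observations per group (the default of 4 matches
  the minimal 2×4 configuration for which a two-sided exact Mann–Whitney
  test can reach p < 0.05). Run *boundaries* use all probes of the class,
  missing or not — spacing is a property of the array, not of one sample's
  QC — and the per-sample floor then filters whole runs, so the filter can
  drop but never split a run.
- Probes at identical positions are allowed (gap 0, ties broken by probe
  ID). Probes in several classes join regions of each class; regions from
  different classes covering exactly the same probe set merge into one
  region with the combined, sorted class label.
- Region IDs (`R000001`, …) are ordinals after the final sort (natural
  chromosome order 1–22, X, Y, MT, then others; then start, end, classes).
  They are specific to one dataset and parameter set and are not
  comparable across runs.

Default `d_min` = 200 bp reflects the distance over which methylation of
neighbouring CpGs remains well correlated on human arrays.

## Screening, testing, correction

Per region: per-sample medians of β and M over non-missing values, the
antisymmetric matrix ΔM of pairwise median-M differences, and
max |ΔM|. The screen is **strict**: a region is tested iff
max |ΔM| > `dM`. The default threshold 1.4 sits at the upper end of the
0.4–1.4 range recommended for M-value effect sizes; lowering it raises
detection but inflates the number of tests performed.

Tested regions get an omnibus p: Mann–Whitney U (two-sided) for n = 2,
Kruskal–Wallis for n > 2. The MWU uses the exact null distribution when the
smaller group has ≤ 8 observations and the pooled values are tie-free, and
the tie-corrected normal approximation with continuity correction otherwise;
exactness matters at group sizes near `n_min` = 4, where the approximation
is unreliable. Kruskal–Wallis uses the tie-corrected chi-square
approximation; when all groups are rank-identical, H = 0 and p = 1 by
construction. When n > 2 and the omnibus p ≤ 0.05, pairwise post-hoc MWU
tests are computed and reported **raw** — they are indicative; the omnibus p
alone drives the significance flag.

Multiple-testing correction (Benjamini–Hochberg step-up by default;
Bonferroni and none available) is applied **over the tested regions only**:
untested regions carry no p-value, and the screening gate exists precisely
to limit the size of the testing family. Correcting over all candidate
regions instead would require imputing p = 1 for unscreened regions; the
chosen family is documented and switchable in code. Significance is
**inclusive**: relevant (= screened) and p_adjusted ≤ α, default 0.05.

Interpretation caveats inherited by any user: probe-level observations
within a region are spatially correlated, so the rank tests' independence
assumption is optimistic and p-values are best read comparatively; regions
with more probes have more power, biasing ranked lists toward long regions.
When replicate samples exist, they should be averaged (per-probe mean β,
provided as an explicit utility) before a unique-sample comparison — never
implicitly.

## Ranking and export

Reports list significant regions first (ascending adjusted p, ties by
descending max |ΔM|, then region ID), then relevant-but-not-significant by
descending max |ΔM|, then the remainder in genomic order. Internal
coordinates are 1-based inclusive (manifest convention); BED output converts
to 0-based half-open; UCSC links are 1-based with a `chr` prefix, Ensembl
region strings drop the prefix. Every conversion is unit-tested. HTML
reports are static, single-directory, with no external assets. Transcript
overlays in region plots come from a local GFF3/GTF file instead of a live
Ensembl query, keeping runs reproducible without network access. All
outputs are byte-identical across repeated and parallel runs: worker results
are reassembled in input order and numbers are formatted with a fixed rule.

## Synthetic data generator

The generator emulates what the pipeline is sensitive to, with defaults
chosen as the package's reference study conditions:

- **Layout**: ~80 clusters per chromosome over 4 chromosomes (3,200 probes),
  cluster sizes 8–12 probes, intra-cluster gaps 20–150 bp, inter-cluster
  gaps 1–5 kb. Intra gaps stay below the default `d_min` and inter gaps
  above it, so clusters map 1:1 onto found regions — the planted truth is
  well-defined at the region level.
- **Classes**: one label per cluster from {gene, tss, island}, plus a 10 %
  per-probe chance of a second class (multi-membership). Datasets are
  written with representative 450K manifest labels (Body, TSS200, Island) so
  the default recode scheme reproduces the generator's classes.
- **Baseline**: the hypo/hyper compartment is drawn per *cluster* from an
  equal mixture of N(−3, 1) and N(+3, 1) on the M scale, with probe-level
  scatter from the component sd. Drawing the compartment per cluster, not
  per probe, encodes regional coherence — the property the method relies
  on; methylation arrays show exactly this bimodal, regionally coherent
  structure.
- **Effects**: in 10 % of clusters, one sample's M values are shifted by
  ±3 — the planted |ΔM| = 3 is comfortably above the 1.4 screen yet small
  enough that β values stay inside (0, 1). Probe-level noise is N(0, 0.5²)
  on M, and 2 % of values are masked as missing.
- One explicitly seeded PRNG stream drives everything; the seed is recorded
  in the run manifest.

What the generator does **not** emulate: Infinium I/II probe-type bias,
colour-channel effects, normalisation artefacts, SNP/cross-hybridising
probes, and realistic genome-scale probe counts. Passing tests on synthetic
data therefore demonstrate the correctness of segmentation, testing and
reporting under the stated statistical model — not robustness to array
chemistry, which is delegated to upstream pre-processing pipelines.

## Problem sizes and numerical choices

The benchmark configuration (3,200 probes, ~320 clusters, two samples) is
the package's reference size for its own validation: large enough that
~32 planted regions and a BH family of tens of tests exercise the ranking
and correction meaningfully, small enough that a hundred seeded null
replicates run in well under a minute. Region-finder correctness is
additionally checked against a brute-force enumerator on hundreds of random
instances of up to 200 probes and 3 classes.

Degenerate inputs: an empty probe set yields an empty region list; an
interval query with no probes returns an explicit "no probes" result; a
query where a sample falls below `n_min` reports medians but is flagged
untested with a warning. Ties in rank tests route to the corrected
asymptotic path. The exact-threshold cases are fixed by convention — screen
strict, significance inclusive — and pinned in tests.

## Known limitations

- No modelling of spatial correlation between adjacent probes; p-values are
  anti-conservative to an unquantified degree on real arrays.
- No smoothing or bump detection: regions are defined by array geometry and
  class annotation only, so DMRs poorly covered by probes are invisible.
- Pre-processing (normalisation, probe filtering) is out of scope; input β
  is taken as given.
- Browser links are plain URL templates for the configured genome build; no
  liftover is performed.
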