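# methpairs

Identification of **differentially methylated regions (DMRs) between unique,
unreplicated samples** from array-based DNA methylation profiles.

Most DMR callers (bumphunter-style regression, group-wise region tests)
need groups of samples to estimate per-probe effects. When the samples are
unique — normal and affected tissue of one patient, a manipulated cell model
and its parent line — those methods cannot be applied. `methpairs` instead
exploits local probe density: it segments the array into probe-dense,
functionally homogeneous regions and compares the *distributions of
probe-level methylation* between samples within each region, so every region
supplies its own observations.

## Method

Input is a probe annotation table (probe ID, chromosome, position, functional
classes; 450K-manifest-style columns by default) and a matrix of methylation
fractions β ∈ [0, 1] for *n* ≥ 2 named samples. The pipeline:

1. **Recode probe classes.** The eleven 450K classes (gene relation: Body,
   5'UTR, 3'UTR, 1stExon, TSS1500, TSS200; island relation: Island, N/S
   Shore, N/S Shelf) are kept as-is (scheme 0), grouped by relation to
   gene / transcription start site / CpG island (scheme 1, default), or
   collapsed into a single class (scheme 2, for platforms without such
   annotation). Custom mappings are supported; probes with no mapped class
   are excluded from region finding under schemes 0–1.
2. **Find regions.** Per class and chromosome, maximal runs of probes with
   consecutive gaps ≤ `d_min` (default 200 bp) are kept when every sample
   has ≥ `n_min` (default 4) non-missing probes in the run. Probes in
   several classes can join several regions; fully identical cross-class
   regions are merged with a combined class label.
3. **Quantify and test.** Statistics use M-values, M = logit₂(β) =
   log₂(β/(1−β)) (β clipped at ε = 0.001). For each region and sample the
   median M is computed; if the largest pairwise difference of median M
   strictly exceeds ΔM (default 1.4), the region is tested — Mann–Whitney U
   on the two samples' probe-level M values (exact for small groups), or
   Kruskal–Wallis for n > 2 with pairwise post-hoc MWU when the omnibus
   p ≤ 0.05. P-values of tested regions are Benjamini–Hochberg adjusted;
   a region is **relevant** when max |ΔM| > 1.4 and **significant** when
   additionally p_adjusted ≤ α (default 0.05).
4. **Report.** Ranked TSV/HTML tables (all / relevant / significant), BED6
   intervals, UCSC/Ensembl browser links, per-region statistics files,
   per-region methylation plots, and a run manifest with input checksums.

A seeded synthetic-data generator plants DMRs of known effect size in
clustered probe layouts and scores recovery, serving as the test bed.

## Worked example

```sh
methpairs simulate --seed 7 --out sim
# seed=7: 3200 probes, 32 planted DMRs -> sim
methpairs run sim/annotation.tsv sim/beta.tsv --out results
# 321 regions, 32 relevant, 32 significant -> results
```

The simulated dataset has two samples and ~320 probe clusters; 10 % carry a
planted median-M offset of |ΔM| = 3 in one sample. The run segments the
probes into 321 regions, screens them at ΔM = 1.4 and flags exactly the 32
planted regions as significant. The top of `results/regions_significant.tsv`:

```
region_id  chrom  start   end     n_probes  classes  median_beta_sample1  median_beta_sample2  median_M_sample1  median_M_sample2  dM_sample1_vs_sample2  max_abs_dM
R000215    3      210083  211093  12        gene     0.1075               0.01216              -3.054            -6.347            3.292                  3.292
R000277    4      143184  144113  12        tss      0.5769               0.1372               0.4474            -2.653            3.1                    3.1
```

Each row is one region: its genomic interval, probe count, class, per-sample
median methylation on both scales, the pairwise median-M difference (here
≈ 3, the planted effect), plus raw/adjusted p-values and browser links in
the remaining columns. `results/regions.bed` holds the same intervals in
0-based half-open BED6 with −10·log₁₀(p_adjusted) scores.

Other subcommands: `methpairs tune` sweeps (`d_min` × `n_min`) and reports
region counts and probe coverage; `methpairs query annotation.tsv beta.tsv
3:210000-212000` quantifies and tests an arbitrary interval.

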