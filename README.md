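# cnaprog

Copy-number alteration analysis for prognostic subtyping of tumor aCGH
cohorts.

High-grade serous ovarian carcinomas carry complex genomes — pervasive
arm-level gains and losses plus recurrent focal amplifications and
deletions — and subsets of these alterations track with how patients fare
on platinum-based therapy.  `cnaprog` implements, as a tested reusable
pipeline, the analysis that turns probe-level log2(tumor/reference) ratios
into survival-linked genomic subgroups:

1. **Segmentation** — circular binary segmentation (CBS): each sample's
   profile is recursively split at the arc [i, j) maximizing
   |mean(arc) − mean(complement)| / √(1/k + 1/(n−k)), accepted when its
   within-stretch permutation p-value < α; segments with < 4 markers merge
   into the neighbor closest in mean; the cohort is reduced to the union
   of all breakpoints without losing any sample's segment means.
2. **Calling** — per-sample dynamic thresholds at 1.11 × MAD of the
   segment means: gains above, losses below, strict inequality.
3. **Significance scan** — per-marker G-score = frequency × mean
   amplitude among samples beyond ±0.4; within-sample permutation null
   pooled across markers; Benjamini–Hochberg q-values; peaks are the
   maximal-G sub-runs of contiguous q < 0.25 regions, with peel-off for
   secondary peaks and broad/focal labels from carrier event lengths.
4. **Subgrouping** — Ward/Euclidean clustering of the reduced matrix
   (chrX excluded), k-cut, Kaplan–Meier / log-rank / Cox contrasts of the
   clusters' progression-free and overall survival.
5. **Markers & classification** — peaks unique to one cluster (reciprocal
   overlap < 25% against every other cluster) become discriminating
   markers; a linear SVM on region-mean log2 features is evaluated by
   leave-one-out cross-validation and can classify external cohorts on
   other platforms after an interval-overlap probe mapping.

A synthetic cohort generator (`cnaprog.simulate`) reproduces the
statistical structure this analysis assumes — two latent outcome subgroups
differing in eight named focal regions (gains 12p12.1, 19q12, 20q11.21,
20q13.12; losses 8p21.3, 8p23.2, 17p11.2, 17p12), shared high-frequency
events, a dense arm-level aneuploidy background, and subgroup-coupled
exponential survival — so every stage is testable without any download.
See `docs/methods.md` for the models and design decisions.

## Worked example

Run the full pipeline on a simulated 16-sample reference cohort:

```
cnaprog run --out demo_run --seed 3 --n-samples 16
```

The run directory contains every stage artifact (probe map, log2 matrix,
SEG segments, calls, score track, peak tables, cluster labels, dendrogram,
survival JSON, marker BED/JSON, LOOCV predictions, a config snapshot and a
SHA-256 manifest).  The printed report begins:

```
copy-number pipeline run summary
==================================
cohort: 16 samples x 6952 probes
parameters: alpha=0.01 n_perm_cbs=1000 min_markers=4 mad_scale=1.11 theta=(0.4,0.4) q<0.25 k=2 svm_c=1.0 seed=3

significant peaks (cohort scan): 39
descriptor kind scope           peak_limits  q_value  frequency_pct
        3q  Amp focal  chr3:8463001-8593200 0.004167           43.8
        8q  Amp focal  chr8:6401501-6553400 0.002000           68.8
       12p  Amp focal chr12:1215201-1302000 0.004167           56.2
       ...
cluster sizes: 1: n=8, 2: n=8
PFS: log-rank p = 0.002552, HR = 13.2 (1.58-110); median months: cluster 1: not reached, cluster 2: 3.8
...
LOOCV accuracy vs cluster labels: 1.000
LOOCV accuracy vs generative subgroups: 1.000
```

Reading it: the cohort scan finds the implanted focal events (e.g. the
8q24.21 gain at 69% frequency, q = 0.002, on the 1/20-scale genome where
`chr8:6401501-6553400` maps to the full-scale locus) among broad
arm-level background peaks; the k = 2 Ward cut separates the two
generative subgroups, which differ strongly in progression-free survival
(log-rank p ≈ 0.003); and the markers unique to each cluster classify the
samples perfectly under leave-one-out at this small n.  At the reference
size (n = 72) LOOCV accuracy is typically 0.90–1.00 and the eight
implanted discriminating regions are recovered in the large majority of
seeds.

Every stage is also available separately (`cnaprog simulate | mask |
segment | call | gistic | cluster | markers | classify | report`) and as
library functions.

## File formats

| artifact | format |
| --- | --- |
| probe map | TSV: `probe_id chrom start end arm`, 0-based half-open |
| log2 matrix | TSV: probe rows × sample columns, `probe_id` index |
| clinical | TSV: `sample pfs_months pfs_event os_months os_event` + covariates |
| segments | SEG TSV: `sample chrom start end n_markers seg_mean`, 1-based inclusive on disk |
| calls | TSV of {−1, 0, 1} + thresholds JSON |
| peaks | TSV: descriptor, kind, broad/focal, `chrN:start-end` (1-based), q, frequency %, genes |
| markers | BED (0-based half-open) + provenance JSON |
| masks / truth / survival | JSON |
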