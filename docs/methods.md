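# Methods

`cnaprog` implements a copy-number analysis pipeline for stratifying tumor
cohorts measured by array CGH into prognostic subgroups, together with a
synthetic cohort generator that makes every stage testable end to end.
This note documents the models, the numerical choices, and the places where
the design was genuinely open.

## Input model

The pipeline starts from probe-level log2(tumor/reference) intensity
ratios on an ordered probe map (0-based half-open coordinates internally;
SEG files are 1-based inclusive on disk, BED files 0-based half-open; both
`chr19` and `19` chromosome dialects are accepted and normalized).  The
synthetic platform tiles hg18-proportional chromosomes at 21.7 kb spacing,
the average spatial resolution of a 105K-feature oligonucleotide array;
chromosome lengths can be shrunk by a common factor (default 1/20) so
desk-scale simulations finish in minutes while arm/cytoband geometry is
preserved.  chrY is never modelled (female reference DNA).

## Segmentation (CBS)

Each sample is segmented per chromosome by recursive circular binary
splitting.  For a stretch of n probes the arc [i, j) maximizing

    U(i, j) = |mean(arc) − mean(complement)| / sqrt(1/k + 1/(n−k)),  k = j−i

is located (ties break to smallest i, then smallest j), and the split is
accepted when its within-stretch permutation p-value, with add-one
smoothing, falls below `alpha` (default 0.01; default 1,000 permutations).
Two deliberate variant choices:

* **Constant-variance statistic.**  U drops the pooled variance factor of
  the classical two-sample t.  Within a stretch the factor is a constant,
  so the argmax is unchanged, and because a permutation does not change
  the value multiset, the permutation rank is unchanged too.  The brute
  force oracle in the test suite enumerates all arcs with this definition.
* **Sequential curtailment.**  The permutation loop stops as soon as the
  accept/reject decision at `alpha` is determined: rejection when the
  exceedance count reaches ceil(alpha·(n_perm+1)); acceptance when no
  exceedance has occurred after 150 permutations (curtailed p ≈ 1/151,
  below alpha/1.5 at the default).  Decisions are deterministic given the
  seed.  This is the same idea as the sequential early-stopping boundary
  used by established CBS implementations and is what keeps a 72-sample
  genome-wide segmentation near twenty seconds on one core.

A consequence of the permutation stopping rule worth knowing: a width-1
outlier can never be a change point, because permuting the stretch moves
the outlier without changing the maximal single-probe arc statistic (the
germline-CNV mask below compensates).

Segments with fewer than four markers are then merged into whichever
neighbor is closest in segment mean (probe-weighted mean recomputed;
leftmost-smallest segment first; exact ties merge left), repeating until
every segment has ≥ 4 markers or the chromosome is a single segment.
Finally the cohort is reduced to the union of all samples' breakpoints: a
region × sample matrix of segment means that reconstructs every sample's
per-probe segment means exactly.

## Gain/loss calling

Per sample, the dynamic threshold is `scale × MAD` (default scale 1.11)
where the MAD is the raw median absolute deviation of the segment means
about their median — unweighted by segment size and without the 1.4826
consistency constant, the literal reading of a "MAD across all segments"
threshold.  Calls are strict: +1 above the threshold, −1 below its
negative, 0 otherwise.  Two caveats are documented as options:

* `center="zero"` centers deviations at 0 instead of the median.
* Passing probe-level values switches the MAD basis to raw ratios.  This
  matters for quiet genomes: with the segment basis the threshold is
  ~0.75× the robust spread of the segment means *themselves*, so an
  event-free genome gets ~45% of probes called at any size.  The
  probe-level basis is insensitive to segment count and is the reading
  under which the "almost nothing is called on a null cohort" property
  holds; the test suite exercises it that way.

## Germline-CNV mask

Common copy-number polymorphisms are re-derived computationally from
normal-vs-reference hybridizations: each normal is segmented and called
like a tumor, except that sub-threshold segments are kept (germline CNVs
are often narrower than four probes), the MAD basis is probe-level (see
above), and strong probe-level outliers (beyond 3 robust SD and at least
the call threshold) are flagged in addition to called segments — the
permutation segmenter cannot isolate single-probe variants on its own.
Probes flagged in at least `min_normals` normals (default 2) form the
platform-level mask and are removed from matrix and probe map before
segmentation.

## Significance scan (GISTIC-style)

Per region ("marker") and kind, the G-score is frequency × mean exceedance
amplitude among aberrant samples, i.e. `(1/N)·Σ value(s)` over samples with
value ≥ θ_amp (amplifications) or `(1/N)·Σ |value|` over samples with
value ≤ −θ_del (deletions); θ defaults to 0.4 for both kinds, the
conservative maximum of the per-sample MAD thresholds.  The null
distribution permutes each sample's region values across positions
(preserving that sample's aberration burden while destroying location) and
pools all permuted G-scores across markers and permutations into one
empirical null per kind; marker p-values use add-one smoothing and are
Benjamini–Hochberg adjusted.  Maximal runs of contiguous markers with
q < 0.25 are significant regions; the reported peak is the maximal
sub-run attaining the region's maximum G (within-sample segment means are
bit-identical across the regions they span, so the flat top of an
implanted event is recovered exactly).

Peel-off then removes, for each sample contributing to the peak, its
*covering segment* — the maximal contiguous aberrant run holding the
anchor's exact segment value — and rescans the region (p from the original
pooled null, BH within the region) for secondary peaks while any marker
stays below the threshold.  Restricting removal to the equal-value run
matters: removing the whole aberrant run would also erase an adjacent,
different-amplitude event of the same sample and hide genuine secondary
peaks.

Peaks are labelled broad/focal from the lengths of the contributing
samples' aberrant runs: median length ≥ half the arm → broad, otherwise
focal, with "both" when each mode holds at least 25% of carriers.  Arm
extents come from the probe map.  One marker-level caveat: q-values are
computed per region of the reduced matrix and the peak reports the minimum
q over its markers.

## Subgrouping and survival

Samples are clustered with Ward's minimum-variance linkage on Euclidean
distances over the reduced matrix, chrX regions excluded (X copy number on
a female-reference platform reflects germline sex, not somatic biology).
Regions are weighted by sqrt(probe count) by default, which makes the
distances equal to those between the probe-resolution expansions of the
reduced profiles — the reduction preserves probe continuity, so a region
speaks with the weight of its probes; unit weights are available via
`probe_weighted=False`.  The tree is cut at a user-chosen k (the primary
analysis uses k=2; no automatic model selection).  Cluster survival
contrasts use the Kaplan–Meier estimator, the two-sided log-rank test, and
a Cox proportional-hazards fit (all via lifelines).

Two statistical caveats are reproduced deliberately rather than "fixed":
survival is tested on the same cohort that produced the clusters, so the
log-rank type-I error is inflated above its nominal level (the test suite
bounds it at 10% for α=0.05 on null cohorts); and the LOOCV below is
evaluated on the cohort whose cluster labels trained it.

## Discriminating markers and classification

Per-cluster significance scans are compared: a peak of one cluster is
*unique* when no same-kind peak of any other cluster overlaps it with at
least 25% of both intervals (reciprocal overlap).  Unique peaks, merged
within kind, form the marker set; each marker region's feature is the mean
log2 ratio over its probes (continuous features preserve amplitude).  The
classifier is a linear support-vector machine (C=1; features greatly
outnumber samples, so a linear kernel is the conservative choice),
evaluated by leave-one-out cross-validation against the cluster labels it
is trained on.  Because cluster numbering is arbitrary, accuracy against
the generative subgroup labels of a simulated cohort is reported under the
better of the two label mappings.

External cohorts on other platforms are classified after an
interval-overlap join of marker regions onto the external probe map
(regions with no overlapping target are flagged and excluded with a
warning; a platform with unresolvable chromosome names is an error).  Two
routes reflect an ambiguity in how a "supervised clustering" can be read:
the trained SVM assigns training-subgroup labels directly (`k=None`), or
the marker-feature space guides a fresh Ward tree cut into k clusters —
the route for cohorts where more than two subgroups are plausible.

## Synthetic cohorts

The generator is additive: each probe's log2 ratio is attenuation ×
(sum of signed magnitudes of the carried events covering the probe's
midpoint) + Gaussian noise.  A probe belongs to an event when its tiling
cell *midpoint* lies inside the event, so abutting p/q-arm events never
double-cover a centromere-junction probe.  Carrier status is Bernoulli per
event and sample with subgroup-dependent probabilities; events sharing a
`mutex_group` are mutually exclusive within a sample (an arm is gained or
lost, never both).  Overlapping carried events sum.  The attenuation
scalar (default 0.8) stands in for tumor-cell fraction.  Survival is
exponential per subgroup (rate ln2/median) with uniform censoring whose
upper bound is solved so the expected censoring fraction over the subgroup
mixture matches the configured rate.  All randomness flows from one
mandatory seed through independent child streams.

### The reference scenario

`default_reference_scenario()` emulates a 72-tumor high-grade serous ovarian
carcinoma cohort with two latent outcome subgroups (36/36):

* **Eight discriminating focal events** at the hg18 coordinates of the
  regions that distinguish the prognostic subgroups — gains at 12p12.1,
  19q12, 20q11.21, 20q13.12 carried by the poor-outcome subgroup, losses
  at 8p21.3, 8p23.2, 17p11.2, 17p12 by the good-outcome subgroup — at
  carrier probability 0.75 in the carrying subgroup and 0.15 in the other,
  magnitude 0.8 (≈0.64 after attenuation).
* **Four shared focal events** (gains 3q26.2, 8q24.21 at 0.75; losses
  16q24.2, 22q13.33 at 0.78 in both subgroups): the most frequent
  alterations of this tumor type, and the probe of the uniqueness logic.
* **Arm-level background everywhere.**  Each autosomal arm is gained,
  lost, or neutral per sample at single-copy amplitudes (0.55/0.60).  On
  thirty *signature* arms the balance is subgroup-dependent (favored kind
  0.90, opposite kind 0.10 in the favored subgroup; plain 0.40/0.40
  passenger behavior in the other), mirroring the aneuploidy-landscape
  differences real outcome subgroups show; all other arms are 0.40/0.40
  passengers in both subgroups.

The background serves two quantitative purposes at once.  It gives the
significance scan's permutation null a realistic per-sample aberration
burden, so recurrent whole arms sit at the null's centre and the
0.15–0.25-frequency minority side of a discriminating event stays
non-significant in the opposite cluster's scan — without it *every*
recurrent locus above a few percent frequency is significant and the
uniqueness rule collapses.  And it gives Ward clustering a dominant
landscape signal, without which eight focal events carry far too little
Euclidean weight to recover the subgroups.

Scenario geometry is tuned to the desk-scale genome: focal windows are
expanded to ≥ 3 Mb full scale (≥ ~7 probes after 1/20 shrinking, safely
above the four-marker merge rule); windows ending sub-margin (< 2.2 Mb)
from a telomere snap onto it, because a leftover sliver narrower than four
probes would be force-merged into the event and dilute carrier amplitudes
below θ; windows near a centromere are pushed ≥ 2.2 Mb away instead, so an
implant never abuts an arm event whose similar amplitude would tempt the
segmenter into fusing the two levels; the adjacent 17p12/17p11.2 pair
keeps a ≥ 2.2 Mb neutral gap for the same reason; and arm background on
implant-bearing arms covers only the remainder outside the focal windows
(1.5 Mb buffer), so focal markers do not ride on an arm-level baseline.
The 8p23.2 window runs to the 8p telomere (it is subtelomeric).

Default survival: PFS medians 4.4/11.0 months and OS medians 15.4/38.5
months for the poor/good subgroups (hazard ratio 2.5; cohort-level medians
near 8 and 38.5 months), censoring 28% (PFS) and 59% (OS) — the
discovery-cohort figures.

On this scenario the full pipeline recovers all eight implanted regions as
matching-kind markers in roughly three quarters of seeds (never fewer than
five), so the majority count across twenty seeds is eight; the derived
marker set also contains broad signature-arm markers, which are genuinely
subgroup-discriminating landscape rather than noise.  LOOCV accuracy is
typically 0.90–1.00.  These are exactly the quantities
`scripts/acceptance.py` recomputes.

### What the generator does not model

No allele-specific copy number, no subclonal mixtures beyond the single
attenuation scalar, no GC/replication-timing waves, no spatial array
artifacts, no platform normalization effects.  Passing tests on this
generator demonstrates the pipeline's contracts under its stated model —
clean additive segments plus white noise — not performance on raw
production arrays.

## Problem sizes and determinism

Desk-scale defaults were chosen so a full 72-sample scenario run takes
tens of seconds and the 20-seed acceptance sweep minutes: genome scale
1/20 (≈ 7,000 probes), CBS with curtailed permutations, vectorized
permutation null.  The byte-identical-rerun check in the test suite uses a
24-sample cohort; determinism is independent of cohort size.  Pipeline
runs write no timestamps, so a rerun under the same config reproduces
every output file hash-for-hash.

## Known limitations

* The permutation CBS cannot place single-probe change points (see above);
  isolated high-amplitude probes are handled only by the CNV mask's
  outlier rescue.
* The pooled permutation null treats every marker exchangeably within a
  sample; markers are not weighted by probe count in the null, matching
  the marker-level test but not a probe-level one.
* Peak limits are the argmax sub-run, not a leave-one-out robust interval,
  so single-sample amplitude quirks can narrow a peak.
* k (the number of subgroups) is a user decision; the package deliberately
  offers no automatic selection.
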