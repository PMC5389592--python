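# Methods

This note documents the models, defaults, and numerical choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model

A sample is a peak list: one row per detected feature with neutral
monoisotopic mass (Da), CE migration time (min), and signal intensity
(arbitrary units). Peak lists are assumed deconvoluted and deisotoped
upstream; charge envelopes, isotope patterns, and raw m/z profiles are out
of scope. Masses are monoisotopic throughout, computed from the pyteomics
`std_aa_mass` residue table plus one water (18.0105647 Da); no
post-translational modifications are modelled.

## Synthetic study generator

The generator emulates a two-strain longitudinal design: 2 strains × 7
animals × 3 time points (NP, GD12, GD18) = 42 samples, with every animal
sampled at every time point (paired design).

**Peptide universe.** Seven fixed uromodulin C-terminal fragments — the
18-mer SGNFIDQTRVLNLGPITR at 592–609 plus six nested sub-fragments of the
same region — and, by default, 180 background fragments: random in-protein
substrings (8–40 residues, unique sequences) of eight synthetic background
proteins, with log-uniform base intensities over [10², 10⁵]. The shipped
protein database is a deterministic synthetic scaffold (random residues
with the region of interest spliced in: R at 591, the 18-mer at 592–609, S
at 615); it is *not* the UniProt rat sequence, and is labelled synthetic
wherever it appears. The background size (180) is a desk-scale stand-in
for the thousands of peptides of a real urinary peptidome, chosen so that a
full study simulates in well under a second while every downstream
behaviour (filtering, multiplicity, family-wise adjustment) is exercised;
all replicate-based checks in the test suite use this size.

**Migration time.** A fixed monotone logistic map of log-mass onto the
calibrated 19–50 min window, plus a per-peptide jitter of ±1.5 min. The map
is a modelling convenience: only the calibrated range matters downstream,
not electrophoretic physics.

**Calibrants.** Ten fixed synthetic "housekeeping" peptides spanning
roughly 0.7–2.9 kDa (hence a wide migration-time spread), each at intensity
5000, always detected, never carrying effects.

**Measurement model.** Per sample: an affine migration-time drift with
slope ~ N(1, 0.02) clipped to [0.95, 1.05] and intercept ~ N(0, 0.4)
clipped to [−1, 1] min; additive time noise of SD 0.05 min; multiplicative
mass error of SD 10 ppm (TOF-typical, well inside the 50 ppm matching
window); a global per-sample intensity factor exp(N(0, 0.3)) emulating
injection/concentration variation; mean-one log-normal intensity noise with
CV 0.25 per peak; and Bernoulli detection with probability logistic in
log-intensity (midpoint 300, scale 0.4 natural-log units), so low-abundance
peptides drive the ≥70% frequency filter while abundant ones are always
seen. Calibrants are exempt from dropout.

**Effects.** `null` sets every abundance factor to 1. `paper_like`
multiplies each Umod fragment in the hypertensive strain by 4 at GD12 and 8
at GD18 (1 at NP), so the summed-Umod hypertensive/control ratio equals
those folds by construction, and gives a random 10% of background peptides
a pregnancy-dependent fold of 2^N(0,1) at GD12 and GD18. `custom` applies a
user table. All factors are recorded in the ground-truth table.

**Seeding.** One root seed fans out through `numpy.random.SeedSequence`
children in a fixed order (universe, effects, study-level draws, then one
child per sample in design order); identical (config, seed) reproduces
byte-identical peak lists, and any stage can be re-derived independently.

**What passing tests do not show.** The generator draws independent
log-normal noise per peak and has no correlated batch structure, no
retention-order inversions, no adducts or charge-state splits, no missing
samples, and a synthetic protein database. Recovery results on it bound the
pipeline's algorithmic correctness, not its performance on real urine.

## Calibration

"Local and linear regression against calibrants" is implemented as: match
each reference calibrant to its nearest observed peak by mass within a wide
100 ppm bootstrap window (wider than the clustering tolerance because
calibration has not happened yet); discard matches that break the reference
migration order (longest-increasing-subsequence filter); require ≥3
survivors, else the sample fails calibration. The time map is a global
least-squares line from observed to reference minutes — global linear
matches the affine drift model; an optional piecewise-linear "local" mode
interpolating between consecutive calibrants is available but off by
default. Mass correction is a single ppm offset (the median signed
deviation — TOF mass error is multiplicative, and the median resists one
mismatched calibrant), applied as division by (1 + offset·10⁻⁶). Intensity
normalization is the single factor that equalizes summed calibrant
intensity to the reference sum (a ratio estimator; a regression-based
estimator would also be defensible, but the ratio is exact under the
multiplicative sample-factor model and keeps the summed-calibrant invariant
exact). Calibration never reorders migration times (slope > 0 enforced).
Calibrant peaks are dropped after calibration by default so internal
standards do not enter clustering as analytes.

## Clustering

Both tolerance ramps are read as linear between their printed anchors and
clamped outside: mass tolerance 50 ppm up to 800 Da rising to 75 ppm at
20 kDa; time tolerance 0.4 min up to 19 min rising to 2.5 min at 50 min.
Admission requires both criteria individually (Chebyshev distance ≤ 1 in
tolerance-normalized units); ties between equally-near centroids break by
normalized Euclidean distance, then by cluster age.

The algorithm is a greedy running-centroid pass — the incremental
equivalent of annotating each new sample against a growing consensus
database, and deterministic for a fixed sample order (samples are processed
in sorted sample-id order). Within a sample, peaks are processed
nearest-first against the centroids existing at sample start, so when two
peaks of one sample compete for a cluster the closer peak wins and the
displaced peak seeds a new cluster; assignments are re-verified against the
current centroid position before committing, since centroids move as
members join (running mean, exact). A diagnostic
(`permutation_robustness`) measures the fraction of peaks whose assignment
changes under random sample-order permutations; on well-separated data it
is 0, and the greedy partition provably coincides with single-linkage over
the pairwise-compatibility graph (asserted against a brute-force oracle in
the tests).

## Differential statistics

Non-detections enter as intensity 0 (the standard reading of an absent
CE-MS peak); an NA-exclusion mode exists behind
`StatsConfig.treat_zero_as_missing`. The frequency filter retains a peptide
when its detection fraction reaches ≥70% in at least one strain ×
time-point group, with a 1e-12 epsilon so 5/7 passes 0.70 exactly.

The rank-sum test enumerates all C(nA+nB, nA) group assignments of the
mid-ranks and reports p = P(|W − E[W]| ≥ |w − E[W]|), which handles ties
exactly and reduces to the classical exact two-sided p on tie-free data
(cross-checked against scipy's exact method); enumeration is used whenever
C(nA+nB, nA) ≤ 2·10⁵ (always at n = 7 per group), with a tie-corrected,
continuity-corrected normal approximation beyond. Note the exact test is
discrete: at n = 7 vs 7 its attainable size at nominal 0.05 is 130/3432 ≈
0.038, so null rejection rates deliberately sit *below* 0.05.

BH adjustment (statsmodels `fdr_bh`) is applied per named comparison family
— one family per cross-sectional comparison (hypertensive vs control at
each time point) — and q-values drive everything downstream: the
per-time-point significance flags, the pattern classification
(all_timepoints / GD12_and_GD18 / single_timepoint / none, with the first
two retained for further analysis), and the regulation calls (q ≤ 0.05 and
fold ≥ 1.5 or ≤ 1/1.5; fold changes are ratios of arithmetic group means of
normalized intensities, oriented hypertensive/control, with "exclusive" and
"undefined" flags for all-zero denominators). Adjusting before classifying
was a design choice; the alternative order (classify on raw p, adjust
after) is not exposed.

The repeated-measures ANOVA is the one-way within-subject F test,
F = MS_time / MS_(time×subject) on (t−1), (t−1)(s−1) df, computed
closed-form (validated against statsmodels `AnovaRM` and the paired-t
identity F = t² at two time points) on animals with complete longitudinal
series; the reported `rm_anova_p` is computed within the hypertensive
strain (the strain whose disease-specific markers the screen confirms),
with the control strain's p alongside. The cross-sectional screening test
is the unpaired rank-sum even though animals are paired across time points
— within-strain longitudinal contrasts would support a signed-rank test,
which is noted as a limitation rather than silently substituted.

Degenerate cases: all values identical → p = 1; RM-ANOVA with zero time
sum-of-squares → p = 1, zero error sum-of-squares with a nonzero time
effect → p = 0.

## Annotation and protein summaries

MS/MS identification is replaced by mass lookup against a pluggable
candidate table (in the synthetic pipeline, the ground truth — a deliberate
substitution, since de novo sequencing is out of scope). All (cluster,
candidate) pairs within tolerance (default: the clustering mass-tolerance
ramp at the cluster's mass) are assigned greedily by ascending |ppm error|,
one-to-one. Protein summaries sum the annotated peptide rows per sample —
exactly linear in the matrix — and report group means and per-time-point
between-strain fold changes.

## Protease prediction

Matching is deliberately single-position (P1/P1' only): it keeps every
prediction auditable against the site context. The default rule table
encodes conventional textbook preferences — trypsin-like serine proteases
(hepsin, plasminogen, granzyme A) after K/R; chymotrypsin-like cathepsin G
after F/Y/W/L; neutrophil elastase after small aliphatics (A/V/I/T); MMP-3
and MMP-12 with hydrophobic P1' (L/I/V/F/M); meprin A subunit α with
acidic/small P1' (D/E/S/T) — with meprin Aα at medium confidence and the
others low. These residue sets are curation choices, shipped as replaceable
TSV data, not measured specificities; quantitative cleavage-efficiency
scoring and protease-expression context are out of scope.

## Pipeline and reproducibility

The one-shot runner executes simulate → calibrate → cluster → stats →
annotate → proteases, failing fast with the offending stage named, and
writes a manifest with the config hash, per-stage output checksums, counts
at each filter, and wall time. Identical config and seed give identical
checksums; stage-by-stage CLI runs reproduce the one-shot outputs. The
YAML config round-trips exactly and rejects unknown keys, nested or not.

## Replicate sizes

Stochastic validation uses 200-replicate batteries for the null-calibration
and effect-recovery checks, 100 replicates for drift recovery and the
clustering oracle, and 25/30 replicates in the acceptance script's
fold-change and null summaries; at the default study size these are the
points where the replicate means are stable to well within the asserted
tolerances.
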