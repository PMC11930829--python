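# Methods

## Data model

All analyses operate on per-sample, per-CpG-site **MEPM** values
(methylated alleles per million mapped molecules). The denominator is
the sample's total molecule count from the upstream molecule-calling
step, not raw reads — the assay's QC and counting logic are all
molecule-based. Absent measurements are true zeros (no fully methylated
molecule observed), so matrices admit no missing values. Site
coordinates follow the BED convention (0-based, half-open); the choice
is internal bookkeeping only, since no operation consumes coordinates
beyond identity.

QC excludes samples with fewer than 10,000 total molecules (strict
less-than: a sample at exactly 10,000 is retained). Cohort splits are
stratified by condition; each stratum contributes `round(0.6·n)` samples
to the discovery side of a 6:4 split, which reproduces 30+31 / 20+21
from 50 patients and 52 controls.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, with known ground truth. It is first-class, tested
code — the packaged experiments run on it.

**Background (normal plasma).** Each site in each sample is positive
with probability `background_pos_freq` (default **0.01**); a positive
site's magnitude is log-normal with arithmetic mean
`background_magnitude_mean` (default **5 MEPM**) and log-scale SD
`dispersion` (default **0.8**). With a 120-marker panel this puts
control positive counts at 0–6 with median ~1, i.e. the sparse
low-level background regime of healthy plasma.

**Tumor signal (plasma).** A case adds an independent
occupancy/magnitude channel at its fired sites: occupancy
`min(0.95, tumor_occupancy · m_stage)` and log-normal magnitude with
mean `tumor_magnitude_mean · m_stage`, where `tumor_occupancy = 0.30`,
`tumor_magnitude_mean = 30 MEPM` and the stage multipliers are
I:1, II:1, III:1.5, IV:3. Identical stage-I/II multipliers make the
early-stage count ranges overlap, as seen in real cohorts, while stage
IV cases approach saturation (~108/120 positive).

**Tissue.** Both tissue types share a baseline channel (occupancy 0.4,
magnitude mean 5 MEPM → ~2 MEPM expected). Tumor tissue adds a channel
at fired sites with occupancy 0.9 and magnitude chosen so that the
expected cancer/adjacent ratio equals `tissue_hyper_effect` (default
**8**); at the defaults the expected cancer mean at markers is 16 MEPM,
comfortably above the 10-MEPM selection criterion. A `cimp_fraction`
(default 2/33) of tumors has its tumor-channel magnitude multiplied by
`cimp_boost` (default 3) at every fired site — the high-methylation
(CIMP) subgroup.

**Marker structure.** Each cancer type owns a planted panel
(PAC 120, HCC 38, CRC 80, GC 153 sites by default). A fraction
`shared_marker_fraction` (default 0.25) of each panel is *pan-cancer*:
those sites fire in tumors of every type, so other cancers light up a
quarter of the PAC panel on top of background — shared tumor biology —
while the remaining sites are type-private and carry the origin signal.
Planted markers get motif distances < 60 bp; half of the decoys
(configurable) violate the motif rule. All outputs are bit-reproducible
given the seed; independent streams per cohort keep, e.g., the
calibration normals independent of the discovery cohort.

**What the generator does not emulate.** Marker-to-marker amplitude
differences, per-patient tumor-burden heterogeneity (every same-stage
case has the same expected occupancy), between-site correlation,
batch/depth effects, and fragment-level properties. Passing tests
therefore demonstrate that the pipeline recovers planted structure
under its own model assumptions at realistic magnitudes — not clinical
performance on real cfDNA.

## Differential methylation

Per site, a two-tailed Mann–Whitney U test: for pooled n ≤ 12 the U
distribution is enumerated exactly over all group assignments of the
mid-ranked pooled values (two-sided p = 2·min(P(U≤u), P(U≥u)), capped
at 1); above that, the tie-corrected normal approximation with
continuity correction. An all-tied site returns p = 1. BH-FDR is applied
across all sites tested in one call (one family per comparison). Fold
changes use a 0.5-MEPM pseudocount in both numerator and denominator —
zero means are routine in plasma and the ratio must stay defined; the
both-zero case gives fold 1.

## Marker selection

Tumor-vs-normal selection is the conjunction of four criteria, with the
boundaries read strictly from their definitions: MWW p < 0.01 with the
cancer mean above the adjacent mean; motif distance < 60 bp (60 fails);
mean cancer-tissue MEPM ≥ 10; normal-plasma positivity frequency < 5%
(positivity = any nonzero value, configurable threshold). The tissue
test is unpaired even on paired cohorts; pairing is retained only as
metadata. Panels are ordered by ascending selection p-value, which also
defines the candidate ranking for panel sizing. Cross-cancer panels use
p < 0.01 plus fold change > 2 between the two tumor types, ≥ 5 MEPM in
the favored type, and the same normal-plasma criterion; the fold-change
directions make the two panels disjoint by construction.

## Positivity-counting classifier

A sample's panel statistic is the number of markers with MEPM strictly
above the per-marker threshold (default 0). The count cut-off is
calibrated on an independent normal-plasma cohort; the default `max`
policy takes the largest calibration count, guaranteeing 100%
specificity on the calibration set, with a quantile policy as the
alternative. Classification is positive iff count > cut-off (strict).
Specificity on *new* controls is then a matter of binomial chance —
occasionally one control in ~30 exceeds the calibration maximum, which
is inherent to the policy rather than a defect.

Panel size is chosen by Monte Carlo cross-validation: for each of
`n_splits` stratified 50/50 train/test splits and each candidate size
s, the positive count over the top-s ranked candidates is standardized
(train statistics) and mapped to a case probability by a univariate
logistic model (scikit-learn, C = 1; the count→probability link is a
modeling choice, as is the 50/50 split), scored on the test half with
the Brier score. The size minimizing the mean Brier wins; exact ties go
to the smallest size. Standardizing the count keeps the regularization
comparable across sizes.

The packaged panel-sizing experiment runs in the weak-shedding regime —
a single-cancer catalog (exactly 120 informative sites among 3000) and
early-stage cases at 10% per-marker positivity, 30 cases vs 31
controls, 200 splits. In the default strong-signal regime the Brier
curve saturates by ~50 markers and the minimum's location is decided by
Monte Carlo noise; panel sizing is informative precisely when individual
markers are weak and patients can present with only a handful of
positive markers, and in that regime the curve is U-shaped with an
interior minimum at the informative panel size.

AUC is computed by the rank formulation (Mann–Whitney U over case/control
score pairs, ties at 0.5), with ROC points from scikit-learn.

## Methylation score

LASSO feature selection standardizes candidates, runs an L1-logistic
path (40 penalties, log-spaced) under 10-fold stratified CV scored by
validation deviance, and applies the one-standard-error rule (strongest
penalty within one SE of the minimum). Selected markers are refit
without penalty on raw MEPM values (statsmodels Logit). Perfect
separation — the expected case for a well-chosen panel — falls back to a
ridge-stabilized fit (L2, C = 1000, fitted on standardized values and
back-transformed), flagged in `training_meta`. The score is the full
linear predictor `Coef₀ + Σ Coefᵢ·Aᵢ`: an intercept is included so that
the zero threshold of the waterfall sign rule is meaningful, and a score
of exactly 0 is called negative, favoring specificity.

Two properties of this procedure are worth knowing. First, on separable
data deviance-based CV rewards confidence, so the 1-SE penalty retains
some noise features in any single fit; selection is *stable* rather than
sparse-exact — strong features are selected in every replicate, while no
noise feature is reproducibly selected across seeds. Second, the number
of selected features is not exactly monotone in the penalty in the dense
region of an l1-logistic path (features can drop back out); monotonicity
holds in the sparse regime.

Stage flags use the full diagnostic panel: a patient is
late-stage-compatible only when the positive count exceeds 8 or the
total positive methylation exceeds 150 MEPM (strict boundaries);
anything else is indeterminate because early- and late-stage ranges
overlap.

## Consensus clustering and CIMP

Resampled consensus clustering: 500 subsamples of 80% of samples,
Ward/Euclidean hierarchical clustering on log1p-transformed MEPM
(robust to the heavy right tail), consensus(i,j) = co-clustering rate
among co-drawn resamples. Samples are processed in sample-id order so
results are equivariant under input permutation.

The number of clusters is judged from the consensus distribution. The
classical relative delta-area rule on the consensus CDF is computed and
reported, but it tracks `1 − mean(consensus)`, which keeps growing with
k on any data and over-calls k badly when subgroups are imbalanced (a
31-vs-2 split has a tiny k=2 area, so later spurious splits look like
large relative gains). The default decision rule is therefore PAC
minimization — the proportion of pairs with ambiguous consensus, mass in
(0.1, 0.9) — with ties to the smallest k and a fallback to k = 2 when
even the best k leaves > 20% of pairs ambiguous (structureless data).
On planted scenarios (2 balanced blobs / 3 blobs / noise / 31-vs-2
CIMP) PAC returns 2/3/2/2 where delta-area returns 3/3/4/6.

With k = 2, the CIMP cluster is the one with the larger median
per-sample total methylation over the diagnostic panel (the feature
space also defaults to the panel, since that is where CIMP is defined);
an exact median tie is an error, not a silent choice. Final assignments
come from average-linkage clustering of 1 − consensus.

## Multi-cancer typing

Each sample is evaluated against all four calibrated panels. No positive
panel → non-cancer; exactly one → that cancer; several → the flagged
panel with the largest fraction positive, where fractions are exact
rationals (`Fraction(count, panel_size)`) so that ties are exact
arithmetic ties (30/120 vs 20/80 ties at 1/4) and yield an indeterminate
call. The decision is invariant to panel order.

## Problem sizes and defaults

The packaged experiments use the cohort sizes of the study design they
emulate: 33 (or 30) tissue pairs, 30 + 31 discovery plasma samples, 96
calibration normals, 25 cases per cancer type in the four-cancer cohort,
3000-site catalogs, 200 Monte Carlo splits for panel sizing, and 200–500
consensus resamples. The packaged fixed seed is 42; the acceptance
script derives every stream from its `--seed` argument instead.

## Known limitations

* The generator's independence assumptions (sites, patients) understate
  real-data correlation; recovery rates here are upper bounds.
* The count→probability logistic in panel sizing and the 50/50 split
  ratio are modeling choices; the selected size is stable under them at
  the packaged settings but the Brier differences between neighboring
  sizes are small.
* The max-policy cut-off trades a guaranteed calibration-set specificity
  for binomial variation on new controls.
* CIMP labeling presumes exactly two clusters; k ≠ 2 is an explicit
  error rather than a forced relabeling.
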