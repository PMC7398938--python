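# Methods

## Model

The pipeline estimates a habitat-suitability function
P(presence | x) from presence points and pseudo-absences, where x is a
vector of gridded environmental predictors. Five classifiers are fitted
to the same binary-response feature table and their probability maps
are combined into a consensus. The workflow assumes (i) presences are a
biased-but-informative sample of occupied cells, (ii) cells far from
any presence are acceptable stand-ins for absences, and (iii) the
species–environment relationship is transferable to shifted (future)
covariate values — the standard, and strong, assumptions of
correlative SDM under climate-change projection.

## Stages, parameters and defaults

**Pseudo-absence sampling.** `n_pseudo_absences = 500` background
points are drawn uniformly at random from valid grid cells (at cell
centres, so predictor values always exist), rejecting cells whose
haversine distance (WGS84 mean radius 6371.0088 km) to *any* presence
is below `min_distance_km = 10`. The default implementation rejection-
samples in batches (oversampling factor 10, at most 100 batches); an
alternative "posthoc" mode draws first and filters afterwards, which can
return fewer points and mirrors a generate-then-remove protocol. A
capacity error reports the exact number of eligible cells when the
request cannot be met.

**Train/test split.** `train_fraction = 0.7`, stratified by label with
round-half-up within each label, so label proportions are preserved to
±1 record; whether to stratify was an open choice and stratification
was chosen because it keeps both classes in both partitions at any
sample size. Both partitions are forced non-empty per label.

**VIF screen.** `vif_threshold = 3`. One variable — the one with the
largest VIF — is removed per iteration, with ties broken by column
order, rather than removing all offenders at once: collinear groups
share inflated VIFs, and dropping one member often clears the rest.
R² is computed by least squares (`numpy.linalg.lstsq`) with an
intercept; R² ≥ 1 − 1e−12 is reported as infinite VIF. VIF is computed
on the pooled (train + test) table. Categorical land cover never enters
the screen (VIF is defined for continuous regressors) and is always
retained.

**Learners.** Hyperparameters are fixed, logged in the run config, and
deliberately untuned: GLM = unpenalised logistic regression on
standardized features; SVM = RBF SVC (C = 1, gamma = "scale") wrapped in
sigmoid (Platt) calibration fitted by 5-fold CV on the training fold,
since the ensemble averages probabilities; RF = 500 trees; BRT =
gradient boosting with learning rate 0.01, depth 3, up to 1000 rounds,
early-stopped on a 20% holdout of the training rows. The MARS-family
member is an adaptive piecewise-linear logistic model built in-package:
reflected hinge pairs max(0, x − t)/max(0, t − x) with knots at the
0.1–0.9 training quantiles are added greedily (each step keeps the
candidate pair with the largest deviance reduction, stopping at 21
basis functions or when the reduction falls below 1e−4 per
observation). Land cover is one-hot encoded with levels frozen at fit
time; unseen levels encode to all zeros. All fits are deterministic
given the seed.

**Evaluation.** AUC uses midranks (exact Mann–Whitney equivalence to
pair counting, ties count half). The TSS threshold scans every distinct
score (predict presence when score ≥ threshold) and keeps the smallest
maximiser; max-TSS was chosen as the threshold rule because it is the
natural companion to TSS reporting. AUC bands: > 0.9 high, (0.7, 0.9]
moderate, (0.5, 0.7] low, ≤ 0.5 random — i.e. the "high" band requires
strictly more than 0.9.

**Consensus.** Unweighted mean over members with TSS > 0.75 (a
TSS-weighted mean exists behind `tss_weighted`, default off). A
separate discard rule for TSS < 0.5 would be subsumed by the 0.75 gate
and is not implemented separately. The member set is fixed on the
current-climate evaluation and reused for future scenarios, so current
and future maps come from the same consensus. If no member passes the
gate the run halts with an explicit gate error rather than silently
averaging weak models.

**Change assessment.** Class breaks default to (0.25, 0.5, 0.75) on the
consensus probability; the four-class scheme's thresholds were an open
choice and equal-width quartiles were adopted, isolated in config.
Classification is value ≤ b1 → not suitable, (b1, b2] → low,
(b2, b3] → moderate, > b3 → high. Class shares are percentages of valid
cells; optional cell-area weighting multiplies each cell by cos(lat)
(hectares via the mean-radius arc length, 111.195 km/degree). The
indicators AC = (Af − Ac)/Ac·100 and CH = (Af − Ac)/Af·100 satisfy
AC·Ac = CH·Af exactly, which is asserted internally before rounding;
reported values are rounded to one decimal, halves away from zero. The
published change table that the worked-example tests reproduce contains
two cells in its low-suitability column (21.9 and 43.8) that are
inconsistent with any rounding of the formula applied to the published
shares (recomputation gives 22.0 and 43.9); the recomputed values are
treated as authoritative and those two cells are checked to within 0.1.

**Zonal summaries.** Zones may be an integer mask grid or shapely
polygons (tested against cell centres). Each zone reports class
percentages and a risk label = the plurality class; zones with no valid
cells are flagged and excluded.

## Virtual-species generator

The generator emulates the statistical structure of a national-scale
SDM input set so that every stage is testable offline with known truth:

- **Covariates**: Gaussian white noise smoothed with a kernel of scale
  `autocorr_range` (default 6 cells) and re-standardized — smooth
  random fields standing in for bioclimatic layers. Collinear copies
  add N(0, 0.1²) noise to a parent (correlation ≈ 0.995), giving the
  VIF screen true redundancy to find. Land cover is a smoothed field
  cut into 4 integer classes at its quartiles.
- **Truth**: logistic suitability with default coefficients
  (2.5, −2.0, 1.5) and intercept −1.0 on three informative covariates.
  The signal strength was set so that the fitted models reach the skill
  range reported for the real national dataset this design emulates
  (per-model AUC ≈ 0.87–0.96, TSS ≈ 0.8), placing the 0.75 consensus
  gate meaningfully below, but not trivially below, member skill.
- **Presences**: `n_presences` distinct cells drawn with probability
  proportional to true suitability (default 662; the benchmarking
  fixture uses 500 presences against 500 pseudo-absences).
- **Futures**: additive shifts of each informative covariate in the
  direction of its coefficient, scaled 1.0 / 1.6 / 2.2 / 3.0 for the
  four scenario–horizon combinations — a monotone "warming helps the
  invader" emulation of stabilisation vs high-emission pathways.
- **Geometry**: 64×64 grid of 0.05° cells anchored at 39°E, 12°N
  (an arid-lowland window), cell-centre registration, row 0
  northernmost.

What the generator does **not** emulate: observation bias in
presences, non-additive or spatially heterogeneous climate change,
interactions or threshold responses in the true niche, nodata
coastlines, and real bioclim inter-variable correlation structure.
Passing tests therefore demonstrate the machinery recovers a known
smooth logistic niche under clean sampling — not that any real-data
map is correct.

## Problem sizes and numerical choices

The test fixture (64×64 cells, 500 presences + 500 pseudo-absences,
five learners) runs the full pipeline in well under a minute while
leaving enough test-partition points (300) for stable AUC/TSS
estimates. Degenerate inputs fail loudly and specifically: constant
columns in VIF, single-class training data, empty domains, zones
without cells, geometry mismatches, and indicator denominators of zero
each raise a named error. ASCII-grid round-trips preserve values to
%.10g; determinism is enforced by seeding every stochastic component
from the run seed with fixed offsets, and verified by byte-identical
rerun checksums in the manifest.

## Known limitations

- Pseudo-absences carry no sampling-bias correction (no target-group
  background).
- No spatial cross-validation; the 70/30 split ignores spatial
  autocorrelation, so reported AUC/TSS are optimistic for clustered
  data.
- Future projections reuse the current-climate member set and assume
  niche stationarity.
- The hinge-basis MARS member does no backward pruning.
- Cell-area weighting uses the cos-latitude approximation, adequate at
  the sub-degree cell sizes used here.
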