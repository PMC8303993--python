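# Methods

This note documents the statistical models, the choices made where the
procedure was genuinely open, and what the synthetic-data experiments do
and do not demonstrate.

## Densitometry and normalization

A lane profile is a sampled intensity trace along the migration axis.
Each reference band is quantified as its **peak volume**: the trapezoidal
integral of the raw profile over a fixed window
`nominal_position ± window_halfwidth`, with no background subtraction and
no per-lane re-centering of the band position.  The fixed window makes
the operation deterministic and exactly testable against planted peak
areas; window halfwidths are configurable because published band tables
give positions but not widths.  Window edges are included as interpolated
points so the integral does not depend on the sampling grid's phase.
Overlapping windows are integrated as given, with a warning.

**Quantile normalization** (used for the ISm line) forces every lane to
the common distribution defined by the across-lane mean of the sorted
rows.  Ties receive the exact mean of their tied reference quantiles (not
an interpolation at the average rank, which differs for three-way and
larger ties).  Consequences worth knowing: the operation is idempotent;
on tie-free data every lane ends with the identical value multiset; and
the per-lane **total** band intensity becomes constant by construction,
which is why the total-intensity model (below) always uses raw totals.
Normalization is applied to raw (not log) intensities, the simplest
reading of the published setting; a log variant can be composed manually.

**Cyclic loess** (used for ISy) operates on `log2(intensity + offset)`
(offset default 1.0, standard for intensity data that may contain zeros).
For each pair of lanes a lowess curve (span default 0.7, three cycles) is
fitted to M = difference vs A = average and half the fitted trend is
removed from each lane; the symmetric update leaves each pair's A values
and the grand log2 mean exactly unchanged.  Values are mapped back and
clipped at zero.

## Global venom-composition analysis

**PERMANOVA.**  Euclidean distances on the band matrix; sequential
(Type I) sums of squares with temperature entered before replicate,
computed by projecting the centered response onto the orthonormalized
design blocks; pseudo-F per term; p-values by freely permuting rows,
`p = (1 + #{F* ≥ F}) / (1 + n_perm)` with 5000 permutations by default.
The distance and permutation scheme were open choices; Euclidean + free
permutation matches the default behaviour of the standard R
implementation (`adonis2`), against which the decomposition is verified
exactly in the tests.  An exhaustive mode enumerates all row permutations
for tiny inputs.  R² values are deterministic given the data; only
p-values depend on the seed.

**Replicate centering** shifts every replicate's per-band mean onto the
grand mean, removing batch structure while leaving within-replicate
deviations untouched.  After centering, the replicate term of a PERMANOVA
is numerically zero.

**LDA.**  Fisher discriminant axes solve `S_b v = λ S_w v`; with three
groups two axes are kept, unit-normalized with the largest-magnitude
loading positive.  Bands are not standardized to unit variance first
(open question in the source procedure; raw intensities are kept so that
loadings remain in intensity units).  A ridge term `ridge · trace(S_w) · I`
(default 1e-8) regularizes near-singular within-group scatter; disabling
it turns singularity into an explicit error that names the option.

**Trend arrow.**  Ordinary least squares of the second discriminant
coordinate on the first across the three temperature centroids, oriented
from the 20 °C toward the 30 °C centroid.  If the centroids are vertical
in the plane (no spread on LD1) the axis direction (0, ±1) is used; fully
coincident centroids are an error.  Individuals get a scalar **arrow
score**: the projection of their (LD1, LD2) score on the arrow direction.
"Correlated with the linear regression" is operationalized as correlation
with this scalar projection — the only scalar consistent with arrows and
correlation circles living in the discriminant plane.

**Band screen.**  Per band, Spearman ρ against the arrow scores with
Bonferroni correction over the number of bands; adjusted p < 0.05 defines
the candidate set, each candidate carrying sign(ρ) as its trend.
Constant bands have undefined correlation and are flagged and excluded.

## Direct versus indirect bands

All bands are clustered by UPGMA on the metric distance 1 − |ρ|
(Spearman), and the dendrogram is cut at height 1 − 0.45, so bands with
average absolute correlation ≥ 0.45 share a cluster.  Clustering uses all
bands; the conditioning sets use only co-clustered *candidates* (the
published screen examines "clusters with at least two bands correlated to
the regression").  For each candidate in such a cluster, a rank-based
partial correlation with the arrow score, conditioning on the other
candidates of the cluster, is computed from the inverse correlation
matrix of the rank-transformed variables (identical to rank
residual-on-residual regression, which the tests assert to 1e-10);
p-values use the t reference with n − 2 − k df.  Bonferroni correction
uses the number of bands screened in this second step — the smallest
defensible family.  A candidate stays **direct** iff its adjusted partial
p < 0.05, otherwise **indirect**; singleton candidates are direct with
their marginal sign; everything else is **unaffected**.  Conditioning
sets larger than n − 3 are an explicit error.

Annotation joins the classification with a band → protein table;
proteins with ≥ 10 peptide matches in the proteomic reference are flagged
abundant.  The packaged tables for ISm and ISy transcribe the published
band contents (markers: LbGAP, LbGAP2, LbSPNm, LbSPNy, LbGAPy4).

## Outcome statistics

**Derived responses** per dish: parasitism rate = (mono + multi) vs
non-parasitized (all larvae); parasitic success = L+LOC vs CC;
encapsulation capacity = LOC+CC vs L; inhibition capacity = L vs LOC+CC;
escape capacity = LOC vs CC — the last four on mono-parasitized larvae
only, since multi-parasitism confounds the outcome.  Dishes with no
informative larvae are dropped from the affected metric (logged), and
escape-capacity dishes with ≤ 2 encapsulation-responding larvae carry a
`sparse` flag so they can be excluded from contrasts (the CLI does so).

**Binomial GLMM.**  Logit link, random intercept per replicate (or
capillary), estimated by maximizing the Laplace approximation to the
marginal likelihood over the fixed effects and log-SDs jointly, with the
random-effect modes solved by penalized Newton iterations — the same
approximation as lme4's `glmer` (nAGQ = 1), with which the tests require
agreement within 1e-3 on coefficients (observed ~1e-5).  Fixed-effect
covariances are conditional on the variance parameters.  The Pearson
overdispersion ratio (χ² at the conditional fitted values over
n − p_fixed − p_variance df) is computed on this first fit; if it exceeds
2, the model is refitted with an additional observation-level random
intercept (OLRE) and flagged.  Complete separation (a temperature level
with only successes or only failures, as in the near-100%/0% cells of
real assays) is detected and flagged, not hidden.  The overall
temperature test is a likelihood-ratio test against the intercept-only
model with the same random structure, chosen over the Wald test as the
better-calibrated default.  Note a blind spot of the ratio rule itself:
when the true extra-binomial variance puts the ratio near 2, the rule
skips the OLRE on some datasets and the test inherits mild
anticonservatism; with clearly present (or clearly absent) overdispersion
the type-I error is calibrated, which is what the 500-simulation
experiment verifies.

**Tukey contrasts.**  Differences of estimated marginal means on the link
scale.  Binomial fits use the single-step multivariate-normal adjustment
(probability that the maximum |Z| of the jointly normal contrasts exceeds
the observed value); Gaussian fits use the classical studentized-range
reference with the containment df.

**Monte-Carlo Fisher test.**  Tables with the observed margins are drawn
by Patefield's algorithm (`scipy.stats.random_table`); the p-value counts
simulated tables whose multivariate-hypergeometric probability is at most
the observed one (with the customary 1e-7 log-scale tolerance),
`p = (1 + #{≤}) / (1 + n_sim)`, n_sim default 2000.  Zero-margin rows or
columns are dropped with a warning.

**Gaussian LMM.**  statsmodels `MixedLM` (REML) with a random replicate
intercept; if the default optimizer walks into a singular profile the fit
falls back to derivative-free optimizers.  An optional maximum-likelihood
Box-Cox transform precedes fitting (positive values required; the error
names the offset remedy).  The temperature effect is a Wald F with
**containment** denominator df: the number of distinct
temperature × replicate cells minus the number of fixed-effect
parameters — 15 − 3 = 12 in the balanced 3 × 5 design, matching the df
pair reported for the real data.  A constant response returns a
degenerate-flagged fit rather than an optimizer crash.

## Synthetic data: what it emulates and what it does not

`BandSimSpec` reproduces the study design: 3 temperatures × 5 replicates
× 7 females = 105 individuals, 35 bands.  Three **direct** bands have
expected intensity linear in temperature (signs +, −, +), three
**indirect** bands equal their parent's realized value plus Gaussian link
noise — so the partial correlation of an indirect band with the trend
given its parent is zero by construction — and the rest are unaffected.
Replicate offsets are drawn per band and replicate and shared by the
replicate's individuals; intensities are clipped at zero because
silver-stain volumes are non-negative.

Defaults, chosen once: baseline intensities uniform on [50, 150];
`effect_size` 2.0 intensity units per °C (a 20-unit shift across the
20→30 °C range, twice the residual SD — a strong effect);
`replicate_sd` 2.5 (replicates then explain ≈ 6% of total variation, the
order observed in real venom data); `noise_sd` 10; `link_noise_sd` 8.
This regime keeps each parent/child pair in its own correlation cluster
(inter-parent |ρ| ≈ 0.3 < 0.45, parent–child ρ ≈ 0.85), which is the
regime in which the screen's ideal behaviour is provable.  With much
stronger per-band effects all planted bands merge into one cluster and
the conditioning step removes nearly all trend signal, leaving partial
correlations dominated by the noise the LDA score carries — a real
property of the published procedure, not an implementation artifact.

Recovery experiments run on the raw simulated matrix (`normalization
="none"`): the generator plants no lane-loading artifacts, so there is
nothing for normalization to remove, and the per-lane monotone remap of
quantile normalization would distort the additive parent + noise
construction (the child's partial-correlation null SD inflates from
1/√n ≈ 0.095 to ≈ 0.16).  Passing recovery therefore shows the screen
works when its assumptions hold; it does not certify behaviour on real
gels, where normalization is both necessary and mildly distorting.

`OutcomeSimSpec` draws per-dish parasitized counts with a
temperature-specific logit plus a dish-level normal intercept (the source
of extra-binomial variation relative to a replicate-level model), splits
off multi-parasitized larvae, and divides the rest among L/LOC/CC by a
baseline-CC multinomial logit with a second, independent dish intercept.
Defaults mirror the real assays: 30 larvae per dish, 15 dishes per
temperature in 5 replicates, parasitism ≈ 77% at 20/25 °C dropping at
30 °C, success declining with temperature, 15% multi-parasitism, dish SD
0.5.  Not emulated: larva-level covariates, host-species differences
within one run, and temporal structure of replicates.

`MelanizationSimSpec` draws ordinal classes 0–5 from a cumulative logit
model with a per-temperature-step latent shift (default −1, matching the
observed decline of *D. melanogaster* melanization at higher temperature)
and capillary random intercepts; capillaries are assigned round-robin so
each serves every temperature, as in the assay.

## Problem sizes used in the test suite

The calibration experiments use 500 null datasets each (PERMANOVA at 999
permutations on the full 105 × 35 design; GLMM at 50 dishes per
temperature with decisive planted overdispersion), screen recovery uses
50 seeds, effect recovery 100 seeds, and the lme4/vegan oracle
comparisons use small fixtures of 30–36 observations.  These sizes give
Monte-Carlo standard errors around 0.01 on rejection rates while keeping
the whole suite in the ten-minute range on a single CPU.

## Known limitations

- Band positions are not re-estimated per lane; real gels with migration
  drift need aligned profiles before quantification.
- Only the published quantification setting (no background, peak volume)
  is implemented; other background modes are out of scope.
- The binomial GLMM supports crossed random intercepts only (which covers
  every model used here), not random slopes or nested structures.
- The ratio > 2 overdispersion rule has a boundary blind spot (see above);
  users with borderline ratios may prefer to force the OLRE.
- Cyclic loess is O(rows² · iterations) lowess fits; fine for hundreds of
  lanes, slow for thousands.
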