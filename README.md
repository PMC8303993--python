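# venomtherm

Rearing temperature changes what is in a parasitoid wasp's venom.
`venomtherm` is a reusable Python implementation of the analysis pipeline
behind that finding for *Leptopilina boulardi* (lines ISm and ISy)
parasitizing *Drosophila* hosts: it quantifies venom protein bands from
1D-gel lane profiles, tests how venom composition shifts across rearing
temperatures (20/25/30 °C), screens which bands respond to temperature
directly rather than through correlated bands, and models the outcomes of
host–parasitoid immune interactions (encapsulation, capsule escape,
melanization) with binomial mixed models.  A synthetic-data module
generates gels, band matrices and parasitism assays with known ground
truth, so every statistical step is testable by recovery experiments.

It is aimed at researchers analyzing individual-level venom profiles or
host–parasitoid assay counts who want the full chain — densitometry →
normalization → multivariate trend → band screen → mixed models — as
tested library code rather than a collection of scripts.

## The analysis in brief

**Venom composition.** Each individual's venom is a vector of reference
band intensities (peak volume: the integral of the lane profile over a
fixed window, no background subtraction), normalized between lanes by
quantile normalization (ISm) or cyclic loess on log2 (ISy).  A sequential
PERMANOVA on Euclidean distances partitions variation into temperature and
replicate.  After centering within replicates, a linear discriminant
analysis of the three temperature groups yields two axes; the least-squares
line through the 20/25/30 °C centroids (the *trend arrow*) summarizes the
direction of venom change.  Each band b is screened by Spearman
correlation ρ_b between its intensity and the individuals' projections on
the arrow, Bonferroni-corrected.  Because correlated bands can ride along,
bands are clustered by UPGMA with distance 1 − |ρ| and cut at |ρ| = 0.45;
within each cluster holding ≥ 2 candidate bands, a rank-based partial
correlation with the trend, conditioning on the co-clustered candidates,
decides *direct* versus *indirect*.  Direct bands are joined with their
known protein content (proteins with ≥ 10 peptide matches count as
abundant).

**Interaction outcomes.** Dissected mono-parasitized larvae fall into
L (free parasitoid larva), LOC (free larva + open capsule) or CC (closed
capsule).  Derived per-dish binomial responses (parasitic success =
L+LOC vs CC, encapsulation = LOC+CC vs L, escape = LOC vs CC, …) are fitted
with binomial-logit GLMMs (Laplace approximation, random intercept per
replicate or capillary).  When the Pearson overdispersion ratio of the
first fit exceeds 2, an observation-level random effect is added.  Tukey
single-step contrasts compare temperatures; a Monte-Carlo Fisher exact
test checks melanization-class × temperature independence; Gaussian LMMs
(optionally Box-Cox transformed) handle continuous responses such as
total band intensity, with containment denominator df (F(2, 12) in the
balanced 3 × 5 design).

## Worked example

```python
from venomtherm import synthdata
from venomtherm.pipeline import run_global_analysis

spec = synthdata.BandSimSpec(seed=1)          # 105 wasps x 35 bands
matrix, truth = synthdata.simulate_band_matrix(spec)
res = run_global_analysis(matrix, normalization="none",
                          n_permutations=5000, seed=1)

print(res.permanova.table.round(3))
print(res.screen.table.query("classification != 'unaffected'")
      [["cluster", "classification", "sign", "rho", "partial_p_bonferroni"]])
```

prints

```
              df      sum_sq     r2  pseudo_f  p_value
term
temperature    2   58832.165  0.129     7.839      0.0
replicate      4   30328.156  0.066     2.020      0.0
Residual      98  367766.121  0.805       NaN      NaN
Total        104  456926.442  1.000       NaN      NaN
         cluster classification  sign       rho  partial_p_bonferroni
band_id
band_4        29         direct     1  0.764068              0.000002
band_5        29       indirect     0  0.620578              1.000000
band_16       28         direct    -1 -0.716732              0.000005
band_17       28       indirect     0 -0.619096              1.000000
band_28       29         direct     1  0.779225              0.000007
band_29       29       indirect     0  0.676612              1.000000
```

Temperature explains 12.9% of venom-composition variation in this
simulation (p = 2·10⁻⁴ at 5000 permutations, printed as 0.0 after
rounding) and replicates 6.6%.  All three planted direct bands are
recovered as direct with the planted trend signs (+1 = intensity rises
with temperature, −1 = falls), and each band's noisy copy is correctly
demoted to *indirect*: its marginal correlation with the trend is strong
(|ρ| ≈ 0.62), but its partial correlation vanishes once its parent band
is conditioned on.

The same steps are available from the shell:

```bash
venomtherm simulate band-matrix --seed 1 --out sim/
venomtherm screen --matrix sim/band_matrix.csv --n-perm 5000 --seed 1 \
    --normalization quantile --out report.csv
venomtherm simulate outcomes --seed 2 --out assay/
venomtherm outcomes --counts assay/outcomes.csv --metric parasitic_success
```

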