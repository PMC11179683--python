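# Methods

This note documents the statistical model, the simulation design, the
numerical choices, and the known limits of the package. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Null hypothesis and test statistic

The test concerns the stochastic-extremeness ordering of association
statistics inside versus outside a pre-specified network. Writing $T_N$ for
a statistic drawn at a random in-network location and $T_{N^c}$ for one
drawn outside, the null is that $T_N$ is *not* stochastically more extreme
than $T_{N^c}$ — i.e., neither upper-tail probabilities beyond positive
thresholds nor lower-tail probabilities beyond negative thresholds dominate.
`ecdf_extremeness_diagnostic` plots exactly these paired tail curves for
inspection; it is a diagnostic, not a test.

The enrichment score operationalizes the ordering: ranking all locations by
signed $T_v$ and walking the weighted running sum, the walk can only climb
near the extremes of the list if in-network values are both large in
magnitude and sign-consistent. ES is invariant to positive rescaling of the
map and symmetric under global sign flips (both covered by property tests);
it is *not* invariant under sign-inconsistent enrichment, which is outside
the current definition.

The key design choice — inherited from sample-permutation GSEA — is the
unit of randomization. Permuting **participants** regenerates the entire
association map under the null while preserving every spatial property of
the data, so exchangeability holds whenever subjects are exchangeable.
Permuting **spatial units** (the label-permutation null) or rotating the
label map (the spin test) instead assumes the map itself is exchangeable or
stationary across space, which smooth maps violate.

## Association statistics

* `gam_wald` (default): per location, least-squares fit of
  `x ~ 1 + sex + ns(age, df) + ns(age, df):sex` where `ns` is a fixed-df
  natural cubic regression spline with knots at evenly spaced age quantiles
  (boundary knots at the extremes). The basis is the standard
  truncated-power construction on numpy; because natural splines contain
  all linear functions, an exactly linear trend is reproduced exactly
  (tested). Effects map to coefficient blocks: **age** → all spline
  coefficients of both smooths (nonlinear age effects that may differ by
  sex); **sex** → the sex main effect plus the interaction smooth;
  **age × sex** → the interaction smooth only. The statistic is the
  quadratic form $\theta^\top \Sigma^{-1}\theta$ with the model-based
  covariance $\hat\sigma^2 (D^\top D)^{-1}$ (HC0 sandwich available behind
  `ModelSpec(robust=True)`), signed by the matching coefficient of a plain
  linear regression `[1, sex, age, age:sex]`; an exactly zero sign
  coefficient resolves to +1. Because the design is shared across
  locations, the whole map is computed with one pseudo-inverse; a
  per-location loop is retained for the robust covariance and verified
  against the vectorized path in tests.
* `ols_wald`: signed squared *t* of the effect coefficient in the linear
  design above. With a one-column spline basis the interaction block of
  `gam_wald` reduces to this exactly (tested).
* `pearson`: correlation of the measurement with the effect covariate
  (centered age, the female indicator, or centered age × sex). This is the
  fast statistic used in the large simulation suites.
* Degenerate locations (zero residual variance / constant measurement)
  yield $T_v = 0$ with a warning rather than ±∞. Singular covariance
  blocks raise; they are never silently pseudo-inverted.

Default `spline_df = 4` per smooth: a conventional choice for monotone-ish
developmental trends over a 8–21-year span; it is an explicit `ModelSpec`
field, not a constant.

## Permutation scheme and seeding

The default scheme permutes whole phenotype rows, keeping
covariate–covariate structure intact; a Freedman–Lane variant (permute
reduced-model residuals, refit on reconstructed data) is available for the
regression statistics when confounding structure warrants it. One master
seed spawns one `SeedSequence` substream per permutation, so the null
stream does not depend on execution order; with several networks tested
against the same data, the permutation association maps are computed once
and reused, with only the ES extraction differing per network.

The p-value uses the strict-inequality counting rule with the conventional
+1 in numerator and denominator, so $p \in [1/(K+1), 1]$. A `tie_ge` switch
selects the ≥ convention that counts ties against the observed score.

**Numerical tie guard.** Enrichment scores are cumulative sums; two walks
that both attain the theoretical maximum 1 can differ by ~1e-16 in floating
point, which would let rounding noise decide a strict comparison. All
permutation counting therefore treats scores within `atol = 1e-12` as tied.
Without the guard, saturated-signal settings show spurious non-monotone
power (null walks "beating" an observed ES of 1.0 by one ulp).

## Synthetic data

The generator emulates the statistical structure of resampled
cortical-surface studies rather than their anatomy:

* **Mesh** — an icosphere ($V = 10\cdot4^s + 2$); vertices play the role of
  registered surface locations. Networks are grown contiguously by
  multi-source BFS from random seeds, standing in for canonical
  parcellations.
* **Phenotypes** — age ~ Uniform(8, 21) years, sex ~ Bernoulli(0.5),
  matching a typical developmental-cohort design.
* **Measurements** — $x_i(v) = m(v) + \beta(v) g_i + \varepsilon_i(v)$ with
  a smooth subject-invariant anatomy surface $m$, an effect amplitude
  $\beta$ equal to `effect_size` inside the target network and 0 outside
  (optionally smoothed borders), and $g$ the effect covariate scaled to
  unit variance — so `effect_size / noise_sd` is the per-vertex
  signal-to-noise ratio and sweeps in multiples of σ are meaningful.
* **Noise** — per-subject Gaussian fields smoothed by `smoothness`
  neighbor-mean passes (default 10), rescaled to unit SD, then mixed with a
  per-subject, per-network random intercept carrying a fraction
  `network_coherence` (default 0.5) of the noise SD; the mixture keeps
  total variance at `noise_sd²`. The intercept is the generator's
  representation of *network-aligned smoothness*: null association maps are
  more coherent within networks than across their borders. This matters
  because an isotropically smooth field on the full sphere would leave the
  spin test exactly calibrated by rotation symmetry; it is the
  within-network excess coherence, not smoothness per se, that breaks the
  rotation null. Both drivers are zeroed in "white" control conditions.

All randomness flows from named substreams (phenotypes, noise,
network effects, permutation, anatomy) of one seed, so any stage can be
held fixed. `force_null` permutes phenotype rows while leaving the
measurement matrix untouched — associations are destroyed everywhere while
maps keep their spatial structure.

What the generator does **not** emulate: cortical folding and areal
distortion, modality-specific noise spectra, heteroskedasticity across the
surface, site/motion artifacts, or realistic network geometry. Calibration
results on these synthetics therefore demonstrate the *mechanism* of
competitor miscalibration and the validity of participant permutation under
exchangeability; they do not reproduce any real-cohort inflation
percentage.

## Experiments and problem sizes

`type1_experiment` / `power_experiment` / `compare_methods` run R
independent replicates of generate → (force_null) → test, reporting the
rejection rate at α with an exact Clopper–Pearson 95% CI; per-replicate
runtime is logged but never asserted. Methods compared in one run share
identical data streams (paired comparison), and reruns with the same master
seed reproduce every p-value bit-identically in sequential mode.

Desk-scale defaults are R = 200 replicates × K = 199 permutations on the
V = 162 mesh with the `pearson` statistic — chosen so a full calibration
study completes in seconds while keeping the binomial CI at ±0.03; the
paper-scale 1000 × 999 design is one argument away. The suite's
method-comparison check uses R = 300 to tighten the Monte-Carlo error
around the spin test's modest inflation (measured ≈ 0.08 at α = 0.05 under
the default smooth, network-coherent null, versus ≈ 0.6 for label
permutation and ≈ 0.05 for participant permutation).

`fdr_adjust` is Benjamini–Hochberg step-up (statsmodels), with the family
enumerated explicitly (e.g., 2 modalities × 3 effects × 7 networks = 42
tests); a hand-coded step-up scan serves as the oracle in tests.

## Spin-test details

Rotations are Haar-uniform via QR of a standard-normal 3×3 matrix with
sign correction and determinant fixed to +1. The *label map* is rotated
(matching the real-data orientation of the procedure); labels are
reassigned by nearest rotated neighbor under chord distance, which orders
identically to great-circle distance on the unit sphere. The default
alternative is one-sided on positive correlation; an absolute-value form is
available. Locations whose rotated source carries an excluded label can be
dropped from the null correlation.

## Degenerate inputs and tie-breaks

* Sort ties in the ranking break by ascending location index —
  deterministic and permutation-invariant given ids.
* A network that is empty or covers the whole map is rejected at partition
  construction; an all-zero in-network map makes the weighted running sum
  undefined and raises.
* Excluded locations (a medial-wall analogue) are dropped before ranking
  and never counted in the network or its complement.
* Readers match location and subject ids exactly, reject truncated rows,
  and refuse silent joins.

## Known limitations

* Enrichment is defined sign-consistently; sign-inconsistent enrichment
  (strong positive and negative associations in one network) is invisible
  to the weighted ES.
* No normalized enrichment score: ES values are not comparable across
  networks of very different sizes; only each network's own permutation
  null calibrates it.
* The GAM covariance is homoskedastic by default; the sandwich option
  covers per-location heteroskedasticity across subjects but not spatial
  error correlation, which the permutation null absorbs instead.
* Exhaustive enumeration is limited to n ≤ 8 subjects and exists as an
  oracle, not an analysis path.
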