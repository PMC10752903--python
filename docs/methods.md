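# Methods

This note documents the statistical machinery, the synthetic-data model and
its defaults, the numerical choices, and the known limitations of the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The Lepage statistic and its null moments

For samples x (n1 ≥ 2) and y (n2 ≥ 2), pooled midranks r_i give the
Wilcoxon rank sum W = Σ_{i∈x} r_i and the Ansari–Bradley score sum
A = Σ_{i∈x} a_i with a_i = min(r_i, n+1−r_i). The Lepage statistic is

    HK = (W − E[W])² / V[W] + (A − E[A])² / V[A],

asymptotically χ²(2) under exchangeability, so the 95% threshold is the
χ²(2) quantile 5.99 (`lepage_critical_value`).

**Moments.** Rather than hard-coding the textbook closed forms, both pairs
of moments come from the finite-population sampling identities applied to
the realized score vector s (= ranks for W, Ansari–Bradley scores for A):

    E[T] = n1·s̄,   V[T] = n1·n2 / (n(n−1)) · Σ(s_i − s̄)².

On untied data these reduce *exactly* to the closed forms (E[W] = n1(n+1)/2,
V[W] = n1n2(n+1)/12, and the even/odd-n Ansari–Bradley moments); with ties,
the midranks themselves carry the correction. The test suite verifies both
reductions against an exhaustive rational-arithmetic enumeration of all
C(n, n1) label assignments for every n1, n2 ≤ 6, and the tie-corrected V[W]
against enumeration up to n = 10.

**Degeneracy.** V[W] = 0 occurs only for an all-constant pooled sample.
V[A] = 0 also occurs for two-valued data split exactly at the step (all
Ansari–Bradley scores equal), so a noise-free binary step is degenerate *at
its own break point* — an inherent property of the scores, not an
implementation artifact. Degenerate windows raise a typed error from
`lepage_statistic` and are recorded as missing (with a stable warning code)
by the scan.

## The moving-window scan and break dating

For an annual series of length N and window w (default 9 years, matching
the canonical 9-year pre/post periods), every year t with w years before
and w years from t onward is a candidate; sample 1 is [t−w, t−1], sample 2
is [t, t+w−1], and the candidate is labelled by the pair (t−1, t). The
detected break is the candidate with the largest HK among those exceeding
the threshold, or none.

**Tie-breaking.** Rank statistics saturate: once two windows separate
completely, W attains its finite-sample extreme and the A-term vanishes, so
several candidates can tie at exactly the same HK even when the true break
is unambiguous. Exact HK ties are therefore broken by the larger absolute
mean contrast between the two windows — when rank information is exhausted,
the magnitude of the mean change is the natural secondary dating criterion.
A remaining tie falls back to the earlier year and is flagged.

**Small samples.** The asymptotic χ²(2) threshold is the default; a
permutation p-value (`permutation_pvalue`, exhaustive when C(n, n1) ≤ 1e5,
otherwise seeded Monte Carlo) is available for small windows. The measured
per-candidate null rejection rate at w = 9 is close to, and slightly below,
the nominal 5% (the HK null is discrete at these sample sizes); the
acceptance script recomputes it at 20,000 replicates.

No multiple-testing correction is applied across scan positions — the scan
is a dating device, not a family of independent tests.

## EOF decomposition

The annual anomaly field (each cell centred in time; checked, with a typed
error otherwise) is weighted by √cos(latitude), cells with any missing year
are dropped (never zero-filled — zero-filling biases the covariance), and
the (year × cell) matrix is decomposed by SVD. This is numerically
equivalent to eigendecomposing the weighted covariance matrix — an
equivalence the tests verify against an explicit covariance oracle — but
better conditioned. Eigenvectors have unit norm in weighted space; PCs
carry the variance, so their amplitude is comparable to the anomaly
amplitude; explained variance is the eigenvalue share, retained for *all*
modes so the fractions always sum to one, also within any sub-box
(`regional_explained_variance`).

Sign convention: each mode is flipped so the area-weighted mean of its
eigenvector over the target region is positive, making "positive phase
before the break" reproducible across runs and platforms.

## Regression attribution

`AttributionModel` fits GPP = α·Prec + β·Temp + γ·CO₂ + δ by OLS
(statsmodels behind the scenes). The intercept is included even though
normalized inputs make it ≈ 0: sub-period means are not zero, and δ cancels
in any period difference. Predictors are deliberately *not*
orthogonalized; contributions use the raw partial coefficients, and
near-collinearity (condition number > 1e8) is reported with a stable
warning code, not corrected. The per-factor contribution to the P2−P1
change is coefficient × (predictor P2-mean − P1-mean); by linearity these
sum to the reconstructed difference exactly (asserted to 1e-12 in the
tests). Correlation reports use the plain two-sided t transform of Pearson
r; an effective-sample-size adjustment for lag-1 autocorrelation is
available but off by default, mirroring standard practice in this analysis
family.

Normalization order: the pipeline z-scores the *JJA regional* series (after
spatial averaging), and records that order in its output metadata.

## Factorial decomposition

GPP_co2 = S1−S0, GPP_climate = S2−S1, GPP_total = S2−S0; additivity is an
algebraic identity and is preserved through every linear downstream step.
For Fig.-style period-difference tables, all three components of a member
are scaled by that member's GPP_total standard deviation over the full
period — one common scale per member. Per-component z-scoring would
destroy component additivity; a common scale preserves it (climate + CO₂ =
total row by row, asserted to 1e-10). Members are classified *strong* iff
the Lepage HK of their total-forcing series at the target break pair
exceeds the threshold; because the HK used for ordering members is
ambiguous in principle, tables report both the scan maximum and the HK at
the target break.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

| parameter | default | meaning |
|---|---|---|
| grid | 24–52°N, 100–149°E, 0.5° | East Asian analysis domain |
| target region | 40–52°N, 110–124°E | where the shift is imposed |
| years / break | 1980–2018 / 2000 | analysis period and prescribed break |
| `precip_step` | 2.0 | step size in interannual SDs |
| `ar1_coefficient` | 0.5 | year-to-year persistence of noise |
| `noise_sd` | prec 15 mm mo⁻¹, temp 0.6 K, rad 8 W m⁻², gpp 0.3 (normalized) | interannual SDs |
| `pdo_amplitude` / period | 0.5 / 25 yr | decadal index strength and period |
| `smoothing_cells` | 3 | Gaussian kernel width of spatial noise correlation |
| coupling (α, β, γ) | (0.8, −0.2, 0.3) | GPP sensitivity to Prec/Temp/CO₂ |
| CO₂ | 339 ppm + 1.8 ppm yr⁻¹ | linear ramp; only its normalized shape matters |
| ensemble | 8 strong (γ_climate 1.2–1.7, γ_CO₂ 0.1–0.3), 4 weak (0.30–0.45, 0.85–1.15) | sensitivity multipliers |

Construction details:

- Interannual anomalies are drawn once per year and broadcast to the
  twelve months, so a year's JJA mean inherits the anomaly exactly and
  `noise_sd` is the per-cell interannual SD by construction. Spatial
  correlation comes from Gaussian-smoothed white fields, renormalized by
  the kernel's L2 norm (periodic convolution keeps the variance uniform),
  so EOF modes are non-degenerate.
- The decadal index is a fixed-phase sinusoid (positive before the break,
  negative after — the phase relationship the phenomenon requires) plus
  AR(1) noise, projected onto a smooth loading centred on the target
  region. The step itself is imposed directly on precipitation inside the
  region box; the teleconnection that would mediate it dynamically is out
  of scope. Because the sinusoid is a deterministic signal, step-recovery
  tests that average over seeds set `pdo_amplitude = 0` to isolate the
  prescribed step.
- GPP is built from the generator's own climatology and population scales
  (z-surfaces), so with coupling (1, 0, 0) and zero noise the normalized
  regional GPP series is *identical* to the normalized precipitation
  series — an exact identity the tests assert.
- Ensemble members share one realization of the climate and CO₂ responses
  (as models driven by common forcing do) and differ in their sensitivity
  multipliers; each scenario adds an independent internal-variability draw,
  so S1−S0 for a CO₂-insensitive member is noise, not exactly zero. The
  default weak group's CO₂ gain roughly cancels its climate loss at the
  break (net shift ≈ 0), which is exactly what makes it undetectable.
- The truth sidecar records the break year, the coupling, the group labels
  (strong iff γ_climate ≥ γ_CO₂), and the deterministic per-factor
  contributions to the P1→P2 normalized GPP change, for recovery tests.

**What the generator does not emulate:** realistic seasonality beyond a
fixed monthly climatology, spatially varying climatologies, precipitation
non-negativity under extreme configurations (the model is deliberately
linear; the default step leaves monthly values positive), land-use forcing,
vegetation dynamics, or the land–atmosphere feedback. Passing tests
therefore demonstrate the *statistical machinery* — detection power,
calibration, recovery, identities — under the assumed structure, not the
fidelity of any real-world archive.

## Numerical and design choices

- JJA means are unweighted 3-month arithmetic means (month-length weighting
  changes values by < 1%); years missing any of the three months are
  dropped and logged.
- Region membership is by cell center, bounds inclusive —
  resolution-independent and unambiguous. Missing cells are excluded from
  the cosine-latitude weights. Regional totals use exact spherical cell
  areas (R²·Δλ·Δsin φ) and convert gC m⁻² month⁻¹ to TgC month⁻¹.
- Anomaly baseline defaults to the full analysis period (configurable).
- Regridding is bilinear (exact on planar fields, which the tests exploit);
  targets outside the source extent raise rather than extrapolate.
- All randomness flows through seeded generator streams
  (`numpy.random.default_rng([seed, stream])`); identical configuration and
  seed reproduce every array bit for bit, and pipeline outputs contain no
  wall-clock timestamps, so whole runs are byte-identical.
- NetCDF output is classic (NetCDF3) via xarray's scipy engine; series and
  tables are CSV; configuration, truth, and the run manifest are YAML with
  stable key order. Every output carries the configuration hash (computed
  over the scientific parameters only) and package version.
- Problem sizes in the test suite and acceptance script (e.g. 500-seed
  detection runs on a 1° grid, 200-seed ensemble recovery, 20,000-replicate
  null calibration) were chosen to give Monte-Carlo standard errors well
  inside the asserted margins at desk scale.

## Known limitations

- The PC of the leading EOF mode *exhibits* the regime shift (its scan is
  significant at the break), but dating a shift by the argmax of a PC1 scan
  is unstable when a domain-coherent trend mode (CO₂ fertilization) has a
  variance share comparable to the regional shift mode: near-degenerate
  modes mix. Dating is therefore done on regional anomaly series; PC1
  serves to localize and display the mode.
- The asymptotic χ²(2) threshold is slightly conservative at 9-year
  windows; the permutation option exists for smaller windows.
- The weak-group false-positive rate at the target break cannot go below
  the Lepage test's discrete size (~3% per member), which bounds how often
  all twelve ensemble labels are recovered simultaneously (~0.97⁴ ≈ 89% of
  seeds); per-decision label accuracy is ~99%.
- Scenario runs share forcing but not internal variability; real model
  ensembles also differ structurally in ways a sensitivity multiplier does
  not capture.
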