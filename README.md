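# gppshift

Detection and attribution of abrupt regime shifts in gross primary
productivity (GPP) over semi-arid East Asia — and a synthetic-data generator
that makes the whole analysis chain testable on a laptop.

## The scientific problem

Semi-arid ecosystems are water-limited: a step decrease in summer
precipitation can flip a region's vegetation productivity into a persistently
lower state. Detecting such a regime shift in a gridded GPP record, dating
it, and attributing it to its drivers takes four linked analyses:

1. **EOF analysis.** The dominant spatio-temporal mode of the
   June–July–August (JJA) GPP anomaly field is extracted by empirical
   orthogonal functions — a singular value decomposition of the
   √cos(latitude)-weighted (year × cell) anomaly matrix. The eigenvector map
   localizes the variability; the principal component (PC) is its time
   series; the eigenvalue fraction is the explained variance.

2. **Lepage change-point scan.** An abrupt shift is dated with the
   nonparametric Lepage statistic, the sum of the squared standardized
   Wilcoxon rank-sum (location) and Ansari–Bradley (scale) statistics:

   ```
   HK = [W − E(W)]² / V(W) + [A − E(A)]² / V(A)
   ```

   Under the null that two adjacent samples come from one distribution,
   HK ~ χ²(2); HK > 5.99 is significant at the 95% level. A 9-year moving
   window slides along the annual series, and the year pair with the largest
   significant HK dates the shift. Null moments are computed from the
   finite-population sampling formulas on the realized midrank scores, so
   tie correction is automatic and the moments match exhaustive enumeration
   exactly.

3. **Regression attribution.** The normalized regional GPP series is
   modelled as `GPP = α·Prec + β·Temp + γ·CO₂ + δ` by ordinary least
   squares. The change in the reconstruction between a pre-shift period P1
   and post-shift period P2 decomposes exactly into per-factor
   contributions `coefficient × (mean_P2 − mean_P1)` of each predictor.

4. **Factorial model decomposition.** Offline land-surface-model ensembles
   run factorial scenarios: S0 (pre-industrial everything), S1 (CO₂ varies),
   S2 (CO₂ + climate vary). Differencing isolates the CO₂-fertilization
   response (S1−S0), the climate response (S2−S1), and the total (S2−S0),
   identically additive. Members whose total response carries a significant
   Lepage shift at the target break form the *strong-shift* group; the rest
   are *weak* — in practice the weak models couple too strongly to CO₂ and
   too weakly to climate.

Because the real gridded archives are large external downloads, the package
ships a first-class synthetic generator (`gppshift.synthetic`) that emulates
the statistical structure of the phenomenon: a JJA precipitation field with
AR(1) interannual noise, a PDO-like decadal index, and a prescribed regional
step; GPP linearly coupled to precipitation, temperature, and CO₂; and a
12-member factorial pseudo-ensemble with strong and weak groups by
construction. Every generated dataset carries a ground-truth sidecar for
parameter-recovery tests.

## Worked example

Run the full synthetic study (generation → preprocessing → EOF → Lepage →
attribution → factorial) in one command:

```bash
gppshift run --synthetic --seed 1 --outdir out/
```

or from Python:

```python
from gppshift import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(outdir="out", seed=1))
print(result.scans["gpp"].summary())
print(result.attribution.summary(result.config.p1, result.config.p2))
print(result.ensemble.summary())
```

which prints (seed 1, default conditions):

```
Lepage moving-window scan
  region:     Eastern China-Mongolia
  window:     9 years per sample
  threshold:  HK > 5.991
  detected:   abrupt change in 1999-2000 (HK = 12.79)

GPP attribution (OLS on normalized drivers)
  years: 1980-2018  |  n = 39  |  R^2 = 0.985
   alpha (prec): +1.244
    beta (temp): -0.067
   gamma (co2): +0.411
  intercept (delta): -0.000
  P2-P1 reconstructed change and contributions:
      prec: -2.820
      temp: +0.015
       co2: +0.325
     total: -2.480

Factorial ensemble summary
  members: 12  |  strong: 8  |  weak: 4
  strong group: LSM01, LSM02, LSM03, LSM04, LSM05, LSM06, LSM07, LSM08
  weak group:   LSM09, LSM10, LSM11, LSM12
  P1': 1991-1999  P2': 2000-2008
  strong mean normalized P2'-P1' change: total -2.10 (climate -2.22, CO2 +0.12)
  weak mean normalized P2'-P1' change: total -0.12 (climate -0.99, CO2 +0.87)
```

Reading the output: the regional GPP series shifts abruptly between 1999 and
2000 (HK = 12.79 ≫ 5.99) — the prescribed break year. The regression
attributes the normalized P2−P1 decrease (−2.48) almost entirely to
precipitation (−2.82), partially offset by CO₂ fertilization (+0.33). The
ensemble classifier recovers exactly the eight members built to be
climate-sensitive; the weak group's total change (−0.12) is small because
its larger CO₂ response (+0.87) cancels its climate response (−0.99). The
first EOF mode explains 21.2% of the domain variance and its PC carries the
same 1999–2000 shift.

Single stages are available as subcommands (`gppshift lepage series.csv
--window 9`, `gppshift attribute panel.csv --p1 1990:1998 --p2 1999:2007`,
`gppshift eof field.nc --variable gpp`, `gppshift factorial ensemble.csv
...`) on CSV/NetCDF inputs; `gppshift simulate` writes the synthetic fields
as CF-style NetCDF with a YAML truth sidecar.

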