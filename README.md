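# spatialpanel

Spatial panel econometrics for province-level environmental-health
analysis: contiguity weight matrices, global Moran's *I* with
randomization/permutation inference, Moran-scatterplot quadrant
classification, and maximum-likelihood estimation of the three classic
spatial panel models — Spatial Durbin (SDM), Spatial Lag (SLM), and
Spatial Error (SEM) — with a synthetic-panel generator for testing and
power/recovery studies.

## The problem

Regional health outcomes such as respiratory-disease mortality are not
independent across neighbouring regions: air pollution (PM\_2.5 in
particular) spills across provincial borders, so ordinary panel
regressions of mortality on pollution are misspecified. The package
implements the standard spatial-econometric workflow for this setting
on a balanced panel of N regions over T periods:

1. **Weights.** A binary Rook-contiguity matrix W is built from a
   printed adjacency list (two regions are neighbours iff they share a
   boundary) and row-standardized so that `(Wx)_i` is the neighbour
   average. The packaged 31-region China table handles its single
   island (Hainan) by assigning Guangdong, its nearest province, as
   neighbour — a data decision encoded in the fixture, not in code.

2. **Exploratory spatial analysis.** Global Moran's *I*,

   I = Σᵢ Σⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / (S² Σᵢ Σⱼ wᵢⱼ),  S² = (1/n) Σᵢ (xᵢ − x̄)²,

   with E[I] = −1/(n−1) under the null, tested either against the
   normal approximation with the exact randomization variance
   (kurtosis-corrected) or by Monte-Carlo permutation; plus the
   HH/LH/LL/HL quadrant classification of standardized values against
   their spatial lags.

3. **Spatial panel models.** The general model

   y_it = α + ρ (W y_t)_i + (W x_t)'_i δ + x'_it β + μ_i + γ_t + ε_it,
   ε_it = λ (M ε_t)_i + ψ_it,  ψ_it ~ N(0, σ²),

   restricted to SDM (λ=0), SLM (λ=δ=0) or SEM (ρ=δ=0), estimated by
   concentrated maximum likelihood after demeaning out fixed effects:
   the scalar spatial parameter is optimized on its admissible interval
   (1/ω_min, 1) with the log-Jacobian computed from the eigenvalues of
   W, and β, σ² recovered by least squares at the optimum. Standard
   errors come from the numerical Hessian of the full likelihood.

4. **Synthetic panels.** Because the original mortality/PM\_2.5 panels
   are not redistributable, the generator simulates balanced panels
   from these same model equations, with covariates calibrated to the
   published descriptive moments, so estimator quality is measured by
   parameter recovery on known ground truth.

## Worked example

```python
import spatialpanel as sp
from spatialpanel.models import ModelSpec, fit_model, model_report

panel = sp.china_like_fixture(seed=42)   # 31 regions x 2004-2008
W = sp.china_weights()                   # row-standardized Rook contiguity

print(sp.moran_by_year(panel, "pm25", W).round(3).to_string(index=False))
fits = [fit_model(panel, W, ModelSpec(family=f)) for f in ("SDM", "SLM", "SEM")]
print(model_report(fits).round(4).to_string())
```

Output:

```
 year  moran_i     z   p
 2004    0.561 4.994 0.0
 2005    0.452 4.083 0.0
 2006    0.543 4.857 0.0
 2007    0.564 5.004 0.0
 2008    0.464 4.192 0.0

             SDM                      SLM                      SEM
           Coef.        Z       p   Coef.        Z       p   Coef.        Z       p
pm25      0.0276   6.6715  0.0000  0.0257   6.5102  0.0000  0.0285   5.5117  0.0000
lngdp     0.4759   3.1710  0.0015  0.4016   2.8275  0.0047  0.3948   2.2220  0.0263
lnhos    -0.1740  -1.7280  0.0840 -0.1607  -1.6007  0.1094 -0.1850  -1.5308  0.1258
lncost   -0.4996  -2.2301  0.0257 -0.5241  -2.3427  0.0191 -0.7436  -2.5820  0.0098
popudens  0.0028  13.3172  0.0000  0.0029  14.3423  0.0000  0.0032  12.3225  0.0000
delta     0.0007   1.5322  0.1255     NaN      NaN     NaN     NaN      NaN     NaN
rho       0.3829   3.8342  0.0001  0.4844   6.7145  0.0000     NaN      NaN     NaN
lambda       NaN      NaN     NaN     NaN      NaN     NaN  0.3927   2.9923  0.0028
sigma2_e  0.0629   8.6250     NaN  0.0630   8.6149     NaN  0.0777   8.5933     NaN
R2        0.7599      NaN     NaN  0.7565      NaN     NaN  0.7035      NaN     NaN
```

Reading it: the per-year Moran's *I* of PM\_2.5 (~0.45–0.56, all
p < 0.001) shows strong positive spatial clustering of pollution. In
the regression block, the SLM spatial parameter ρ̂ = 0.48 (p < 0.001)
says a region's mortality co-moves with its neighbours' mortality, and
the PM\_2.5 coefficients (~0.026–0.029) say each extra μg/m³ of PM\_2.5
raises respiratory mortality by about 0.03 deaths per 10,000 — on this
synthetic panel these estimates recover the data-generating values they
were simulated from (ρ = 0.5078, β_PM = 0.0289).

A CLI mirrors the library (`spatialpanel weights|moran|fit|simulate|
fixture|recovery|analyze`); `spatialpanel analyze --seed 7 --out out/`
runs the whole workflow and writes CSV artifacts plus a JSON run log.

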