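# ledcens

Classical and Bayesian inference for the **logistic-exponential
lifetime distribution (LED)** observed under **improved adaptive
Type-II progressive censoring (IAT-II PCS)** — for reliability
engineers and survival analysts who run life tests with staged unit
withdrawals and hard time limits, and need parameter, survival and
hazard estimates with honest uncertainty from the resulting censored
samples.

## The model and the censoring mechanism

A lifetime X follows LED(ν, η) when

    S(x) = P(X > x) = 1 / (1 + (e^{νx} − 1)^η),      ν, η > 0,

with rate ν (per unit time) and dimensionless shape η.  The family
reduces to the exponential law at η = 1 and covers constant,
increasing, decreasing, bathtub and upside-down-bathtub hazard shapes

    h(t) = νη e^{νt} (e^{νt} − 1)^{η−1} / (1 + (e^{νt} − 1)^η).

An IAT-II PCS life test starts n units with a removal plan
R = (R₁, …, R_m), Σ Rᵢ = n − m, and thresholds T₁ < T₂: Rᵢ survivors
are withdrawn at the i-th failure while it precedes T₁, withdrawals
are suspended once T₁ passes, and the test hard-stops at
T* = min(X_m, T₂).  Writing E₂ failures observed, executed removals
Rᵢ and B terminally withdrawn survivors, the likelihood is

    L(ν, η) ∝ ∏_{i≤E₂} f(xᵢ) · ∏_{i≤E₁} S(xᵢ)^{Rᵢ} · S(T*)^B .

The package provides the exact log-likelihood with closed-form score
and observed information, damped-Newton maximum likelihood,
normal-theory intervals for (ν, η) and delta-method intervals for
S(t), h(t), a componentwise random-walk Metropolis–Hastings sampler
under independent gamma priors with squared-error and LINEX point
estimates and percentile/shortest credible intervals, an exact
sequential-conditional IAT-II PCS simulator, a Monte Carlo
performance-study engine (bias, MSE, interval width, coverage), and a
goodness-of-fit pipeline with the packaged repairable-mechanical-
equipment (RME) benchmark data.

## Worked example

```python
import numpy as np
from ledcens import fit_mle, aci_params, plugin_reliability
from ledcens.analysis import ks_gof
from ledcens.datasets import rme_data, table4_sample

# Complete-data fit of the 30 RME failure intervals
fit = fit_mle(rme_data())
print(fit.estimates)            # LEDParams(nu=0.5415..., eta=1.5864...)
gof = ks_gof(rme_data(), "led")
print(gof.statistic, gof.pvalue)  # 0.0732... 0.9933...

# One of the packaged censored samples (case III: the test stopped at T2)
sample = table4_sample("A")
fit = fit_mle(sample)
print(fit.estimates)            # LEDParams(nu=0.3664..., eta=1.5621...)
print(plugin_reliability(fit, 0.5))   # (0.9245..., 0.2580...)
print(aci_params(fit)[1])       # shape interval (0.9085..., 2.2157...)
```

The complete RME data are well described by the LED: the
Kolmogorov–Smirnov distance 0.073 (p = 0.993) beats the Weibull
alternative (0.075, p = 0.991).  For censored sample A the fitted
rate is 0.366 and shape 1.562; the plug-in survival at t = 0.5 is
0.925 with hazard 0.258, and the 95% normal-theory interval for the
shape is (0.909, 2.216).

The same workflow is scriptable from the shell:

```sh
ledcens gof rme
ledcens fit-mle table4a --t-eval 0.5
ledcens analyze table4c --draws 5000 --seed 2
ledcens simulate --scheme scheme.yaml --nu 1.5 --eta 1.2 --seed 3
```

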