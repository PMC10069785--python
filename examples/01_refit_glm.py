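"""Refit a logistic GLM for known measurement error in one covariate.

A cohort-style binary outcome is regressed on a noisy exposure (think
systolic blood pressure measured with error) and two clean covariates.
The naive fit attenuates the exposure coefficient; the MCEM refit
recovers it and widens the standard error accordingly.
"""

import numpy as np
import pandas as pd

from eivfit import GlmFitter, MeasurementErrorSpec, naive_covariance, run_mcem

rng = np.random.default_rng(1)
n = 1000
exposure = rng.normal(0.0, 1.0, n)            # true (latent) exposure
age = rng.normal(50.0, 8.0, n)
smoker = rng.binomial(1, 0.3, n).astype(float)
eta = -1.0 + 0.9 * exposure + 0.03 * (age - 50) + 0.5 * smoker
y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)

sigma_u2 = 0.35                               # known error variance
data = pd.DataFrame({
    "exposure": exposure + rng.normal(0, np.sqrt(sigma_u2), n),
    "age": age,
    "smoker": smoker,
})

fitter = GlmFitter("binomial", ["exposure", "age", "smoker"])
fitter.builder.freeze(data)
naive = fitter.fit(y, data)
_, naive_se = naive_covariance(fitter, y, data, naive.beta)

spec = MeasurementErrorSpec(["exposure"], sigma_u2)
res = run_mcem(fitter, y, data, spec, B=50, seed=7)

print("coefficient (truth 0.9):")
print(f"  naive : {naive.beta[1]: .3f}  (SE {naive_se[1]:.3f})")
print(f"  MCEM  : {res.beta[1]: .3f}  (SE {res.se[1]:.3f})")
print(f"mean ESS {res.ess_mean:.1f} of B=50; converged in {res.n_iter} iters")
print("The naive slope is biased toward zero; the MCEM refit moves it back")
print("toward the truth and reports a larger SE reflecting the latent X.")
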