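"""Bias / RMSE / coverage study on the quadratic-logistic design.

Replicates the benchmark simulation at reduced size: binary responses with
logit P(Y=1) = 0.5 + X - 0.3 X^2, X ~ N(0,1), classical error on X.  The
table compares the naive fit and the MCEM correction for the quadratic
coefficient (-0.3) across error variances.
"""

from eivfit import SimDesign, run_sim_study

design = SimDesign(n=500, beta_true=(0.5, 1.0, -0.3), n_datasets=30,
                   B=30, seed=99)
_, summary = run_sim_study(design, sigma_u2_grid=[0.1, 0.25, 0.5])
print(summary.to_string(index=False, float_format=lambda v: f"{v:0.3f}"))
print()
print("rel_bias = mean(est - (-0.3)) / 0.3, rmse over replicates, coverage")
print("= share of 95% Wald intervals containing -0.3.  The naive bias and")
print("undercoverage grow with sigma_u2; MCEM stays near-unbiased with")
print("coverage close to the nominal level.")
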