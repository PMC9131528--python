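"""Maximum-likelihood path analysis of regional volumes and anxiety score.

Draws a cohort from a known linear path model (three regional volumes
predicting an anxiety score with standardized weights 0.6 / 0.4 / 0.2) and
refits it by maximum likelihood, reporting standardized coefficients,
chi-square, RMSEA and AIC.
"""

import numpy as np

from anxnet import sem, simulate

model = sem.PathModel.from_text("HADS ~ PFC + AMG + HIP")
true_paths = np.array([0.6, 0.4, 0.2])
theta_true = np.concatenate([true_paths, [1, 1, 1], [0, 0, 0],
                             [1 - true_paths @ true_paths]])

_, data = simulate.gen_sem_cohort(model, theta_true, n=5000, seed=21)
fit = sem.fit_ml(model, data)

print("standardized coefficients (true 0.6 / 0.4 / 0.2):")
for edge, s in fit.standardized.items():
    print(f"  {edge:10s} s = {s:.3f}")
print(f"chi2 = {fit.chi2:.4f}  df = {fit.df}  RMSEA = {fit.rmsea:.4f}  AIC = {fit.aic:.2f}")
# The saturated model (free predictor covariances) is just-identified, so
# chi2 ~ 0 and RMSEA = 0 by convention; the estimates should recover the
# generating standardized weights within sampling error (~0.013 at n=5000).
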