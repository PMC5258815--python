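"""Elastic-net predictor selection with repeated stratified holdout CV.

One binary predictor (B-dependent donor-specific reactivity) carries a
log-odds-ratio of 2 for graft dysfunction; five covariates are pure noise.
The penalized logistic path is tuned by mean holdout AUC with the
one-standard-error parsimony rule, then refit on the full data.
"""

import numpy as np
import pandas as pd

import camrspot as cs

rng = np.random.default_rng(4001)
n = 50
signal = rng.integers(0, 2, n).astype(float)
y = (rng.random(n) < 1 / (1 + np.exp(0.5 - 2.0 * signal))).astype(int)
X = pd.DataFrame({"bdep_dsr": signal})
for j in range(5):
    X[f"noise{j}"] = rng.normal(size=n)

spec = cs.ElasticNetSpec(alpha_grid=(0.5, 1.0), n_lambda=20, n_repeats=20, seed=1)
res = cs.elastic_net_select(X, y, spec)

print("selected predictors:", res.selected or "(none)")
print(f"winning penalty: alpha = {res.alpha}, lambda = {res.lam:.3f}")
print(f"cross-validated AUC: {res.cv_auc:.3f}")
print(f"refit AUC: {res.refit_roc.auc:.3f} "
      f"(95% bootstrap CI {res.refit_roc.ci95[0]:.2f}-{res.refit_roc.ci95[1]:.2f})")
sens, spec_ = res.refit_roc.best_operating_point
print(f"Youden-optimal operating point: sensitivity {sens:.2f}, "
      f"specificity {spec_:.2f}")
print("\nThe informative ELISPOT indicator dominates the selection; noise")
print("covariates are usually shrunk to zero, though at n=50 a chance-")
print("correlated covariate occasionally survives.")
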