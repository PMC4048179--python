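"""Fit the lasso and the graph-guided fused lasso on the same eQTL panel.

The fusion penalty pulls coefficients of correlated genes toward a shared
value, so a SNP that regulates a whole co-expression module is recovered for
all of its targets, where the plain lasso finds only the strongest few.
"""

import numpy as np

from structmap.benchmarks import support_f1
from structmap.networks import correlation_network
from structmap.preprocess import standardize
from structmap.simgen import eqtl_benchmark_config, simulate_dataset
from structmap.solvers import (
    cross_validate,
    default_lambda_grid,
    fit_gflasso,
    fit_lasso,
    lasso_fitter,
)

sim = simulate_dataset(eqtl_benchmark_config(seed=0))
Xs, _ = standardize(sim.genotypes.values)
Ys, _ = standardize(sim.expression.values)

grid = default_lambda_grid(Xs, Ys, n_points=6, ratio=0.05)
cv = cross_validate(lasso_fitter(tol=1e-4, max_iter=500), Xs, Ys, grid,
                    folds=10, seed=0)
lam = cv.selected.lam
print(f"10-fold CV selected lambda = {lam:.1f}")

res_l = fit_lasso(Xs, Ys, lam, tol=1e-7)
net = correlation_network(sim.expression, threshold=0.5)
res_g = fit_gflasso(Xs, Ys, net, lam, 0.5 * lam, tol=1e-7, max_iter=3000)

for name, res in (("lasso", res_l), ("gflasso", res_g)):
    B = res.dense()
    f1 = support_f1(B, sim.truth.B)
    print(f"{name:8s}: {int((np.abs(B) > 1e-3).sum()):4d} associations, "
          f"support F1 vs planted truth = {f1:.2f}, "
          f"objective {res.final_objective:.1f}")
# The fused fit should recover a larger fraction of each causal SNP's module
# (higher F1) at the same sparsity weight.
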