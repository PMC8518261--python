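"""Penalty selection with StARS: instability along the penalty path.

Fits the graphical lasso on random subsamples along a decreasing penalty
path and picks the least regularization whose edge-set instability stays
under the cut beta = 0.05.
"""

import tailored_glasso as tg
from tailored_glasso.core import empirical_covariance, graph_from_precision
from tailored_glasso.solver import solve_glasso

theta, truth = tg.generate_scalefree_precision(100, 0.2, seed=0)
data = tg.sample_mvn(theta, 80, seed=1)

res = tg.stars_select(data, tg.StarsConfig(n_subsamples=10, seed=2))
print("lambda      instability (monotonized)")
for lam, inst in zip(res.lambda_path, res.monotonized_path):
    marker = "  <- selected" if lam == res.lambda_opt else ""
    print(f"  {lam:.3f}     {inst:.4f}{marker}")

fit = solve_glasso(empirical_covariance(data), res.lambda_opt, validate=False)
graph = graph_from_precision(fit.theta_hat)
print(f"\nselected lambda {res.lambda_opt:.3f} -> {graph.n_edges} edges "
      f"(sparsity {graph.sparsity:.3f}) out of {truth.n_edges} true edges")
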