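# tailored-glasso

Sparse Gaussian graphical model estimation with data-tuned integration of
prior information — the **tailored graphical lasso**, together with the
unweighted and weighted graphical lasso it generalizes, StARS penalty
selection, extended-BIC model scoring, and a simulation benchmark.

## The problem

Gene, protein and other omics association networks are routinely estimated
as Gaussian graphical models: assuming the `p` measured variables are
jointly Gaussian, an edge between variables `i` and `j` corresponds to a
non-zero entry `θ_ij` of the precision matrix `Θ = Σ⁻¹`, with partial
correlation `ρ_ij = −θ_ij / √(θ_ii θ_jj)`.  With far fewer samples than
candidate edges (`n ≪ (p²−p)/2`), the graphical lasso makes estimation
possible by L1-penalizing the entries of `Θ`:

    Θ̂ = argmax_{Θ ≻ 0}  log det Θ − tr(SΘ) − λ‖Θ‖₁ .

When a related data source is available — say an mRNA network as prior
information for a protein–protein network — the *weighted* graphical lasso
penalizes each entry by `λ(1 − w_ij)`, where `w_ij ∈ [0, 1]` is the prior
confidence in edge `{i, j}`.  That trusts the prior blindly: misleading
weights distort the estimate, and weakly-scaled weights (partial
correlations rarely exceed 0.2 in omics data) barely register.

The **tailored graphical lasso** passes the weights through a logistic
transform `g_k(w) = 1/(1 + e^{−k(w−w₀)})` whose steepness `k` is chosen by
the data (extended BIC), under a penalty budget `λ_k‖P_k‖₁ = λp²` fixed by
a single StARS run on the unweighted problem.  `k = 0` recovers the
unweighted graphical lasso exactly, `k ≈ 4` approximates the plain weighted
one, and large `k` sharpens the prior into a near-binary trust decision at
the midpoint `w₀` (the lower β-quantile of the non-zero weights).  The
selected `k` is interpretable as a usefulness score for the prior: useful
priors earn a large `k` and improve the network; misleading priors drive
`k` to zero and cost nothing.

## Worked example

```python
import tailored_glasso as tg

theta, truth = tg.generate_scalefree_precision(100, 0.2, seed=0,
                                               also_feasible_for=0.2)
data = tg.sample_mvn(theta, 80, seed=1)          # the data of interest
prior_data = tg.sample_mvn(theta, 80, seed=2)    # related data, same network

stars = tg.StarsConfig(n_subsamples=10, seed=3)
W = tg.weights_from_prior_data(prior_data, stars)
result = tg.tailored_fit(data, W, gamma=0.0, stars_config=stars)

graph = tg.graph_from_precision(result.theta_hat)
prec, rec = tg.precision_recall(graph, truth)
```

Running `python examples/fit_with_prior.py` (exactly this pipeline) prints:

```
prior weights: 125 non-zero, max 0.210
selected steepness k_opt = 58  (0 = ignore prior, large = trust and sharpen it)
sigmoid midpoint w0 = 0.0014, StARS penalty lambda = 0.269, budget-preserving lambda_k = 0.536
estimated graph: 152 edges (sparsity 0.031)
against the true graph: precision 0.42, recall 0.64
```

The large selected `k` says the prior data carried real structure, and the
fit uses it: the unweighted graphical lasso on the same data reaches
precision ≈ 0.31 and recall ≈ 0.47 (see `examples/simulate_benchmark.py`,
which also shows `k` collapsing to ≈ 2 and the tailored fit matching the
unweighted one when the prior is completely misleading).

The other example scripts cover StARS selection
(`examples/stars_selection.py`) and the method comparison
(`examples/simulate_benchmark.py`).

## Command line

```sh
tailored-glasso weights --prior-data mrna.tsv --out weights.tsv
tailored-glasso fit --data rppa.tsv --prior-weights weights.tsv \
    --gamma 0.6 --seed 0 --out run
tailored-glasso simulate --case 1 --replicates 20 --seed 0 --out bench.tsv
```

`fit` writes the estimated precision matrix (TSV), the edge list, and a JSON
run report (selected `k`, `w₀`, penalties, eBIC path, sparsity, config echo).
Inputs are delimited text: data matrices with samples in rows and an optional
header of variable names; weight matrices square and symmetric with entries
in [0, 1].

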