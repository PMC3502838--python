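# ecgi — inverse ECG imaging by maximum margin clustering + SVR

Noninvasive electrocardiographic imaging (ECGI) estimates cardiac source
activity from body-surface potentials (BSPs). With an equivalent-double-layer
source model the forward relation is linear, `φ_B = A·φ_m`, where `φ_m` are
transmembrane potentials (TMPs) at the ventricular-surface source nodes and
`A` is the boundary lead-field operator. `A` is severely ill-conditioned
(here: 412 leads × 478 nodes, condition number 5.6×10¹²), so direct inversion
amplifies measurement noise and classical regularization (Tikhonov, LSQR)
heavily smooths the solution.

This package implements an alternative, regression-based reconstruction:

1. **Maximum margin clustering (MMC).** Training time instants (one scaled
   BSP vector per instant) are partitioned without labels by finding the
   labeling `y ∈ {±1}ⁿ`, `|Σ yᵢ| ≤ ℓ`, that admits the widest-margin
   separating hyperplane. The non-convex problem is solved by alternating a
   Laplacian-loss support vector regression (ε-SVR at ε = 0) against the
   current labels with an exact combinatorial bias/label update minimizing
   `Σᵢ |ω·φ(xᵢ) + b − yᵢ|`. Recursive bisection yields k clusters.
2. **Per-cluster multi-output SVR.** For each cluster, one Gaussian-kernel
   ε-SVR per source node maps scaled BSPs to TMPs,
   `f(x) = Σᵢ (αᵢ − αᵢ*) K(xᵢ, x) + b`, with
   `K(xᵢ, xⱼ) = exp(−‖xᵢ − xⱼ‖²/2σ²)`. Hyperparameters (C, σ, ε) are chosen
   per cluster by a genetic algorithm refined by Nelder–Mead simplex against
   cross-validated MSE.
3. **Routing + evaluation.** Test instants are routed down the MMC tree to
   their cluster's regressor. Accuracy per instant is reported as relative
   error `RE = ‖φᶜ − φᵉ‖/‖φᵉ‖` and Pearson correlation CC over nodes,
   against single-SVR, zero-order Tikhonov (SVD filter factors, L-curve
   corner λ) and LSQR (L-curve-selected early stopping) baselines.

A synthetic forward simulator generates the full study protocol — per-node
action-potential templates, a breakthrough-driven activation sequence, a
condition-controlled transfer matrix, 30 dB Gaussian noise, and the
358-instant record (0–357 ms at 1 ms) split into 298 training and 60 test
instants (test times 3, 9, …, 357 ms) — so every stage is testable without
external data.

## Worked example

```python
from ecgi import ExperimentConfig, HyperoptSettings, SimulationConfig, run_experiment

cfg = ExperimentConfig(
    simulation=SimulationConfig(n_leads=60, n_nodes=80),   # reduced protocol
    n_clusters=4,
    hyperopt=HyperoptSettings(folds=3, pop_size=6, generations=4,
                              output_subsample=10, simplex_max_iter=15),
    seed=1,
)
report = run_experiment(cfg)
for method, s in report.summary["methods"].items():
    print(f"{method:>11s}  mean RE {s['mean_re']:.4f}  mean CC {s['mean_cc']:.4f}")
print("cluster sizes:", report.summary["cluster_sizes"])
```

Output:

```
       lsqr  mean RE 49.2489  mean CC 0.0528
    mmc_svr  mean RE 0.0675  mean CC 0.9907
 single_svr  mean RE 0.0905  mean CC 0.9887
   tikhonov  mean RE 0.9414  mean CC 0.1499
```

with cluster sizes `{0: 71, 1: 78, 2: 72, 3: 77}`. Reading: at condition
5.6×10¹² with 30 dB noise the linear inversions barely recover the TMP
pattern (Tikhonov RE ≈ 0.94; LSQR's mean is inflated by a few unstable
instants), the single SVR reconstructs well (RE ≈ 0.09, CC ≈ 0.99), and
clustering the instants into four temporal regimes before regression
improves it further (RE ≈ 0.07). The same comparison is available from the
shell via `ecgi run --config experiment.yaml`, and `ecgi simulate`,
`ecgi cluster`, `ecgi baseline` expose the individual stages.

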