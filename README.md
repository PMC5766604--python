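# sparsesynergies

Where is hand control sparse? Reach-to-grasp movements are widely held to
be built from *synergies* — recurring patterns of coordinated joint
motion — but competing accounts disagree about where the economy lies:
in using few synergies per action (sparse combinations), in synergies
that each move few joints (sparse elements), in both at once (double
sparsity), or nowhere (the PCA baseline). This package implements all
four coding hypotheses as dictionary-learning estimators, benchmarks
them by multi-class grasp classification under additive Gaussian noise,
and quantifies how each representation distributes work across atoms and
joints. It is aimed at computational motor-control researchers who want
a tested, reproducible pipeline for kinematic synergy analysis.

## The model

Vectorized trials X ∈ R^{n×p} (p = sensors × time points, each sensor
normalized to [−1, 1]) are factorized as X ≈ U Vᵀ with synergy atoms in
the columns of V ∈ R^{p×r} and per-trial coefficients U ∈ R^{n×r}:

| hypothesis          | estimator                    | problem |
|---------------------|------------------------------|---------|
| no sparsity         | `SynergyPCA`                 | truncated PCA |
| sparse combinations | `L1SparseCoding`             | min ½(np)⁻¹‖X−UVᵀ‖²_F + η Σ‖U_k‖₁, ‖V^j‖₂ ≤ 1 |
| sparse elements     | `StructuredSparsePCA`        | min ½(np)⁻¹‖X−UVᵀ‖²_F + λ ΣΩ_v(V^k), ‖U^j‖₂ ≤ 1 |
| double sparsity     | `StructuredSparseDictionary` | min ½(np)⁻¹‖X−UVᵀ‖²_F + λ ΣΩ_v(V^k), ‖U_j‖₁ ≤ η, ‖V^i‖₂ = 1 |

Ω_v is the ℓ1/ℓ2 group norm over per-joint coordinate groups, so the
structured penalty switches whole joints on or off within an atom. All
estimators follow scikit-learn conventions (`fit`, `transform`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn model selection. Representations are compared through a
ridge one-hot classifier with validation-based hyperparameter selection,
per-subject t-score standardization, one-way ANOVA with post-hoc
t-tests, and the sparsity/usage/commonality/selectivity statistics.
Because no public dataset accompanies the benchmark design, a seeded
generator produces dataglove-like trials with known double-sparse ground
truth (9 classes × 50 trials, 10 sensors; see `docs/methods.md`).

## Worked example

```python
import numpy as np
from sparsesynergies import (SynthSpec, generate_dataset, split_dataset,
                             HyperGrids, select_and_test, metric_report)

dataset, truth = generate_dataset(SynthSpec(seed=3))
split = split_dataset(dataset.labels, seed=4)
grids = HyperGrids(r=[16], lambda_=[1e-4], eta=[10.0, 20.0],
                   lambda_rm=[1e-8, 1e-4, 1e-2])
record, art = select_and_test(dataset, split, "srssd", grids,
                              sigma=0.4, seed=0)
report = metric_report(art["U_test"], art["learner"].dictionary_,
                       art["y_test"])
print(f"test accuracy      {record.accuracy:.3f}")
print(f"selected eta       {record.eta}")
print(f"coeff sparsity     {report.coeff_sparsity:.3f}")
print(f"dict sparsity      {report.dict_sparsity:.3f}")
print(f"mean commonality   {report.mean_commonality:.3f}")
```

which prints

```
test accuracy      0.844
selected eta       10.0
coeff sparsity     0.124
dict sparsity      0.307
mean commonality   0.813
```

At moderate noise (σ = 0.4) the double-sparsity representation
classifies 84% of the noisy test trials into the nine grasp types
(chance is 11%); validation selected the tighter coefficient budget
η = 10, about 31% of dictionary entries and 12% of coefficients are
exactly zero at this mild group weight, and the high mean commonality
reflects the shared atoms every class draws on.

A CLI mirrors the library (`sparsesynergies generate / learn / metrics /
run-scenario1 / run-scenario2 / compare / raster`); tables are tidy CSV.

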