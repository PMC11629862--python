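# replicluster

Tools for studying a selective force that can drive bacterial metabolic
genes into clusters and operons: the perturbation of metabolite homeostasis
caused by DNA replication.

## The problem

In growing bacteria, loci near the replication origin are present in more
copies than loci near the terminus. Under the Helmstetter–Cooper model a
locus at fractional ori–ter position *p* has average copy number

```
n(p) = 2^[((1 − p)·C + D)/τ]
```

where C is the replication period, D the post-replication division delay
and τ the division time; the log₂ origin:terminus coverage ratio (the
peak-to-trough ratio of sequencing data, PTR) equals C/τ. When a cell
changes growth rate, genes at *different* positions change copy number —
and hence enzyme abundance — by *different* factors. Metabolic control
analysis shows that unequal enzyme fold-changes move metabolite pools,
potentially by large factors even for enzymes with negligible flux control,
whereas a coordinate fold-change merely rescales fluxes and leaves all
concentrations untouched (perfect homeostasis). Genes that co-locate on the
ori–ter axis therefore insulate their pathway's metabolite pools from
growth-rate shifts, which creates a selective pressure for gene clustering.

`replicluster` implements that whole chain of reasoning as testable code:

- **`replication`** — copy-number arithmetic: `average_copy_number`,
  `log2_ptr`, the per-cell `instantaneous_copy_number` with nested forks,
  transcript steady states and the growth-shift fold-change r.
- **`mca`** — finite-change response formulas (flux amplification factor,
  single-enzyme metabolite response), the replication-coupled flux
  response, and finite-difference flux/concentration control coefficients
  with their summation theorems (ΣFCC = 1, ΣCCC = 0).
- **`linlog`** — metabolic models in the linlog format
  `v = E (A′ + B′ log x + C′ log c)`, whose steady state is analytic:
  `log x = −(N E B′)⁻¹ (N E A′ + N E C′ log c)`.
- **`toy`** — the two-enzyme pathway `X_in → s → X_out` with
  `s_ss = (E1/E2)(k1/k2)X_in`, the scaled sensitivity
  `∂ln s/∂ln(C/τ) = (C/τ) ln2 (p₂ − p₁)`, and the CV position-scan surface.
- **`optimize`** — the homeostasis objective F (average coefficient of
  variation of steady-state metabolite concentrations across division
  times) and `GenePositionModel`, which fits gene positions — or, for
  comparison, promoter strengths — by box-constrained local minimization
  of F from random starts.
- **`evolution`** — a population simulation of gene-order evolution by
  inversions and translocations with fitness 1/F, median culling and
  fitness-proportional resampling, tracking pure and mixed cluster
  formation.
- **`proximity`** — the proximity score PS = −log₂(Q1 of pooled
  within-module gene-pair distances), PTR estimation from coverage
  windows, per-species one-sided t-tests (PTR > 1, PTR > 2), and the
  PS ~ log₂PTR regression.
- **`synth`** — synthetic coverage profiles, annotated genomes with
  planted clustered/scattered modules, random valid linlog models, and a
  packaged 34-reaction / 26-metabolite central-carbon benchmark model
  (glycolysis, pentose-phosphate pathway, TCA cycle, glyoxylate shunt,
  acetate exchange; glucose and acetate external).

## Worked example

```python
import numpy as np
from replicluster import (
    ReplicationParams, average_copy_number, carbon_fixture,
    GenePositionModel, ObjectiveConfig,
)

# A fast grower: C = 40 min, D = 20 min, dividing every 30 min.
rep = ReplicationParams(C=40, D=20, tau=30)
print(round(average_copy_number(rep, 0.0), 3),   # 4.0  copies at the origin
      round(average_copy_number(rep, 1.0), 3))   # 1.587 at the terminus

# Optimize the positions of the 34 carbon-metabolism genes for homeostasis.
model = carbon_fixture()
fit = GenePositionModel(model, ObjectiveConfig(mode="positions")).fit(
    n_runs=3, seed=42)
print(fit.summary())
```

Output:

```
4.0 1.587
Homeostasis optimization (positions mode): 3 runs, 34 genes
  start F: median 0.1279
  final F: median 7.329e-06 (best 6.039e-06, worst 2.011e-05)
  descent satisfied in 3/3 runs
```

A random gene layout leaves the average metabolite coefficient of
variation across division times (F) at ≈ 0.13 — a 13% typical swing in
metabolite pools between fast and slow growth. Optimizing gene positions
drives F to ≈ 10⁻⁵: the genes co-locate into clusters whose enzymes scale
together, so the metabolome barely notices the growth-rate change. Running
the same experiment in `mode="promoters"` (genes frozen, per-gene rate
multipliers optimized instead) converges orders of magnitude worse on
average — promoter strengths cannot track a τ-dependent copy-number ratio.

The evolutionary version, with explicit inversions and translocations:

```python
from replicluster import GeneOrderEvolution, EvoConfig
res = GeneOrderEvolution(model, EvoConfig(pop_size=2000, generations=2000)).run(seed=1)
print(res.summary())
```

prints the fitness gain of the fittest strain and the pure/mixed clusters
it accumulated.

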