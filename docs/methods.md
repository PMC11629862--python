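# Methods

## Replication copy-number model

A locus at fractional position p on its replichore (p = 0 at the origin,
p = 1 at the terminus; each arm of a circular chromosome maps independently
onto [0, 1]) has population-average copy number n(p) = 2^[((1−p)C + D)/τ],
with C the replication period, D the division delay and τ the division time
(all in minutes). Three consequences used throughout:

- log₂ of the origin:terminus copy ratio equals C/τ, which identifies the
  sequencing-coverage peak-to-trough ratio (PTR) with replication activity;
- a shift of division time τ₀ → τk multiplies the abundance of a transcript
  from position p by r = 2^[((τ₀−τk)/(τkτ₀))((1−p)C + D)] (times promoter
  and decay ratios when those also change), so faster growth (τk < τ₀)
  raises abundance everywhere except at the terminus with D = 0;
- the per-cell picture is discrete: with nested replication rounds at fork
  progresses g₁ > g₂ > … (round i carrying 2^(i−1) forks), a locus has 2^k
  copies where k counts rounds with g > p. Copy numbers are treated as
  continuous population averages everywhere except this per-cell view.

D is held constant across division times; nothing in the package models
replication-initiation control or fits C and D to data (PTR estimation from
coverage is a separate, purely descriptive operation).

## Linlog steady-state engine

Rates are v = E(A′ + B′ log x + C′ log c) with natural logarithms — the
standard linlog formulation. The primed parameters absorb a reference
steady state (A′ = (J⁰/E⁰)(1 − B log x⁰ − C log c⁰), B′ = diag(J⁰/E⁰)B,
C′ = diag(J⁰/E⁰)C), so rates at the reference state return J⁰ identically.
The steady state is analytic, log x = −(N E B′)⁻¹(N E A′ + N E C′ log c),
which is the entire simulation engine: no ODE integration anywhere.

Key exact properties (both are tested, and the first carries the whole
argument): scaling every enzyme by a common factor r leaves x unchanged and
scales all fluxes by r; and the solution is invariant to the choice of
concentration units once the parameters are re-derived.

A singular N E B′ during optimization or evolution is treated as a lethal
phenotype — the objective returns a large sentinel value (1e6) and the
caller carries on — rather than as an error, because box-constrained search
and random rearrangements legitimately visit degenerate enzyme patterns.

### The carbon benchmark model

The packaged fixture is a linlog model of E. coli central carbon
metabolism: glycolysis with the PTS uptake, the pentose-phosphate pathway,
the TCA cycle, the glyoxylate shunt, acetate excretion/import, and three
biosynthetic drains (R5P, 2-oxoglutarate, oxaloacetate) — 34 reactions,
26 variable metabolites, glucose and acetate external. The reference flux
vector is hand-balanced (N J⁰ = 0 with all fluxes positive, glucose uptake
10 flux units), reference concentrations and enzyme levels are 1, and
elasticities are +1 for substrates and −1 for products. It is a
structurally realistic benchmark — the contract is topology, exact
dimensions and internal consistency, not quantitative agreement with
measured kinetics — so absolute metabolite values computed on it are not
comparable with experiments.

## Control coefficients

Flux and concentration control coefficients are estimated by central finite
differences in log-enzyme space with relative step 1e-4 around the
reference state, re-solving the analytic steady state per perturbation.
The linlog steady state is smooth there, and the summation theorems
(ΣFCC = 1 per flux, ΣCCC = 0 per metabolite) are recovered to ~1e-9 —
comfortably inside the 1e-6 tolerance asserted in the tests. "Pathway
flux" means the flux of a designated output reaction (the fixture uses
pyruvate dehydrogenase; random models use their terminal export), since a
full network has no single canonical pathway.

## Homeostasis objective and optimization

For a gene layout p (one position per reaction) and division-time grid
τ ∈ {20, 30, 40, 50, 70, 90, 120} min, enzyme abundances at each τ are
E_i = E⁰_i · n(p_i; C, D, τ) with C = 40, D = 20 min defaults (classic
fast-growth E. coli values; exposed in `ObjectiveConfig`). The objective
F is the mean over metabolites of the coefficient of variation of the
steady-state concentration across the τ grid; fitness is 1/F. F = 0 exactly
when the metabolite vector is τ-independent, which co-located genes achieve
via the uniform-scaling property.

Optimization is box-constrained L-BFGS-B from uniform-random starting
layouts, one recorded seed per run (ftol 1e-15, gtol 1e-9, up to 2000
iterations and 1e6 evaluations). The contract is monotone descent and
convergence reporting, not global optimality — a local optimizer is the
point, since the question is whether clusters form, not what the global
optimum is. Promoter mode freezes the random layout and optimizes per-gene
rate multipliers k directly (start k = 1, positive box bounds); the same
master seed produces the same per-run layouts in both modes, so runs pair.

Position optimization reliably reaches F ~ 1e-5 (co-location), while
promoter optimization — whose τ-independent multipliers cannot equalize
τ-dependent copy-number ratios — lands orders of magnitude higher on
average, though individual runs occasionally find small-F operating points.
Because converged F values are heavy-tailed across runs, the paired
position-vs-promoter comparison uses a one-sided Wilcoxon signed-rank test
together with the ordering of the means.

## Gene-order evolution

Genomes are circles of 600 loci spaced 10 kb: an ori marker, a ter marker
initially antipodal, one target gene per model reaction, and neutral loci.
Per generation each genome suffers at most one event: an inversion with
probability 0.005 (block length max(1, round(N(5, var 9)))) or a
translocation with half that probability (block max(1, round(N(3, var 9)));
excised and reinserted uniformly). Blocks are resampled if they would
contain ori or ter. Fitness is 1/F on the target genes' fractional
positions (arc distance from ori normalized by that arm's ori–ter arc);
genomes whose minimum ori–ter arc falls below 75% of its initial value get
a sentinel minimal fitness, conserving chromosome architecture. Selection
removes variants strictly below the median fitness (ties at the median
survive, so selection can never empty the population) and resamples
survivors proportionally to fitness back to the population size. Fitness
values are cached by the target-position vector, so rearrangements that
only shuffle neutral loci within an arm cost nothing; results are identical
to recomputation. The full trajectory is reproducible from the seed.

Cluster bookkeeping: the ori and ter marker positions are dropped and the
circle is cut at ori. Pure clusters are maximal runs of ≥ 2 consecutive
target genes; mixed clusters are maximal runs bounded by target genes whose
internal non-target gaps are each ≤ 2 loci and which are not purely
contiguous (a pure run inside a mixed span is reported as both). A cluster
may span the ter gap — genes flanking the terminus on the two arms have
nearly equal p, so grouping them is homeostatically coherent — but never
the origin.

The reference experiment (population 1e5, 1e5–2.5e5 generations) is far
beyond a desktop budget; the packaged default test runs population 2,000
for 2,000 generations, which already shows the qualitative outcome —
monotone fitness gain of the fittest strain and formation of pure and/or
mixed clusters — across seeds.

## Genomic statistics

The proximity score pools all unordered within-module gene-pair distances
(minimum circular distance between gene midpoints, nucleotides) across all
modules, takes the first quartile Q1 (linear-interpolation quantile), and
reports PS = −log₂(Q1). Midpoints avoid gene-length artifacts; using all
pairs rather than adjacent pairs follows from treating a module as an
unordered gene set. The distance dialect (midpoint vs start anchoring) is
the main free choice here and is isolated in one helper.

PTR is estimated as log₂ of the ratio of mean depths in 50-kb windows
centered on ori and ter. Per-species replicate log₂PTR values are tested
one-sided against 0 (PTR > 1) and against 1 (PTR > 2) with one-sample
t-tests; species passing the latter at p ≤ 0.01 are flagged
mero-oligoploid. The PS ~ log₂PTR association is an ordinary least-squares
regression (statsmodels) at species or genus level (genus values are
species averages), with a one-sided two-sample t-test comparing PS between
mero-oligoploid and other species.

## Synthetic data

- **Coverage**: expected depth follows the copy-number curve, scaled so the
  terminus expectation matches the configured depth. Because the profile is
  exponential in position, a raw window mean is a slightly biased estimator
  of the locus-point value (continuum bias factor 2^(−(C/τ)δ) with δ the
  half-window as a fraction of the arm); each simulated window is
  normalized so its expected mean equals the window-center copy number,
  making the window-mean estimator exact without noise and unbiased with
  noise. Counts are Poisson by default; a negative-binomial (gamma-Poisson)
  option models the overdispersion of real libraries. Real coverage also
  carries mappability, GC and strand artifacts that the simulator does not
  emulate, so recovery tests certify the estimator, not robustness to
  library artifacts.
- **Annotations**: genes occupy evenly spaced slots on a circular genome;
  each module is placed as a contiguous block with probability θ and
  scattered uniformly otherwise, so θ = 0 and θ = 1 bracket the
  scattered/clustered extremes with everything else identical.
- **Random linlog models**: an import–chain–export topology with random
  drain branches, balanced positive reference flux, unit reference state,
  and ±1 elasticities with uniform jitter (resampled if the steady-state
  matrix is singular at reference). This needs r ≥ m + 1 reactions for m
  metabolites. These models exercise every algebraic property the engine
  relies on, but they are tree-like; they do not probe the dense loops of
  real metabolism the way the carbon fixture does.

## Known limitations

- Elasticities are fixed parameters, so the linlog response is trusted only
  in a neighbourhood of the reference state; extreme enzyme patterns during
  optimization can leave that range silently (they show up only as large F
  or singular sentinels).
- Enzyme abundance is assumed proportional to gene copy number, with no
  regulatory buffering (supercoiling, titration, growth-rate-dependent
  promoters).
- The evolution model has no duplications, deletions or insertion-sequence
  mechanics; rearrangement rates are constant and at most one event per
  genome per generation occurs.
- The optimization and evolution experiments characterize the packaged
  benchmark network; quantitative converged-F values are model-specific.
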