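"""Population simulation of gene-order evolution by inversions and translocations.

A genome is a circular arrangement of loci (default 600, spaced 10 kb):
an origin marker, a terminus marker initially antipodal, the target genes
encoding the enzymes of a linlog metabolic model, and neutral loci.
Each generation every genome may undergo at most one structural
rearrangement — an inversion (reversing a contiguous block) or a
translocation (excising a block and reinserting it elsewhere); blocks never
contain the ori or ter markers. Block lengths are max(1, round(N(5, 9)))
loci for inversions and max(1, round(N(3, 9))) for translocations.

A genome's fitness is 1/F, where F is the homeostasis objective evaluated
on the fractional ori–ter positions of its target genes (arc distance from
ori along the gene's replichore, normalized by that arm's length). Genomes
whose minimum ori–ter arc shrinks below 75% of its initial value get a
sentinel minimal fitness, conserving overall chromosome structure. After
mutation, variants strictly below the median fitness are removed and the
survivors are resampled proportionally to fitness back to the population
size. Cluster statistics (pure clusters: contiguous runs of >= 2 target
genes; mixed clusters: runs bounded by target genes with internal
non-target gaps of at most 2 loci) are recorded per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linlog import LinlogModel
from .optimize import SENTINEL_F, HomeostasisObjective, ObjectiveConfig

__all__ = [
    "ORI",
    "TER",
    "EvoGenome",
    "EvoConfig",
    "ClusterReport",
    "EvolutionResults",
    "GeneOrderEvolution",
    "apply_inversion",
    "apply_translocation",
    "genome_fitness",
    "detect_clusters",
    "target_positions",
]

ORI = 0  #: locus code of the replication origin marker
TER = 1  #: locus code of the replication terminus marker
_FIRST_TARGET = 2

#: Fitness assigned to inviable genomes (broken ori-ter structure or
#: singular metabolic steady state).
SENTINEL_FITNESS = 1e-12


@dataclass
class EvoConfig:
    """Parameters of the evolutionary simulation.

    Defaults follow the full-scale experiment (population 1e5, 600 loci,
    10 kb spacing, p_inv = 0.005 with p_transl = p_inv / 2, division times
    20–120 min); population size and generations scale down freely.
    """

    pop_size: int = 100_000
    generations: int = 1000
    n_loci: int = 600
    spacing: int = 10_000
    p_inv: float = 0.005
    p_transl: float | None = None  # defaults to p_inv / 2
    inv_block_mean: float = 5.0
    inv_block_sd: float = 3.0
    transl_block_mean: float = 3.0
    transl_block_sd: float = 3.0
    min_oriter_frac: float = 0.75
    taus: tuple = (20.0, 30.0, 40.0, 50.0, 70.0, 90.0, 120.0)
    C: float = 40.0
    D: float = 20.0

    def __post_init__(self) -> None:
        if self.p_transl is None:
            self.p_transl = self.p_inv / 2.0
        if not (0 <= self.p_inv <= 1 and 0 <= self.p_transl <= 1):
            raise ValueError("mutation probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.n_loci < 10:
            raise ValueError("n_loci too small")


@dataclass
class EvoGenome:
    """A circular genome: an integer arrangement of locus identities.

    Codes: 0 = ori, 1 = ter, 2 .. 2+n_targets-1 = target genes, larger
    codes = neutral loci. Every identity appears exactly once.
    """

    arrangement: np.ndarray
    n_targets: int

    def __post_init__(self) -> None:
        self.arrangement = np.asarray(self.arrangement, dtype=np.int32)
        n = self.arrangement.size
        if not np.array_equal(np.sort(self.arrangement), np.arange(n)):
            raise ValueError("arrangement must contain each locus identity exactly once")

    @classmethod
    def initial(cls, n_loci: int, n_targets: int, rng: np.random.Generator) -> "EvoGenome":
        """Ori at index 0, ter antipodal, targets at random other loci."""
        arr = np.full(n_loci, -1, dtype=np.int32)
        arr[0] = ORI
        arr[n_loci // 2] = TER
        slots = np.setdiff1d(np.arange(n_loci), [0, n_loci // 2])
        tgt_slots = rng.choice(slots, size=n_targets, replace=False)
        arr[tgt_slots] = np.arange(_FIRST_TARGET, _FIRST_TARGET + n_targets)
        rest = np.setdiff1d(slots, tgt_slots)
        arr[rest] = np.arange(_FIRST_TARGET + n_targets, n_loci)
        return cls(arrangement=arr, n_targets=n_targets)


def _sample_block(
    arrangement: np.ndarray, rng: np.random.Generator, mean: float, sd: float
) -> tuple[int, int]:
    """A contiguous block (start, length) avoiding the ori and ter markers."""
    n = arrangement.size
    for _ in range(1000):
        length = max(1, int(round(rng.normal(mean, sd))))
        length = min(length, n - 3)
        start = int(rng.integers(n))
        idx = (start + np.arange(length)) % n
        block = arrangement[idx]
        if ORI not in block and TER not in block:
            return start, length
    raise RuntimeError("could not sample a block avoiding ori/ter")


def apply_inversion(
    arrangement: np.ndarray,
    rng: np.random.Generator,
    mean: float = 5.0,
    sd: float = 3.0,
) -> np.ndarray:
    """Reverse a random contiguous block (never containing ori or ter)."""
    start, length = _sample_block(arrangement, rng, mean, sd)
    idx = (start + np.arange(length)) % arrangement.size
    out = arrangement.copy()
    out[idx] = arrangement[idx[::-1]]
    return out


def apply_translocation(
    arrangement: np.ndarray,
    rng: np.random.Generator,
    mean: float = 3.0,
    sd: float = 3.0,
) -> np.ndarray:
    """Excise a random block and reinsert it at a uniform permitted position."""
    n = arrangement.size
    start, length = _sample_block(arrangement, rng, mean, sd)
    idx = (start + np.arange(length)) % n
    block = arrangement[idx].copy()
    remaining = np.delete(arrangement, idx)
    insert_at = int(rng.integers(remaining.size + 1))
    return np.concatenate([remaining[:insert_at], block, remaining[insert_at:]]).astype(
        np.int32
    )


def target_positions(arrangement: np.ndarray, n_targets: int) -> np.ndarray | None:
    """Fractional ori–ter position of each target gene, or None if inviable.

    Each locus maps onto its replichore: arc distance from ori divided by
    that arm's ori–ter arc length. Returns None when the minimum ori–ter
    arc is shorter than the viability threshold checked by the caller
    (the caller compares arcs; this function only maps positions).
    """
    n = arrangement.size
    io = int(np.flatnonzero(arrangement == ORI)[0])
    it = int(np.flatnonzero(arrangement == TER)[0])
    d_ter = (it - io) % n
    codes = np.arange(_FIRST_TARGET, _FIRST_TARGET + n_targets)
    pos_index = np.empty(n, dtype=np.int64)
    pos_index[arrangement] = np.arange(n)
    d = (pos_index[codes] - io) % n
    p = np.where(d <= d_ter, d / d_ter, (n - d) / (n - d_ter))
    return p


def _oriter_arcs(arrangement: np.ndarray) -> tuple[int, int]:
    n = arrangement.size
    io = int(np.flatnonzero(arrangement == ORI)[0])
    it = int(np.flatnonzero(arrangement == TER)[0])
    d = (it - io) % n
    return d, n - d


def genome_fitness(
    genome: EvoGenome | np.ndarray,
    engine: HomeostasisObjective,
    cfg: EvoConfig,
    n_targets: int | None = None,
) -> float:
    """1 / F for the genome's target-gene layout; sentinel when inviable."""
    arr = genome.arrangement if isinstance(genome, EvoGenome) else np.asarray(genome)
    nt = genome.n_targets if isinstance(genome, EvoGenome) else n_targets
    if nt is None:
        raise ValueError("n_targets required for a raw arrangement")
    d1, d2 = _oriter_arcs(arr)
    initial_min = arr.size // 2  # ter starts antipodal
    if min(d1, d2) < cfg.min_oriter_frac * initial_min:
        return SENTINEL_FITNESS
    p = target_positions(arr, nt)
    F = engine.F(p)
    if F >= SENTINEL_F:
        return SENTINEL_FITNESS
    return 1.0 / max(F, 1e-12)


@dataclass
class ClusterReport:
    """Pure and mixed target-gene clusters of one arrangement.

    ``pure_sizes``: gene counts of maximal contiguous runs of >= 2 target
    genes. ``mixed_sizes``: locus spans of maximal runs bounded by target
    genes whose internal non-target gaps are each <= 2 loci and which are
    not purely contiguous.
    """

    pure_sizes: list[int] = field(default_factory=list)
    mixed_sizes: list[int] = field(default_factory=list)

    @property
    def n_pure(self) -> int:
        return len(self.pure_sizes)

    @property
    def n_mixed(self) -> int:
        return len(self.mixed_sizes)

    @property
    def max_pure(self) -> int:
        return max(self.pure_sizes, default=0)

    @property
    def max_mixed(self) -> int:
        return max(self.mixed_sizes, default=0)

    @property
    def any_cluster(self) -> bool:
        return bool(self.pure_sizes or self.mixed_sizes)


def detect_clusters(genome: EvoGenome | np.ndarray, n_targets: int | None = None) -> ClusterReport:
    """Find pure and mixed target-gene clusters on the circular order.

    The ori and ter marker positions are removed and the circle is cut at
    ori (a cluster may not span the origin; it may span the ter gap, where
    genes on both arms are equally terminus-proximal).
    """
    arr = genome.arrangement if isinstance(genome, EvoGenome) else np.asarray(genome)
    nt = genome.n_targets if isinstance(genome, EvoGenome) else n_targets
    if nt is None:
        raise ValueError("n_targets required for a raw arrangement")
    n = arr.size
    io = int(np.flatnonzero(arr == ORI)[0])
    seq = np.roll(arr, -io)[1:]  # cut at ori, drop the ori marker
    seq = seq[seq != TER]
    is_t = (seq >= _FIRST_TARGET) & (seq < _FIRST_TARGET + nt)

    report = ClusterReport()
    # Pure clusters: maximal runs of consecutive targets, length >= 2.
    run = 0
    for flag in np.append(is_t, False):
        if flag:
            run += 1
        else:
            if run >= 2:
                report.pure_sizes.append(run)
            run = 0
    # Mixed clusters: group consecutive targets with <= 2 non-targets
    # between them; keep groups of >= 2 targets with at least one gap.
    tpos = np.flatnonzero(is_t)
    if tpos.size >= 2:
        group_start = 0
        gaps_in_group = False
        for k in range(1, tpos.size + 1):
            gap = tpos[k] - tpos[k - 1] - 1 if k < tpos.size else None
            if gap is None or gap > 2:
                n_genes = k - group_start
                if n_genes >= 2 and gaps_in_group:
                    span = int(tpos[k - 1] - tpos[group_start] + 1)
                    report.mixed_sizes.append(span)
                group_start = k
                gaps_in_group = False
            elif gap > 0:
                gaps_in_group = True
    return report


@dataclass
class EvolutionResults:
    """Trajectory and endpoint of one evolutionary run.

    ``trajectory`` is a DataFrame with one row per recorded generation:
    best and mean fitness, and pure/mixed cluster statistics of the fittest
    strain. ``best_genome`` is the fittest arrangement at the end.
    """

    trajectory: "object"
    best_genome: EvoGenome
    config: EvoConfig
    seed: int | None = None

    @property
    def initial_fitness(self) -> float:
        return float(self.trajectory["best_fitness"].iloc[0])

    @property
    def final_fitness(self) -> float:
        return float(self.trajectory["best_fitness"].iloc[-1])

    def summary(self) -> str:
        t = self.trajectory
        last = t.iloc[-1]
        report = detect_clusters(self.best_genome)
        return "\n".join(
            [
                f"Gene-order evolution: pop {self.config.pop_size}, "
                f"{int(t['generation'].iloc[-1]) + 1} generations, seed {self.seed}",
                f"  fittest-strain fitness: {self.initial_fitness:.4g} -> "
                f"{self.final_fitness:.4g} "
                f"({self.final_fitness / self.initial_fitness:.2f}x)",
                f"  final mean fitness: {last['mean_fitness']:.4g}",
                f"  fittest strain: {report.n_pure} pure cluster(s) (largest "
                f"{report.max_pure} genes), {report.n_mixed} mixed (largest span "
                f"{report.max_mixed} loci)",
            ]
        )


class GeneOrderEvolution:
    """Driver for the mutation / selection / resampling loop.

    Parameters
    ----------
    model : LinlogModel
        Metabolic model whose reactions define the target genes (one gene
        per reaction).
    config : EvoConfig
        Population and mutation parameters.

    Fitness values are cached by target-gene layout, so only genomes whose
    rearrangement actually moved a target gene (or a marker) trigger a new
    steady-state evaluation; results are identical to recomputation.
    """

    def __init__(self, model: LinlogModel, config: EvoConfig | None = None):
        self.model = model
        self.config = config if config is not None else EvoConfig()
        obj_cfg = ObjectiveConfig(taus=self.config.taus, C=self.config.C, D=self.config.D)
        self.engine = HomeostasisObjective(model, obj_cfg)
        self.n_targets = model.n_reactions

    def _fitness(self, arrangement: np.ndarray, cache: dict) -> float:
        # Fitness depends only on the target-gene layout, so the cache is
        # keyed by the fractional-position vector: rearrangements that only
        # shuffle neutral loci within an arm are free.
        d1, d2 = _oriter_arcs(arrangement)
        initial_min = arrangement.size // 2
        if min(d1, d2) < self.config.min_oriter_frac * initial_min:
            return SENTINEL_FITNESS
        p = target_positions(arrangement, self.n_targets)
        key = p.tobytes()
        fit = cache.get(key)
        if fit is None:
            F = self.engine.F(p)
            fit = SENTINEL_FITNESS if F >= SENTINEL_F else 1.0 / max(F, 1e-12)
            cache[key] = fit
        return fit

    def run(self, seed: int | None = None, record_every: int = 1) -> EvolutionResults:
        import pandas as pd

        cfg = self.config
        rng = np.random.default_rng(seed)
        founder = EvoGenome.initial(cfg.n_loci, self.n_targets, rng)

        variants: list[np.ndarray] = [founder.arrangement]
        cache: dict[bytes, float] = {}
        fitness_list: list[float] = [self._fitness(founder.arrangement, cache)]
        population = np.zeros(cfg.pop_size, dtype=np.int64)  # variant index per individual

        rows = []
        p_any = cfg.p_inv + cfg.p_transl
        for gen in range(cfg.generations):
            # --- mutation: at most one event per genome per generation
            u = rng.random(cfg.pop_size)
            mutants = np.flatnonzero(u < p_any)
            for ind in mutants:
                parent = variants[population[ind]]
                if u[ind] < cfg.p_inv:
                    child = apply_inversion(parent, rng, cfg.inv_block_mean, cfg.inv_block_sd)
                else:
                    child = apply_translocation(
                        parent, rng, cfg.transl_block_mean, cfg.transl_block_sd
                    )
                variants.append(child)
                fitness_list.append(self._fitness(child, cache))
                population[ind] = len(variants) - 1

            # --- selection: drop strictly-below-median variants
            fitness = np.asarray(fitness_list)
            ind_fit = fitness[population]
            median = np.median(ind_fit)
            survivors = population[ind_fit >= median]
            surv_fit = fitness[survivors]

            # --- resampling proportional to fitness back to pop_size
            probs = surv_fit / surv_fit.sum()
            population = survivors[
                rng.choice(survivors.size, size=cfg.pop_size, replace=True, p=probs)
            ]

            if gen % record_every == 0 or gen == cfg.generations - 1:
                ind_fit = fitness[population]
                best_idx = population[int(np.argmax(ind_fit))]
                report = detect_clusters(variants[best_idx], self.n_targets)
                rows.append(
                    {
                        "generation": gen,
                        "best_fitness": float(fitness[best_idx]),
                        "mean_fitness": float(ind_fit.mean()),
                        "n_pure": report.n_pure,
                        "max_pure": report.max_pure,
                        "n_mixed": report.n_mixed,
                        "max_mixed": report.max_mixed,
                        "n_variants": int(np.unique(population).size),
                    }
                )

        fitness = np.asarray(fitness_list)
        ind_fit = fitness[population]
        best_idx = population[int(np.argmax(ind_fit))]
        best = EvoGenome(arrangement=variants[best_idx].copy(), n_targets=self.n_targets)
        return EvolutionResults(
            trajectory=pd.DataFrame(rows), best_genome=best, config=cfg, seed=seed
        )
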