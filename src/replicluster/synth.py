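"""Synthetic inputs: coverage profiles, annotated genomes, linlog models.

Every generator is a pure function of its configuration and seed, and its
output passes the invariant checks of the consuming module. The packaged
carbon-metabolism fixture — a 34-reaction / 26-variable-metabolite linlog
model of E. coli central carbon metabolism (glycolysis, pentose-phosphate
pathway, TCA cycle, glyoxylate shunt and acetate exchange, with glucose and
acetate as the two external metabolites) — is also built here; its
stoichiometry is the textbook topology with a hand-balanced positive
reference flux, unit reference concentrations and enzyme levels, and
elasticities of +1 for substrates and -1 for products. It serves as a
structurally realistic benchmark network, not as a fit to measured data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .linlog import LinlogModel, derive_parameters, load_network, steady_state
from .proximity import CoverageProfile, GenomeAnnotation
from .replication import ReplicationParams

__all__ = [
    "CoverageSimConfig",
    "AnnotationSimConfig",
    "simulate_coverage",
    "generate_annotated_genome",
    "random_linlog",
    "carbon_fixture",
]


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageSimConfig:
    """Configuration for simulated ori/ter coverage windows.

    ``noise`` is one of ``"none"`` (expected depth, float), ``"poisson"``,
    or ``"nb"`` (negative binomial via a gamma-Poisson mixture with
    ``dispersion`` as the gamma shape; smaller means more overdispersed).
    """

    rep: ReplicationParams
    genome_length: int = 4_000_000
    depth_ter: float = 100.0
    noise: str = "poisson"
    dispersion: float = 10.0
    window: int = 50_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth_ter <= 0:
            raise ValueError("depth_ter must be positive")
        if self.noise not in ("none", "poisson", "nb"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.genome_length < 2 * self.window:
            raise ValueError("genome shorter than the two coverage windows")


def simulate_coverage(cfg: CoverageSimConfig) -> CoverageProfile:
    """Simulate read depth in 50-kb windows centered on ori and ter.

    The depth profile follows the Helmstetter–Cooper copy-number curve
    ``2**(((1 - p) C + D) / tau)`` scaled so the terminus-locus expectation
    is ``depth_ter``. Because that profile is exponential in position, the
    raw window mean is a slightly biased estimator of the locus-point value;
    each window is therefore normalized so that its expected mean equals the
    copy number at the window center, making the window-mean log2 ratio an
    unbiased (and, without noise, exact) estimator of C/tau.
    """
    rep, G = cfg.rep, cfg.genome_length
    half = cfg.window // 2
    arm = G / 2.0  # replichore length; ori at 0, ter at G/2

    ori_pos = np.arange(-half, half)
    ter_pos = np.arange(G // 2 - half, G // 2 + half)
    p_ori = np.abs(ori_pos) / arm
    p_ter = 1.0 - np.abs(ter_pos - G / 2.0) / arm

    a = rep.C / rep.tau

    def window_lambda(p: np.ndarray, p_center: float) -> np.ndarray:
        shape = 2.0 ** ((1.0 - p) * a)
        point = 2.0 ** ((1.0 - p_center) * a)
        return cfg.depth_ter * shape * (point / shape.mean())

    lam_ori = window_lambda(p_ori, 0.0)
    lam_ter = window_lambda(p_ter, 1.0)

    if cfg.noise == "none":
        d_ori, d_ter = lam_ori, lam_ter
    else:
        rng = np.random.default_rng(cfg.seed)
        if cfg.noise == "poisson":
            d_ori = rng.poisson(lam_ori).astype(float)
            d_ter = rng.poisson(lam_ter).astype(float)
        else:
            k = cfg.dispersion
            d_ori = rng.poisson(rng.gamma(k, lam_ori / k)).astype(float)
            d_ter = rng.poisson(rng.gamma(k, lam_ter / k)).astype(float)
    return CoverageProfile(
        ori_positions=ori_pos % G,
        ori_depth=d_ori,
        ter_positions=ter_pos,
        ter_depth=d_ter,
        genome_length=G,
    )


# ---------------------------------------------------------------------------
# Annotated genomes with planted clustered or scattered modules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationSimConfig:
    """Configuration for synthetic circular genome annotations.

    ``theta`` interpolates between fully scattered module genes (0: every
    module's genes land on uniformly random loci) and fully clustered
    (1: every module is a contiguous block of adjacent genes).
    """

    genome_length: int = 2_000_000
    n_genes: int = 400
    gene_length: int = 900
    n_modules: int = 10
    genes_per_module: int = 5
    theta: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError("module genes exceed total gene count")
        if self.genome_length // self.n_genes < self.gene_length:
            raise ValueError("genes do not fit in the genome without overlap")


def generate_annotated_genome(cfg: AnnotationSimConfig) -> GenomeAnnotation:
    """Place module genes as contiguous blocks (prob. theta) or scattered."""
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.genome_length // cfg.n_genes
    free = list(range(cfg.n_genes))  # gene slots around the circle
    assignment: dict[int, str] = {}

    clustered = rng.random(cfg.n_modules) < cfg.theta
    # Contiguous modules first: they need runs of adjacent free slots.
    for mod in np.flatnonzero(clustered):
        placed = False
        for _ in range(200):
            start = int(rng.integers(cfg.n_genes))
            run = [(start + k) % cfg.n_genes for k in range(cfg.genes_per_module)]
            if all(slot in free for slot in run):
                for k, slot in enumerate(run):
                    assignment[slot] = f"M{mod}"
                    free.remove(slot)
                placed = True
                break
        if not placed:
            raise ValueError("could not place contiguous module; genome too full")
    for mod in np.flatnonzero(~clustered):
        slots = rng.choice(len(free), size=cfg.genes_per_module, replace=False)
        for slot in sorted((free[s] for s in slots), reverse=True):
            assignment[slot] = f"M{mod}"
            free.remove(slot)

    genes: list[tuple[str, int, int, str]] = []
    modules: dict[str, set] = {f"M{mod}": set() for mod in range(cfg.n_modules)}
    for slot in range(cfg.n_genes):
        start = slot * spacing
        gid = f"g{slot:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((gid, start, start + cfg.gene_length, strand))
        if slot in assignment:
            modules[assignment[slot]].add(gid)
    return GenomeAnnotation(
        genome_length=cfg.genome_length, genes=genes, modules=modules, circular=True
    )


# ---------------------------------------------------------------------------
# Random linlog models
# ---------------------------------------------------------------------------


def random_linlog(m: int, r: int, seed: int | None = None) -> LinlogModel:
    """A random valid linlog model: a metabolite chain with drain branches.

    The topology is an import reaction feeding a chain of the m variable
    metabolites, a terminal export, and r - (m + 1) drain reactions pulling
    from random chain metabolites (so r >= m + 1 is required). The reference
    flux is balanced by construction with all entries positive; x0, c0 and
    E0 are 1 and elasticities are +1 for substrates and -1 for products with
    uniform jitter. Construction is retried with fresh jitter if the
    steady-state matrix comes out singular at the reference state.
    """
    if r < m + 1:
        raise ValueError("need r >= m + 1 reactions for a balanced chain topology")
    rng = np.random.default_rng(seed)
    n_drains = r - (m + 1)

    N = np.zeros((m, r))
    reactions = []
    substrates: list[list[int]] = []  # variable-metabolite substrate indices
    products: list[list[int]] = []
    # chain: import (external -> x0), x_j -> x_{j+1}, export x_{m-1} -> out
    N[0, 0] = 1.0
    reactions.append("import")
    substrates.append([])
    products.append([0])
    for j in range(m - 1):
        N[j, j + 1] = -1.0
        N[j + 1, j + 1] = 1.0
        reactions.append(f"chain_{j}")
        substrates.append([j])
        products.append([j + 1])
    N[m - 1, m] = -1.0
    reactions.append("export")
    substrates.append([m - 1])
    products.append([])
    drain_targets = rng.integers(0, m, size=n_drains)
    for d, j in enumerate(drain_targets):
        N[j, m + 1 + d] = -1.0
        reactions.append(f"drain_{d}")
        substrates.append([int(j)])
        products.append([])

    # Balanced positive reference flux: import 1, small drains, chain carries
    # the remainder downstream of each drain point.
    drain_flux = np.zeros(n_drains)
    if n_drains:
        drain_flux = rng.uniform(0.05, 0.15, size=n_drains)
        drain_flux *= min(1.0, 0.5 / drain_flux.sum())
    J0 = np.zeros(r)
    J0[0] = 1.0
    outflow_at = np.zeros(m)
    for d, j in enumerate(drain_targets):
        J0[m + 1 + d] = drain_flux[d]
        outflow_at[j] += drain_flux[d]
    carried = 1.0
    for j in range(m - 1):
        carried -= outflow_at[j]
        J0[j + 1] = carried
    J0[m] = carried - outflow_at[m - 1]

    for attempt in range(20):
        Bx = np.zeros((r, m))
        Bc = np.zeros((r, 1))
        for i in range(r):
            for j in substrates[i]:
                Bx[i, j] = 1.0 + rng.uniform(-0.3, 0.3)
            for j in products[i]:
                Bx[i, j] = -1.0 + rng.uniform(-0.3, 0.3)
        Bc[0, 0] = 1.0 + rng.uniform(-0.3, 0.3)
        model = LinlogModel(
            N=N,
            E0=np.ones(r),
            J0=J0,
            x0=np.ones(m),
            c0=np.ones(1),
            Bx=Bx,
            Bc=Bc,
            reactions=list(reactions),
            externals=["substrate_in"],
            output_reaction=m,  # the export reaction
        )
        params = derive_parameters(model)
        try:
            x_ref = steady_state(model, params, model.E0)
        except np.linalg.LinAlgError:
            continue
        if np.allclose(x_ref, model.x0, rtol=1e-8, atol=1e-10):
            return model
    raise RuntimeError("failed to build a nonsingular random linlog model")


# ---------------------------------------------------------------------------
# The packaged carbon-metabolism fixture
# ---------------------------------------------------------------------------

# (reaction id, {metabolite: coefficient}, reference flux); names ending in
# _ext are the external metabolites glucose and acetate.
_CARBON_REACTIONS: list[tuple[str, dict[str, float], float]] = [
    ("pts", {"glucose": -1, "pep": -1, "g6p": 1, "pyr": 1}, 10.0),
    ("pgi", {"g6p": -1, "f6p": 1}, 7.0),
    ("pfk", {"f6p": -1, "fbp": 1}, 8.6),
    ("fba", {"fbp": -1, "dhap": 1, "g3p": 1}, 8.6),
    ("tpi", {"dhap": -1, "g3p": 1}, 8.6),
    ("gapdh", {"g3p": -1, "bpg13": 1}, 18.0),
    ("pgk", {"bpg13": -1, "pg3": 1}, 18.0),
    ("gpm", {"pg3": -1, "pg2": 1}, 18.0),
    ("eno", {"pg2": -1, "pep": 1}, 18.0),
    ("pyk", {"pep": -1, "pyr": 1}, 6.0),
    ("pdh", {"pyr": -1, "accoa": 1}, 16.0),
    ("zwf", {"g6p": -1, "pg6": 1}, 3.0),
    ("gnd", {"pg6": -1, "ru5p": 1}, 3.0),
    ("rpe", {"ru5p": -1, "x5p": 1}, 1.6),
    ("rpi", {"ru5p": -1, "r5p": 1}, 1.4),
    ("tkt1", {"x5p": -1, "r5p": -1, "s7p": 1, "g3p": 1}, 0.8),
    ("tal", {"s7p": -1, "g3p": -1, "e4p": 1, "f6p": 1}, 0.8),
    ("tkt2", {"x5p": -1, "e4p": -1, "f6p": 1, "g3p": 1}, 0.8),
    ("ppc", {"pep": -1, "oaa": 1}, 2.0),
    ("cs", {"accoa": -1, "oaa": -1, "cit": 1}, 12.5),
    ("acn", {"cit": -1, "icit": 1}, 12.5),
    ("icd", {"icit": -1, "akg": 1}, 11.5),
    ("akgdh", {"akg": -1, "succoa": 1}, 10.0),
    ("sucoas", {"succoa": -1, "succ": 1}, 10.0),
    ("sdh", {"succ": -1, "fum": 1}, 11.0),
    ("fum", {"fum": -1, "mal": 1}, 11.0),
    ("mdh", {"mal": -1, "oaa": 1}, 12.0),
    ("icl", {"icit": -1, "succ": 1, "glx": 1}, 1.0),
    ("ms", {"glx": -1, "accoa": -1, "mal": 1}, 1.0),
    ("pta_ack", {"accoa": -1, "acetate": 1}, 3.0),
    ("acs", {"acetate": -1, "accoa": 1}, 0.5),
    ("prs", {"r5p": -1}, 0.6),  # nucleotide biosynthesis drain
    ("gdh", {"akg": -1}, 1.5),  # glutamate biosynthesis drain
    ("aspC", {"oaa": -1}, 1.5),  # aspartate biosynthesis drain
]

_CARBON_METABOLITES = [
    "g6p", "f6p", "fbp", "dhap", "g3p", "bpg13", "pg3", "pg2", "pep", "pyr",
    "accoa", "cit", "icit", "akg", "succoa", "succ", "fum", "mal", "oaa",
    "glx", "pg6", "ru5p", "r5p", "x5p", "s7p", "e4p",
]
_CARBON_EXTERNALS = ["glucose", "acetate"]


def build_carbon_model() -> LinlogModel:
    """Construct the carbon-metabolism benchmark model programmatically."""
    mets = _CARBON_METABOLITES
    exts = _CARBON_EXTERNALS
    met_idx = {mname: j for j, mname in enumerate(mets)}
    ext_idx = {cname: k for k, cname in enumerate(exts)}
    r = len(_CARBON_REACTIONS)
    m = len(mets)
    N = np.zeros((m, r))
    Bx = np.zeros((r, m))
    Bc = np.zeros((r, len(exts)))
    J0 = np.zeros(r)
    names = []
    for i, (rid, stoich, flux) in enumerate(_CARBON_REACTIONS):
        names.append(rid)
        J0[i] = flux
        for mname, coef in stoich.items():
            if mname in ext_idx:
                Bc[i, ext_idx[mname]] = 1.0 if coef < 0 else -1.0
            else:
                N[met_idx[mname], i] = coef
                Bx[i, met_idx[mname]] = 1.0 if coef < 0 else -1.0
    return LinlogModel(
        N=N,
        E0=np.ones(r),
        J0=J0,
        x0=np.ones(m),
        c0=np.ones(len(exts)),
        Bx=Bx,
        Bc=Bc,
        metabolites=list(mets),
        reactions=names,
        externals=list(exts),
        output_reaction=names.index("pdh"),
    )


def carbon_fixture() -> LinlogModel:
    """Load the packaged 34-reaction carbon-metabolism model."""
    ref = resources.files("replicluster") / "data" / "carbon_core.json"
    with resources.as_file(ref) as path:
        return load_network(Path(path))


def _write_packaged_fixture(target: str | Path) -> None:
    """Regenerate the packaged JSON from the programmatic builder."""
    from .linlog import _model_to_dict

    with open(target, "w") as fh:
        json.dump(_model_to_dict(build_carbon_model()), fh, indent=1)
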