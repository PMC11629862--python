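"""Linlog metabolic models with an analytic steady state.

The linlog format approximates every enzymatic rate as the enzyme abundance
times a linear combination of logarithms of metabolite concentrations::

    v = E (A' + B' log x + C' log c)

with E a diagonal matrix of enzyme abundances, x the variable metabolites,
c the external metabolites (model parameters), and A', B', C' parameter
arrays absorbing the reference state. The parameters are derived from a
reference steady state (fluxes J0, concentrations x0, c0, enzymes E0) and
elasticity matrices Bx (w.r.t. variable metabolites) and Bc (external):

    A' = (J0/E0) (1 - Bx log x0 - Bc log c0)
    B' = diag(J0/E0) Bx
    C' = diag(J0/E0) Bc

so that rates evaluated at the reference state return J0 exactly. Because
the rates are linear in log x, the steady state (N v = 0, N the
stoichiometry matrix) is analytic:

    log x = -(N E B')^{-1} (N E A' + N E C' log c)

Feeding arbitrary enzyme levels into that solution yields the new steady
state without ODE integration; scaling every enzyme by a common factor r
leaves x unchanged and scales all fluxes by r (perfect homeostasis), which
is the algebraic backbone of the position-optimization and evolution
experiments in this package. Natural logarithms throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LinlogModel",
    "LinlogParams",
    "SingularSteadyStateError",
    "LoadError",
    "derive_parameters",
    "rates",
    "steady_state",
    "load_network",
    "save_network",
]


class SingularSteadyStateError(np.linalg.LinAlgError):
    """The steady-state system matrix N diag(E) B' is singular."""


class LoadError(ValueError):
    """A model file violates the schema or the model invariants."""


@dataclass
class LinlogModel:
    """A linlog model: stoichiometry, reference state and elasticities.

    Attributes
    ----------
    N : (m, r) ndarray
        Stoichiometry of the m variable metabolites across r reactions.
    E0, J0 : (r,) ndarrays
        Reference enzyme abundances (strictly positive) and reference
        steady-state fluxes (must satisfy N @ J0 = 0).
    x0 : (m,) ndarray
        Reference variable-metabolite concentrations, strictly positive.
    c0 : (n_ext,) ndarray
        External-metabolite concentrations (parameters), strictly positive.
    Bx : (r, m) ndarray
        Elasticities of each reaction w.r.t. the variable metabolites.
    Bc : (r, n_ext) ndarray
        Elasticities w.r.t. the external metabolites.
    metabolites, reactions, externals : lists of str
        Names, in matrix order.
    output_reaction : int
        Index of the designated pathway-output reaction (reference flux
        for flux control coefficients).
    """

    N: np.ndarray
    E0: np.ndarray
    J0: np.ndarray
    x0: np.ndarray
    c0: np.ndarray
    Bx: np.ndarray
    Bc: np.ndarray
    metabolites: list[str] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    externals: list[str] = field(default_factory=list)
    output_reaction: int = -1

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        for name in ("E0", "J0", "x0", "c0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        self.Bx = np.asarray(self.Bx, dtype=float)
        self.Bc = np.asarray(self.Bc, dtype=float)
        m, r = self.N.shape
        if not self.metabolites:
            self.metabolites = [f"x{j}" for j in range(m)]
        if not self.reactions:
            self.reactions = [f"v{i}" for i in range(r)]
        if not self.externals:
            self.externals = [f"c{k}" for k in range(self.c0.size)]
        self.validate()

    @property
    def n_metabolites(self) -> int:
        return self.N.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.N.shape[1]

    @property
    def n_external(self) -> int:
        return self.c0.size

    def validate(self) -> None:
        m, r = self.N.shape
        if self.E0.shape != (r,) or self.J0.shape != (r,):
            raise LoadError("E0/J0 must have one entry per reaction")
        if self.x0.shape != (m,):
            raise LoadError("x0 must have one entry per variable metabolite")
        if self.Bx.shape != (r, m):
            raise LoadError(f"Bx must be {(r, m)}, got {self.Bx.shape}")
        if self.Bc.shape != (r, self.c0.size):
            raise LoadError(f"Bc must be {(r, self.c0.size)}, got {self.Bc.shape}")
        if np.any(self.E0 <= 0) or np.any(self.x0 <= 0) or np.any(self.c0 <= 0):
            raise LoadError("E0, x0 and c0 must be strictly positive")
        resid = np.abs(self.N @ self.J0)
        scale = max(1.0, float(np.abs(self.J0).max()))
        if resid.max() > 1e-9 * scale:
            raise LoadError(
                f"reference fluxes are not a steady state: |N J0| = {resid.max():.3g}"
            )
        if len(self.metabolites) != m or len(self.reactions) != r:
            raise LoadError("name lists inconsistent with matrix dimensions")
        if not (-r <= self.output_reaction < r):
            raise LoadError("output_reaction index out of range")


@dataclass(frozen=True)
class LinlogParams:
    """The derived absolute-quantity parameter set (A', B', C')."""

    Ap: np.ndarray
    Bp: np.ndarray
    Cp: np.ndarray


def derive_parameters(model: LinlogModel) -> LinlogParams:
    """Fold the reference state into absolute-quantity parameters A', B', C'."""
    if np.any(model.x0 <= 0) or np.any(model.c0 <= 0):
        raise ValueError("reference concentrations must be strictly positive")
    scale = model.J0 / model.E0
    Ap = scale * (1.0 - model.Bx @ np.log(model.x0) - model.Bc @ np.log(model.c0))
    Bp = scale[:, None] * model.Bx
    Cp = scale[:, None] * model.Bc
    return LinlogParams(Ap=Ap, Bp=Bp, Cp=Cp)


def rates(
    model: LinlogModel,
    params: LinlogParams,
    E: np.ndarray,
    x: np.ndarray,
    c: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate all reaction rates v = E (A' + B' log x + C' log c)."""
    E = np.asarray(E, dtype=float)
    x = np.asarray(x, dtype=float)
    c = model.c0 if c is None else np.asarray(c, dtype=float)
    if np.any(x <= 0) or np.any(c <= 0):
        raise ValueError("metabolite concentrations must be strictly positive")
    if np.any(E < 0):
        raise ValueError("enzyme abundances must be non-negative")
    return E * (params.Ap + params.Bp @ np.log(x) + params.Cp @ np.log(c))


def steady_state(
    model: LinlogModel,
    params: LinlogParams,
    E: np.ndarray,
    c: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic steady-state concentrations for enzyme levels E.

    Solves log x = -(N diag(E) B')^{-1} (N diag(E) (A' + C' log c)).

    Raises
    ------
    SingularSteadyStateError
        If N diag(E) B' is singular (callers in the optimization and
        evolution layers translate this into a worst-case objective value).
    """
    E = np.asarray(E, dtype=float)
    c = model.c0 if c is None else np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("external concentrations must be strictly positive")
    if np.any(E <= 0):
        raise ValueError("steady state requires strictly positive enzyme levels")
    NE = model.N * E[None, :]
    M = NE @ params.Bp
    rhs = NE @ (params.Ap + params.Cp @ np.log(c))
    try:
        logx = -np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSteadyStateError(str(exc)) from exc
    if not np.all(np.isfinite(logx)):
        raise SingularSteadyStateError("non-finite steady-state solution")
    return np.exp(logx)


# ---------------------------------------------------------------------------
# Serialization: JSON (single file) and TSV (three tables in a directory).
# Both dialects carry the same information and load bit-equivalently.
# ---------------------------------------------------------------------------


def _model_to_dict(model: LinlogModel) -> dict:
    reactions = []
    for i, rid in enumerate(model.reactions):
        stoich = {
            model.metabolites[j]: float(model.N[j, i])
            for j in range(model.n_metabolites)
            if model.N[j, i] != 0
        }
        reactions.append({"id": rid, "stoichiometry": stoich})
    elast = []
    for i in range(model.n_reactions):
        for j in range(model.n_metabolites):
            if model.Bx[i, j] != 0:
                elast.append(
                    {
                        "reaction": model.reactions[i],
                        "metabolite": model.metabolites[j],
                        "external": False,
                        "value": float(model.Bx[i, j]),
                    }
                )
        for k in range(model.n_external):
            if model.Bc[i, k] != 0:
                elast.append(
                    {
                        "reaction": model.reactions[i],
                        "metabolite": model.externals[k],
                        "external": True,
                        "value": float(model.Bc[i, k]),
                    }
                )
    return {
        "metabolites": list(model.metabolites),
        "externals": list(model.externals),
        "reactions": reactions,
        "reference": {
            "E0": [float(v) for v in model.E0],
            "J0": [float(v) for v in model.J0],
            "x0": [float(v) for v in model.x0],
            "c0": [float(v) for v in model.c0],
        },
        "elasticities": elast,
        "output_reaction": model.reactions[model.output_reaction],
    }


def _model_from_dict(data: dict) -> LinlogModel:
    try:
        metabolites = list(data["metabolites"])
        externals = list(data["externals"])
        reaction_specs = data["reactions"]
        ref = data["reference"]
        elast = data["elasticities"]
    except KeyError as exc:
        raise LoadError(f"missing required section {exc}") from exc
    met_idx = {mname: j for j, mname in enumerate(metabolites)}
    ext_idx = {cname: k for k, cname in enumerate(externals)}
    reactions = [spec["id"] for spec in reaction_specs]
    rxn_idx = {rid: i for i, rid in enumerate(reactions)}
    m, r = len(metabolites), len(reactions)
    N = np.zeros((m, r))
    for i, spec in enumerate(reaction_specs):
        for mname, coef in spec["stoichiometry"].items():
            if mname in ext_idx:
                continue  # external metabolites are parameters, not balanced
            if mname not in met_idx:
                raise LoadError(f"unknown metabolite {mname!r} in {spec['id']!r}")
            N[met_idx[mname], i] = float(coef)
    Bx = np.zeros((r, m))
    Bc = np.zeros((r, len(externals)))
    for entry in elast:
        rid = entry["reaction"]
        if rid not in rxn_idx:
            raise LoadError(f"elasticity references unknown reaction {rid!r}")
        i = rxn_idx[rid]
        mname = entry["metabolite"]
        if entry.get("external", False):
            if mname not in ext_idx:
                raise LoadError(f"unknown external metabolite {mname!r}")
            Bc[i, ext_idx[mname]] = float(entry["value"])
        else:
            if mname not in met_idx:
                raise LoadError(f"unknown metabolite {mname!r}")
            Bx[i, met_idx[mname]] = float(entry["value"])
    out = data.get("output_reaction", reactions[-1])
    try:
        model = LinlogModel(
            N=N,
            E0=np.asarray(ref["E0"], dtype=float),
            J0=np.asarray(ref["J0"], dtype=float),
            x0=np.asarray(ref["x0"], dtype=float),
            c0=np.asarray(ref["c0"], dtype=float),
            Bx=Bx,
            Bc=Bc,
            metabolites=metabolites,
            reactions=reactions,
            externals=externals,
            output_reaction=rxn_idx.get(out, -1) if isinstance(out, str) else int(out),
        )
    except (LoadError, ValueError) as exc:
        raise LoadError(str(exc)) from exc
    return model


def load_network(path: str | Path) -> LinlogModel:
    """Load a linlog model from a JSON file or a directory of TSV tables.

    The JSON dialect is a single object with ``metabolites``, ``externals``,
    ``reactions`` (id + stoichiometry mapping), ``reference`` (E0/J0/x0/c0)
    and ``elasticities`` sections. The TSV dialect is a directory holding
    ``reactions.tsv`` (reaction, metabolite, coefficient), ``reference.tsv``
    (kind, name, value) and ``elasticities.tsv`` (reaction, metabolite,
    external, value); both load to identical models.
    """
    path = Path(path)
    if path.is_dir():
        return _model_from_dict(_read_tsv_dir(path))
    with open(path) as fh:
        data = json.load(fh)
    return _model_from_dict(data)


def save_network(model: LinlogModel, path: str | Path, dialect: str = "json") -> None:
    """Write a model as JSON (``dialect='json'``) or a TSV directory."""
    path = Path(path)
    data = _model_to_dict(model)
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    elif dialect == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        _write_tsv_dir(data, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_tsv_dir(data: dict, path: Path) -> None:
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("reaction\tmetabolite\tcoefficient\n")
        for spec in data["reactions"]:
            for mname, coef in spec["stoichiometry"].items():
                fh.write(f"{spec['id']}\t{mname}\t{coef!r}\n")
    with open(path / "reference.tsv", "w") as fh:
        fh.write("kind\tname\tvalue\n")
        ref = data["reference"]
        for i, rid in enumerate([s["id"] for s in data["reactions"]]):
            fh.write(f"E0\t{rid}\t{ref['E0'][i]!r}\n")
            fh.write(f"J0\t{rid}\t{ref['J0'][i]!r}\n")
        for j, mname in enumerate(data["metabolites"]):
            fh.write(f"x0\t{mname}\t{ref['x0'][j]!r}\n")
        for k, cname in enumerate(data["externals"]):
            fh.write(f"c0\t{cname}\t{ref['c0'][k]!r}\n")
        fh.write(f"output\t{data['output_reaction']}\t0\n")
    with open(path / "elasticities.tsv", "w") as fh:
        fh.write("reaction\tmetabolite\texternal\tvalue\n")
        for e in data["elasticities"]:
            fh.write(
                f"{e['reaction']}\t{e['metabolite']}\t{int(e['external'])}\t{e['value']!r}\n"
            )


def _read_tsv_dir(path: Path) -> dict:
    import csv

    def read(name):
        fp = path / name
        if not fp.exists():
            raise LoadError(f"missing table {name} in {path}")
        with open(fp) as fh:
            return list(csv.DictReader(fh, delimiter="\t"))

    rxn_rows = read("reactions.tsv")
    ref_rows = read("reference.tsv")
    ela_rows = read("elasticities.tsv")

    reactions: dict[str, dict] = {}
    met_order: list[str] = []
    for row in rxn_rows:
        spec = reactions.setdefault(row["reaction"], {"id": row["reaction"], "stoichiometry": {}})
        spec["stoichiometry"][row["metabolite"]] = float(row["coefficient"])
        if row["metabolite"] not in met_order:
            met_order.append(row["metabolite"])

    E0, J0, x0, c0 = {}, {}, {}, {}
    output = None
    for row in ref_rows:
        kind, name, value = row["kind"], row["name"], row["value"]
        if kind == "E0":
            E0[name] = float(value)
        elif kind == "J0":
            J0[name] = float(value)
        elif kind == "x0":
            x0[name] = float(value)
        elif kind == "c0":
            c0[name] = float(value)
        elif kind == "output":
            output = name
        else:
            raise LoadError(f"unknown reference kind {kind!r}")
    metabolites = list(x0)
    externals = list(c0)
    rids = list(reactions)
    missing = [rid for rid in rids if rid not in E0 or rid not in J0]
    if missing:
        raise LoadError(f"reference state missing for reactions {missing}")
    elast = [
        {
            "reaction": row["reaction"],
            "metabolite": row["metabolite"],
            "external": bool(int(row["external"])),
            "value": float(row["value"]),
        }
        for row in ela_rows
    ]
    return {
        "metabolites": metabolites,
        "externals": externals,
        "reactions": [reactions[rid] for rid in rids],
        "reference": {
            "E0": [E0[rid] for rid in rids],
            "J0": [J0[rid] for rid in rids],
            "x0": [x0[mname] for mname in metabolites],
            "c0": [c0[cname] for cname in externals],
        },
        "elasticities": elast,
        "output_reaction": output if output is not None else rids[-1],
    }
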