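"""Metabolic control analysis: response formulas and control coefficients.

Flux control coefficients (FCC) ``C_Ei^J = d ln J / d ln E_i`` quantify the
fractional change in pathway flux per fractional change in one enzyme;
concentration control coefficients (CCC) do the same for metabolite pools.
They obey the summation theorems: FCCs over all enzymes sum to 1, CCCs sum
to 0. For finite (not infinitesimal) fold-changes ``r_i`` of a subset of
enzymes, the flux amplification factor is

    J_r / J_0 = 1 / (1 - sum_i C_Ei^J (r_i - 1) / r_i)

and the single-enzyme metabolite response is

    S_r / S_0 = (1 - (C^J - C^S)(r-1)/r) / (1 - C^J (r-1)/r).

The replication-coupled response composes the amplification factor with the
copy-number fold-changes that a shift of division time imposes on every
locus as a function of its ori–ter position: genes co-located at position p
give a pure flux rescaling 2**(((tau0-tauk)/(tauk*tau0)) ((1-p)C+D)) with no
metabolite perturbation, whereas scattered genes perturb metabolite pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linlog import LinlogModel, derive_parameters, rates, steady_state
from .replication import ReplicationParams, relative_abundance_change

__all__ = [
    "ControlCoefficients",
    "SingularResponseError",
    "flux_amplification",
    "metabolite_response_single_enzyme",
    "replication_flux_response",
    "clustered_flux_response",
    "control_coefficients_from_linlog",
]

_SINGULAR_TOL = 1e-12


class SingularResponseError(ZeroDivisionError):
    """The linear MCA response formula has a vanishing denominator.

    Signals that the requested perturbation drives the first-order MCA
    approximation outside its validity range.
    """


@dataclass
class ControlCoefficients:
    """Flux and concentration control coefficients of a metabolic model.

    fcc: (r,) array, one FCC per enzyme for the designated pathway flux.
    ccc: (r, m) array of CCCs, enzymes by metabolites.
    """

    fcc: np.ndarray
    ccc: np.ndarray
    reactions: list[str] | None = None
    metabolites: list[str] | None = None

    def summary(self) -> str:
        import pandas as pd

        rxn = self.reactions or [f"v{i}" for i in range(len(self.fcc))]
        met = self.metabolites or [f"x{j}" for j in range(self.ccc.shape[1])]
        df = pd.DataFrame(self.ccc, index=rxn, columns=met)
        df.insert(0, "FCC", self.fcc)
        footer = (
            f"\nsum(FCC) = {self.fcc.sum():.6f}; "
            f"max |sum CCC per metabolite| = {np.abs(self.ccc.sum(axis=0)).max():.2e}"
        )
        return df.to_string(float_format=lambda v: f"{v: .4f}") + footer


def flux_amplification(fcc_subset, r) -> float:
    """Finite-change flux amplification J_r/J_0 for enzyme fold-changes r.

    With a coordinate fold-change (all r_i equal) and FCCs summing to 1,
    the flux scales exactly by r.
    """
    fcc = np.asarray(fcc_subset, dtype=float)
    r = np.asarray(r, dtype=float)
    if fcc.shape != r.shape:
        raise ValueError("fcc_subset and r must be aligned")
    if np.any(r <= 0):
        raise ValueError("fold-changes must be positive")
    denom = 1.0 - float(np.sum(fcc * (r - 1.0) / r))
    if denom <= _SINGULAR_TOL:
        raise SingularResponseError(
            f"amplification denominator {denom:.3g} <= 0: linear MCA breaks down"
        )
    return 1.0 / denom


def metabolite_response_single_enzyme(fcc: float, ccc: float, r: float) -> float:
    """Metabolite fold-change S_r/S_0 when one enzyme scales by r.

    For an enzyme with negligible flux control (fcc = 0) this reduces to
    1 + ccc (r-1)/r, so even flux-neutral enzymes can perturb pools by
    arbitrarily large factors.
    """
    if r <= 0:
        raise ValueError("fold-change r must be positive")
    frac = (r - 1.0) / r
    denom = 1.0 - frac * fcc
    if abs(denom) <= _SINGULAR_TOL:
        raise SingularResponseError("metabolite response denominator vanished")
    return (1.0 - (fcc - ccc) * frac) / denom


def clustered_flux_response(
    p: float, params: ReplicationParams, tau0: float, tauk: float
) -> float:
    """Flux rescaling when all pathway genes sit at the same position p.

    Equals 2**(((tau0 - tauk) / (tauk tau0)) ((1 - p) C + D)): the common
    copy-number fold-change of the co-located genes, applied to the flux
    with no metabolite change (perfect homeostasis).
    """
    return relative_abundance_change(params.C, params.D, p, tau0, tauk)


def replication_flux_response(
    fcc,
    positions,
    params: ReplicationParams,
    tau0: float,
    tauk: float,
    regulator_ratio=None,
    degradation_ratio=None,
) -> float:
    """Pathway-flux fold-change when the division time shifts tau0 -> tauk.

    Each gene i at position p_i experiences the copy-number fold-change
    r_i (optionally modulated by regulator and degradation ratios); the
    aggregate flux response is the amplification factor over those r_i.
    With equal positions, unit ratios and FCCs summing to 1 this equals
    :func:`clustered_flux_response`.
    """
    fcc = np.asarray(fcc, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if fcc.shape != positions.shape:
        raise ValueError("fcc and positions must be aligned")
    n = fcc.size
    reg = np.ones(n) if regulator_ratio is None else np.asarray(regulator_ratio, float)
    deg = np.ones(n) if degradation_ratio is None else np.asarray(degradation_ratio, float)
    r = np.array(
        [
            relative_abundance_change(
                params.C, params.D, p, tau0, tauk, f0=1.0, fk=reg[i], gamma0=deg[i], gammak=1.0
            )
            for i, p in enumerate(positions)
        ]
    )
    return flux_amplification(fcc, r)


def control_coefficients_from_linlog(
    model: LinlogModel,
    rel_step: float = 1e-4,
    output_reaction: int | None = None,
) -> ControlCoefficients:
    """Estimate FCCs and CCCs by central finite differences in log-enzyme space.

    Each enzyme is perturbed by a factor exp(+/- rel_step) around the
    reference state; the steady state is re-solved analytically and the
    log-derivatives of the designated output-reaction flux (FCC) and of
    every metabolite concentration (CCC) are taken. On a valid model the
    summation theorems are recovered to ~rel_step**2.
    """
    params = derive_parameters(model)
    out = model.output_reaction if output_reaction is None else output_reaction
    r, m = model.n_reactions, model.n_metabolites
    fcc = np.zeros(r)
    ccc = np.zeros((r, m))
    h = rel_step
    for i in range(r):
        logj = []
        logx = []
        for sign in (+1.0, -1.0):
            E = model.E0.copy()
            E[i] *= np.exp(sign * h)
            x = steady_state(model, params, E)
            v = rates(model, params, E, x)
            if v[out] <= 0:
                raise FloatingPointError(
                    "output flux became non-positive during perturbation"
                )
            logj.append(np.log(v[out]))
            logx.append(np.log(x))
        fcc[i] = (logj[0] - logj[1]) / (2.0 * h)
        ccc[i] = (logx[0] - logx[1]) / (2.0 * h)
    return ControlCoefficients(
        fcc=fcc, ccc=ccc, reactions=list(model.reactions), metabolites=list(model.metabolites)
    )
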