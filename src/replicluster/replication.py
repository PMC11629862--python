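"""Locus copy number under the Helmstetter–Cooper replication model.

In bacteria that replicate bidirectionally from a single origin, a locus at
fractional position ``p`` along its replichore (``p = 0`` at the origin,
``p = 1`` at the terminus) is copied ``(1 - p) * C`` minutes before the end
of the C period. Averaged over an exponentially growing population with
division time ``tau`` and post-replication delay ``D``, the mean copy
number of the locus is ``2 ** (((1 - p) * C + D) / tau)``, which decreases
from origin to terminus. The log2 ratio of origin to terminus copy number
(the peak-to-trough ratio of sequencing coverage) equals ``C / tau``.

Copy numbers here are continuous population averages; the per-cell integer
view with discrete replication forks is :func:`instantaneous_copy_number`.
Positions are defined per replichore: each arm of a circular chromosome
maps independently onto [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReplicationParams",
    "TranscriptParams",
    "average_copy_number",
    "log2_ptr",
    "growth_rate",
    "instantaneous_copy_number",
    "transcript_steady_state",
    "relative_abundance_change",
]


@dataclass(frozen=True)
class ReplicationParams:
    """Cell-cycle parameters of the Helmstetter–Cooper model.

    Parameters
    ----------
    C : float
        DNA replication period in minutes (time for a fork to traverse one
        replichore). Must be positive.
    D : float
        Delay between the end of replication and cell division, minutes.
        Must be non-negative.
    tau : float
        Division (doubling) time in minutes. Must be positive.
    """

    C: float
    D: float = 0.0
    tau: float = 60.0

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ValueError(f"C must be positive, got {self.C}")
        if not (self.D >= 0):
            raise ValueError(f"D must be non-negative, got {self.D}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class TranscriptParams:
    """Promoter output and transcript decay for one gene.

    ``f_y`` is the evaluated regulatory function (transcription rate per
    gene copy); ``gamma`` is the first-order transcript degradation rate
    (1/min), i.e. ``ln 2 / t_half``.
    """

    f_y: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.f_y >= 0):
            raise ValueError(f"f_y must be non-negative, got {self.f_y}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def _check_position(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("fractional position p must lie in [0, 1]")
    return p


def average_copy_number(params: ReplicationParams, p) -> np.ndarray | float:
    """Population-average copy number of a locus at fractional position p.

    Returns ``2 ** (((1 - p) * C + D) / tau)``; strictly decreasing in p
    and >= 1 whenever ``D >= 0``. Accepts scalars or arrays of positions.
    """
    p_arr = _check_position(p)
    n = 2.0 ** (((1.0 - p_arr) * params.C + params.D) / params.tau)
    return float(n) if np.isscalar(p) or n.ndim == 0 else n


def log2_ptr(params: ReplicationParams) -> float:
    """log2 of the origin:terminus copy-number (peak-to-trough) ratio, = C/tau."""
    return params.C / params.tau


def growth_rate(params: ReplicationParams) -> float:
    """Exponential growth rate mu = ln2 / tau, in 1/min."""
    return math.log(2.0) / params.tau


def instantaneous_copy_number(round_progress: Sequence[float], p: float) -> int:
    """Per-cell integer copy number with explicit nested replication rounds.

    ``round_progress`` lists the fractional fork progress of each active
    replication round, oldest first with strictly decreasing progress
    (round i carries 2**(i-1) forks per replichore because it initiated on
    every product of the previous round). A locus at position p has been
    copied by every round whose progress exceeds p, so it is present in
    ``2**k`` copies where k counts those rounds.
    """
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError("fractional position p must lie in [0, 1]")
    prog = [float(g) for g in round_progress]
    for g in prog:
        if not (0.0 < g < 1.0):
            raise ValueError("round progress values must lie in (0, 1)")
    if any(a <= b for a, b in zip(prog, prog[1:])):
        raise ValueError(
            "round progress must be strictly decreasing (oldest round first)"
        )
    k = sum(1 for g in prog if g > p)
    return 2**k


def transcript_steady_state(
    params: ReplicationParams, p: float, t: TranscriptParams
) -> float:
    """Steady-state transcript abundance n(p) * f_y / gamma.

    Linear birth/death balance per gene copy: production n(p)*f_y,
    first-order decay gamma.
    """
    return average_copy_number(params, p) * t.f_y / t.gamma


def relative_abundance_change(
    C: float,
    D: float,
    p: float,
    tau0: float,
    tauk: float,
    f0: float = 1.0,
    fk: float = 1.0,
    gamma0: float = 1.0,
    gammak: float = 1.0,
) -> float:
    """Fold-change r of a transcript when division time shifts tau0 -> tauk.

    r = n_k/n_0 * (f_k/f_0) * (gamma_0/gamma_k)
      = 2**(((tau0 - tauk)/(tauk*tau0)) * ((1-p)*C + D)) * (f_k/f_0) * (g_0/g_k)

    Faster growth (tauk < tau0) raises the copy number of every locus with
    p < 1 (or D > 0), hence r > 1 there when promoters and decay are equal.
    """
    if min(tau0, tauk, f0, gamma0, gammak) <= 0 or C <= 0 or D < 0:
        raise ValueError("times and rates must be positive (D non-negative)")
    if fk < 0:
        raise ValueError("fk must be non-negative")
    p = float(_check_position(p))
    exponent = ((tau0 - tauk) / (tauk * tau0)) * ((1.0 - p) * C + D)
    return 2.0**exponent * (fk / f0) * (gamma0 / gammak)
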