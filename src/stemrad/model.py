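"""Non-spatial model ingredients: reaction terms, equilibria and stability.

The reaction part of the model reads (all rates per year)::

    dS/dt = (2 p(D, a) - 1) eps S + q(m(t - tau)) D(t - tau)
    dD/dt = 2 (1 - p(D, a)) eps S - (d + q(m)) D
    da/dt = a (beta S a / (1 + a) - alpha)
    dm/dt = gamma exp(-S / S0) - alpha m

with the symmetric-division probability ``p`` and the dedifferentiation rate
``q`` of :func:`fraction_p` and :func:`dediff_rate_q`.  The delayed arguments
(only ``m`` and ``D`` are ever delayed) are supplied explicitly, which keeps
these functions usable both for 0-D trajectories and as the local part of the
reaction-diffusion right-hand side.

Equilibria
----------
``E1 = (0, 0, 0, m1)`` is the empty state.  ``E2 = (S2, S2/d, 0, m2)`` with
``S2 = -S0 ln(alpha m2 / gamma)`` is the working point of the whole analysis:
the closed forms satisfy the m-equation for any ``m2``, but the S- and
D-equations balance exactly only at the single value ``m2*`` where
``q(m2*) = d`` (see :func:`consistent_m2`).  ``E3`` activates the Wnt-beta
pathway; its ``a3`` is the positive root of
``eta (1 - r) a^2 - (1 + r (1 + eta)) a - r = 0`` with ``r = psi alpha / (d
beta)``, equivalently the state where ``p(D3, a3) = 1/2``, and is an exact
equilibrium only in the limit ``q(m3) -> 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "CellState",
    "EquilibriumPoint",
    "fraction_p",
    "dediff_rate_q",
    "reaction_rhs",
    "equilibrium_E1",
    "equilibrium_E2",
    "equilibrium_E3",
    "consistent_m2",
    "e2_stability_at_zero_delay",
]


@dataclass(frozen=True)
class CellState:
    """Concentrations (S, D, a, m); scalar values or equally shaped arrays."""

    S: float | np.ndarray
    D: float | np.ndarray
    a: float | np.ndarray
    m: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("S", "D", "a", "m"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.D, self.a, self.m], dtype=float)


@dataclass(frozen=True)
class EquilibriumPoint:
    label: Literal["E1", "E2", "E3"]
    state: CellState
    free_parameter: float | None
    stable: Literal["stable", "unstable", "conditional"]


def fraction_p(D, a, params: ModelParameters):
    """Probability that a CSC division yields two CSCs (divided by two).

    ``p = eta a / ((1 + eta a) (1 + psi D))``, in [0, 1): increasing in the
    activator ``a``, decreasing in the inhibiting DC concentration ``D``.
    """
    D = np.asarray(D, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(D < 0) or np.any(a < 0):
        raise ValueError("fraction_p requires D >= 0 and a >= 0")
    ea = params.eta * a
    out = ea / ((1.0 + ea) * (1.0 + params.psi * D))
    return out if out.ndim else float(out)


def dediff_rate_q(m_delayed, params: ModelParameters):
    """Dedifferentiation rate ``q = q0/2 (1 + tanh((m - m0)/sigma))`` in (0, q0)."""
    m_delayed = np.asarray(m_delayed, dtype=float)
    if np.any(m_delayed < 0):
        raise ValueError("dediff_rate_q requires m >= 0")
    if params.sigma == 0:
        raise ValueError("sigma must be nonzero")
    out = 0.5 * params.q0 * (1.0 + np.tanh((m_delayed - params.m0) / params.sigma))
    return out if out.ndim else float(out)


def reaction_rhs(state: CellState, delayed: CellState, params: ModelParameters) -> np.ndarray:
    """The four non-diffusive right-hand sides.

    ``delayed`` supplies ``m(t - tau)`` and ``D(t - tau)``, used only in the
    S-equation; the mitotic rate ``epsilon`` multiplies both S-equation terms.
    Returns an array shaped like the state components, ordered (S, D, a, m).
    """
    p = fraction_p(state.D, state.a, params)
    q_now = dediff_rate_q(state.m, params)
    q_del = dediff_rate_q(delayed.m, params)
    eps = params.epsilon
    dS = (2.0 * p - 1.0) * eps * state.S + q_del * delayed.D
    dD = 2.0 * (1.0 - p) * eps * state.S - (params.d + q_now) * state.D
    da = state.a * (params.beta * state.S * state.a / (1.0 + state.a) - params.alpha)
    dm = params.gamma * np.exp(-state.S / params.S0) - params.alpha * state.m
    return np.array([dS, dD, da, dm])


def consistent_m2(params: ModelParameters) -> float:
    """The unique microRNA level at which E2 is an exact equilibrium.

    The S- and D-equations balance at E2 iff ``q(m2) = d``, i.e.
    ``m2* = m0 + sigma artanh(2 d / q0 - 1)``; requires ``0 < d < q0``.
    """
    ratio = 2.0 * params.d / params.q0 - 1.0
    if not -1.0 < ratio < 1.0:
        raise ValueError("consistent m2 requires 0 < d < q0")
    return params.m0 + params.sigma * math.atanh(ratio)


def equilibrium_E1(m1: float) -> EquilibriumPoint:
    """The empty state (0, 0, 0, m1); an equilibrium iff m1 = gamma/alpha."""
    if m1 < 0:
        raise ValueError("m1 must be >= 0")
    return EquilibriumPoint("E1", CellState(0.0, 0.0, 0.0, m1), m1, "conditional")


def equilibrium_E2(params: ModelParameters, m2: float) -> EquilibriumPoint:
    """Closed-form E2 = (S2, S2/d, 0, m2), S2 = -S0 ln(alpha m2 / gamma).

    Valid for 0 < m2 < gamma/alpha (so that S2 > 0).  The point solves the
    m-equation identically; the S/D balance is exact only at
    ``m2 = consistent_m2(params)``.
    """
    if not 0.0 < m2:
        raise ValueError("E2 requires m2 > 0")
    if m2 >= params.gamma / params.alpha:
        raise ValueError(
            "equilibrium leaves the admissible region: m2 >= gamma/alpha"
        )
    S2 = -params.S0 * math.log(params.alpha * m2 / params.gamma)
    stable = "stable" if e2_stability_at_zero_delay(params, m2) else "unstable"
    return EquilibriumPoint("E2", CellState(S2, S2 / params.d, 0.0, m2), m2, stable)


def equilibrium_E3(params: ModelParameters) -> EquilibriumPoint:
    """Activated-pathway state; a3 from its closed form, p(D3, a3) = 1/2."""
    r = params.psi * params.alpha / (params.d * params.beta)
    if r == 1.0:
        raise ValueError("E3 undefined: psi*alpha/(d*beta) == 1")
    lead = 1.0 + r * (1.0 + params.eta)
    a3 = (lead / (2.0 * params.eta * (1.0 - r))) * (
        1.0 + math.sqrt(1.0 + 4.0 * r * params.eta * (1.0 - r) / lead**2)
    )
    S3 = params.alpha * (1.0 + a3) / (params.beta * a3)
    D3 = S3 / params.d
    m3 = (params.gamma / params.alpha) * math.exp(-S3 / params.S0)
    return EquilibriumPoint("E3", CellState(S3, D3, a3, m3), None, "unstable")


def e2_stability_at_zero_delay(params: ModelParameters, m2: float) -> bool:
    """E2 is stable at tau = 0 iff d < q0 and m2 < gamma/alpha (strictly)."""
    return params.d < params.q0 and m2 < params.gamma / params.alpha
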