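"""Method-of-lines integration of the delayed reaction-diffusion system.

Space is discretised on a cell-centred uniform grid with a five-point
Laplacian; zero-flux boundaries are realised by mirror ghost cells across the
boundary faces, which makes the discrete operator exactly conservative (the
sum of the Laplacian over the domain telescopes to zero).  Time stepping is
the classical fourth-order Runge-Kutta scheme; the delayed quantities --
only ``m(t - tau)`` and ``D(t - tau)`` enter the equations -- are read from a
ring-buffer history by cubic Hermite interpolation on the step interval
bracketing the delayed time, using the stored stage-consistent derivatives.
The history is initialised constant at the initial condition on [-tau, 0].

The same driver integrates the homogeneous (0-D) system when no grid is
given, which is the reduction used for bifurcation scans, and accepts an
optional radiotherapy term contributing ``-delta R S`` to the S-equation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "SimulationGrid",
    "FieldState",
    "HistoryBuffer",
    "laplacian",
    "initial_condition",
    "PRINTED_E2",
    "simulate",
    "SimulationResult",
    "pattern_metrics",
    "PatternMetrics",
]

#: Equilibrium anchor (S2, D2, a2, m2) used by the published initial fields.
PRINTED_E2 = (0.140000, 0.001605, 0.000000, 0.080000)


class ConfigurationError(ValueError):
    """Raised for inconsistent numerical settings (e.g. unstable dt)."""


@dataclass(frozen=True)
class SimulationGrid:
    """Cell-centred square grid on (0, L) x (0, L) with zero-flux boundaries."""

    L: float
    nx: int
    ny: int
    boundary: str = "zero-flux"

    def __post_init__(self) -> None:
        if self.L <= 0 or self.nx < 3 or self.ny < 3:
            raise ValueError("grid requires L > 0 and at least 3 cells per side")

    @classmethod
    def from_spacing(cls, L: float, dx: float) -> "SimulationGrid":
        n = round(L / dx)
        if abs(n * dx - L) > 1e-9 * L:
            raise ValueError("dx must divide L")
        return cls(L=L, nx=n, ny=n)

    @property
    def dx(self) -> float:
        return self.L / self.nx

    @property
    def dy(self) -> float:
        return self.L / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-centre coordinates, indexing 'ij'."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dy
        return np.meshgrid(x, y, indexing="ij")


def laplacian(f: np.ndarray, grid: SimulationGrid) -> np.ndarray:
    """Five-point Laplacian with mirror (zero-flux) ghost cells."""
    if f.shape != grid.shape:
        raise ValueError(f"field shape {f.shape} != grid shape {grid.shape}")
    p = np.pad(f, 1, mode="edge")
    return (
        (p[2:, 1:-1] - 2.0 * f + p[:-2, 1:-1]) / grid.dx**2
        + (p[1:-1, 2:] - 2.0 * f + p[1:-1, :-2]) / grid.dy**2
    )


@dataclass
class FieldState:
    """Concentration fields (or scalars for the homogeneous reduction) at time t."""

    S: np.ndarray
    D: np.ndarray
    a: np.ndarray
    m: np.ndarray
    t: float = 0.0

    def stacked(self) -> np.ndarray:
        return np.stack([np.asarray(self.S, float), np.asarray(self.D, float),
                         np.asarray(self.a, float), np.asarray(self.m, float)])

    @classmethod
    def from_stacked(cls, y: np.ndarray, t: float) -> "FieldState":
        return cls(S=y[0], D=y[1], a=y[2], m=y[3], t=t)

    def means(self) -> np.ndarray:
        return np.array([np.mean(self.S), np.mean(self.D),
                         np.mean(self.a), np.mean(self.m)])


def initial_condition(
    grid: SimulationGrid,
    anchor: tuple[float, float, float, float] = PRINTED_E2,
) -> FieldState:
    """The published trigonometric perturbations of the E2 state.

    The four fields are perturbed around ``anchor = (S2, D2, a2, m2)``::

        S = S2 - 0.1   cos((x^2+y^2) pi - 0.01  sin((x^2+y^2) pi))
        D = D2 - 0.0002 cos(sqrt(x^2+y^2) pi + 0.0003 sin(sqrt(x^2+y^2) pi))
        a = a2 + 0.002 cos^2(x + 2) + 0.001 sin^2(y + 4)
        m = m2 + 0.001 cos^2(x - 2) + 0.001 sin^2(y - 4)

    The nesting of the S and D formulas follows the source verbatim (the
    small sine term perturbs the phase of the cosine); the squared
    trigonometric reading of the a and m formulas makes those perturbations
    non-negative and matches their quoted anchor values.  Any negative cell
    value is clamped to zero for admissibility.
    """
    S2, D2, a2, m2 = anchor
    X, Y = grid.coordinates()
    r2 = X**2 + Y**2
    r = np.sqrt(r2)
    S = S2 - 0.1 * np.cos(r2 * np.pi - 0.01 * np.sin(r2 * np.pi))
    D = D2 - 0.0002 * np.cos(r * np.pi + 0.0003 * np.sin(r * np.pi))
    a = a2 + 0.002 * np.cos(X + 2.0) ** 2 + 0.001 * np.sin(Y + 4.0) ** 2
    m = m2 + 0.001 * np.cos(X - 2.0) ** 2 + 0.001 * np.sin(Y - 4.0) ** 2
    return FieldState(
        S=np.clip(S, 0.0, None), D=np.clip(D, 0.0, None),
        a=np.clip(a, 0.0, None), m=np.clip(m, 0.0, None), t=0.0,
    )


class HistoryBuffer:
    """Uniformly sampled past values of the delayed fields D and m.

    One sample is appended at the start of every accepted step, holding the
    field values and their time-derivatives (the first Runge-Kutta stage,
    which is the exact right-hand side at the sample).  Queries earlier than
    the first sample return the constant pre-history.
    """

    def __init__(self, t0: float, D0: np.ndarray, m0: np.ndarray,
                 dt: float, horizon: float) -> None:
        self.dt = dt
        self.t0 = t0
        self._initial = (np.asarray(D0, float), np.asarray(m0, float))
        capacity = max(2, int(math.ceil(horizon / dt)) + 3)
        self._buf: deque = deque(maxlen=capacity)

    def append(self, t: float, D: np.ndarray, m: np.ndarray,
               dD: np.ndarray, dm: np.ndarray) -> None:
        self._buf.append((t, np.array(D, float, copy=True), np.array(m, float, copy=True),
                          np.array(dD, float, copy=True), np.array(dm, float, copy=True)))

    def spans(self, t_query: float) -> bool:
        return t_query <= self.t0 or (
            len(self._buf) >= 2 and self._buf[0][0] <= t_query <= self._buf[-1][0]
        )

    def interpolate(self, t_query: float) -> tuple[np.ndarray, np.ndarray]:
        """Cubic Hermite interpolation of (D, m) at ``t_query``."""
        if t_query <= self.t0 + 1e-12 * max(1.0, abs(self.t0)):
            return self._initial
        if not self._buf:
            raise RuntimeError("history buffer is empty")
        tb = self._buf[0][0]
        idx = int(math.floor((t_query - tb) / self.dt + 1e-9))
        idx = min(max(idx, 0), len(self._buf) - 1)
        t_l = self._buf[idx][0]
        if t_query < t_l and idx > 0:
            idx -= 1
            t_l = self._buf[idx][0]
        if idx == len(self._buf) - 1:
            # exactly at the newest sample
            _, D, m, _, _ = self._buf[idx]
            return D, m
        t_l, Dl, ml, dDl, dml = self._buf[idx]
        t_r, Dr, mr, dDr, dmr = self._buf[idx + 1]
        h = t_r - t_l
        s = (t_query - t_l) / h
        h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
        h10 = s * (1.0 - s) ** 2
        h01 = s**2 * (3.0 - 2.0 * s)
        h11 = s**2 * (s - 1.0)
        D = h00 * Dl + h10 * h * dDl + h01 * Dr + h11 * h * dDr
        m = h00 * ml + h10 * h * dml + h01 * mr + h11 * h * dmr
        return D, m


class RadiationTerm(Protocol):
    """Anything providing a kill-rate constant for one step interval."""

    def rate_for_step(self, t: float, dt: float) -> float: ...


def _reaction(y: np.ndarray, D_del, m_del, p: ModelParameters) -> np.ndarray:
    """Raw reaction right-hand side on stacked fields (no validation/clamping)."""
    S, D, a, m = y
    ea = p.eta * a
    frac = ea / ((1.0 + ea) * (1.0 + p.psi * D))
    q_now = 0.5 * p.q0 * (1.0 + np.tanh((m - p.m0) / p.sigma))
    q_del = 0.5 * p.q0 * (1.0 + np.tanh((m_del - p.m0) / p.sigma))
    eps = p.epsilon
    dS = (2.0 * frac - 1.0) * eps * S + q_del * D_del
    dD = 2.0 * (1.0 - frac) * eps * S - (p.d + q_now) * D
    da = a * (p.beta * S * a / (1.0 + a) - p.alpha)
    dm = p.gamma * np.exp(-S / p.S0) - p.alpha * m
    return np.stack([dS, dD, da, dm])


@dataclass
class SimulationResult:
    """Probe time series, spatial means and snapshots of one run."""

    t: np.ndarray
    means: np.ndarray                      # shape (n_t, 4): S, D, a, m
    probes: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    snapshots: dict[float, FieldState] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    params: ModelParameters | None = None

    def series(self, component: str) -> np.ndarray:
        return self.means[:, "SDam".index(component)]


def simulate(
    params: ModelParameters,
    t_end: float,
    dt: float = 0.01,
    grid: SimulationGrid | None = None,
    initial: FieldState | None = None,
    record_times: Iterable[float] = (),
    probes: Iterable[tuple[int, int]] = (),
    radiation: RadiationTerm | None = None,
    include_reaction: bool = True,
) -> SimulationResult:
    """Integrate the (possibly delayed, possibly spatial) system to ``t_end``.

    Without a grid the homogeneous reduction is integrated from ``initial``
    (default: the equilibrium anchor of the published initial fields); with a
    grid the default initial condition is :func:`initial_condition`.  The run
    is fully deterministic.  ``radiation`` adds ``-delta R S`` to the
    S-equation with the per-step rate supplied by the term object;
    ``include_reaction=False`` integrates pure diffusion (a conservation
    diagnostic).  Raises :class:`ConfigurationError` for a diffusion-unstable
    ``dt`` or a delay shorter than one step, and aborts on non-finite fields.
    """
    p = params
    tau = p.tau
    if dt <= 0 or t_end <= 0:
        raise ConfigurationError("dt and t_end must be positive")
    if 0.0 < tau < dt:
        raise ConfigurationError("delay tau must be 0 or >= dt")
    if grid is not None:
        dmax = max(p.DS, p.DD, p.Da, p.Dm)
        limit = grid.dx**2 / (4.0 * dmax)
        if dt > limit:
            raise ConfigurationError(
                f"dt={dt} exceeds the diffusion stability bound {limit:.4g}"
            )
    if initial is None:
        if grid is not None:
            initial = initial_condition(grid)
        else:
            S2, D2, a2, m2 = PRINTED_E2
            initial = FieldState(S=np.float64(S2), D=np.float64(D2),
                                 a=np.float64(a2), m=np.float64(m2), t=0.0)
    y = initial.stacked().astype(float)
    if grid is not None and y.shape[1:] != grid.shape:
        raise ConfigurationError("initial fields do not match the grid")

    def rhs(t: float, y: np.ndarray, D_del, m_del, rad_rate: float) -> np.ndarray:
        out = _reaction(y, D_del, m_del, p) if include_reaction else np.zeros_like(y)
        if grid is not None:
            out[0] += p.DS * laplacian(y[0], grid)
            out[1] += p.DD * laplacian(y[1], grid)
            out[2] += p.Da * laplacian(y[2], grid)
            out[3] += p.Dm * laplacian(y[3], grid)
        if rad_rate:
            out[0] -= rad_rate * y[0]
        return out

    n_steps = int(round(t_end / dt))
    history = HistoryBuffer(0.0, y[1], y[3], dt, max(tau, dt))
    record_times = sorted(set(float(rt) for rt in record_times))
    rec_idx = {int(round(rt / dt)) for rt in record_times}
    probes = [tuple(q) for q in probes]

    times = np.empty(n_steps + 1)
    means = np.empty((n_steps + 1, 4))
    probe_data = {q: np.empty((n_steps + 1, 4)) for q in probes}
    snapshots: dict[float, FieldState] = {}
    warnings: list[str] = []

    def record(i: int, t: float, y: np.ndarray) -> None:
        times[i] = t
        means[i] = [np.mean(c) for c in y]
        for q in probes:
            probe_data[q][i] = y[(slice(None),) + q]
        if i in rec_idx:
            snapshots[round(t, 10)] = FieldState.from_stacked(y.copy(), t)

    record(0, 0.0, y)

    neg_flagged = False
    for i in range(n_steps):
        t = i * dt
        rad_rate = radiation.rate_for_step(t, dt) if radiation is not None else 0.0
        if tau > 0.0:
            D_del0, m_del0 = history.interpolate(t - tau)
            D_delh, m_delh = history.interpolate(t + 0.5 * dt - tau)
            D_del1, m_del1 = history.interpolate(t + dt - tau)
            k1 = rhs(t, y, D_del0, m_del0, rad_rate)
            history.append(t, y[1], y[3], k1[1], k1[3])
            y2 = y + 0.5 * dt * k1
            k2 = rhs(t + 0.5 * dt, y2, D_delh, m_delh, rad_rate)
            y3 = y + 0.5 * dt * k2
            k3 = rhs(t + 0.5 * dt, y3, D_delh, m_delh, rad_rate)
            y4 = y + dt * k3
            k4 = rhs(t + dt, y4, D_del1, m_del1, rad_rate)
        else:
            # no delay: classical RK4, delayed arguments are the stage values
            k1 = rhs(t, y, y[1], y[3], rad_rate)
            y2 = y + 0.5 * dt * k1
            k2 = rhs(t + 0.5 * dt, y2, y2[1], y2[3], rad_rate)
            y3 = y + 0.5 * dt * k2
            k3 = rhs(t + 0.5 * dt, y3, y3[1], y3[3], rad_rate)
            y4 = y + dt * k3
            k4 = rhs(t + dt, y4, y4[1], y4[3], rad_rate)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite field values at t = {t + dt:.4f}; reduce dt or check parameters"
            )
        if not neg_flagged:
            for ci, name in enumerate("SDam"):
                lo = float(np.min(y[ci]))
                scale = float(np.max(np.abs(y[ci]))) or 1.0
                if lo < -1e-8 * scale:
                    warnings.append(
                        f"{name} dropped to {lo:.3e} at t = {t + dt:.4f} "
                        "(possible numerical misconfiguration)"
                    )
                    neg_flagged = True
        record(i + 1, (i + 1) * dt, y)

    return SimulationResult(
        t=times, means=means, probes=probe_data,
        snapshots=snapshots, warnings=warnings, params=p,
    )


@dataclass(frozen=True)
class PatternMetrics:
    """Summary statistics of one spatial snapshot field."""

    minimum: float
    maximum: float
    mean: float
    center_of_mass: tuple[float, float]
    localization_radius: float
    radial_fraction: float
    radial_profile: np.ndarray      # mean deviation per radius bin
    radial_bins: np.ndarray         # outer radius of each bin


def pattern_metrics(f: np.ndarray, grid: SimulationGrid, n_bins: int | None = None) -> PatternMetrics:
    """Quantify localisation and circular symmetry of a pattern snapshot.

    The deviation energy is the squared departure from the spatial mean.  The
    localisation radius is the smallest radius around the domain centre
    containing 90% of that energy (0 for a uniform field).  The radial
    fraction is the share of deviation variance captured by the angular mean
    at each radius: close to 1 for circularly symmetric patterns.
    """
    f = np.asarray(f, float)
    if f.shape != grid.shape:
        raise ValueError("field does not match grid")
    X, Y = grid.coordinates()
    mean = float(f.mean())
    dev = f - mean
    energy = dev**2
    total = float(energy.sum())
    com = (
        (float((X * f).sum() / f.sum()), float((Y * f).sum() / f.sum()))
        if f.sum() != 0 else (grid.L / 2, grid.L / 2)
    )
    r = np.hypot(X - grid.L / 2.0, Y - grid.L / 2.0)
    if n_bins is None:
        n_bins = max(8, grid.nx // 2)
    edges = np.linspace(0.0, float(r.max()) + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(r.ravel(), edges) - 1, 0, n_bins - 1)
    prof = np.bincount(which, weights=dev.ravel(), minlength=n_bins)
    counts = np.maximum(np.bincount(which, minlength=n_bins), 1)
    prof = prof / counts
    uniform_floor = (1e-13 * max(1.0, abs(mean))) ** 2 * f.size
    if total <= uniform_floor:
        return PatternMetrics(mean, mean, mean, com, 0.0, 1.0, prof, edges[1:])
    order = np.argsort(r.ravel())
    cum = np.cumsum(energy.ravel()[order])
    j = int(np.searchsorted(cum, 0.9 * total))
    radius = float(r.ravel()[order][min(j, r.size - 1)])
    radial_part = prof[which].reshape(f.shape)
    frac = float(np.sum(radial_part**2) / total)
    return PatternMetrics(
        minimum=float(f.min()), maximum=float(f.max()), mean=mean,
        center_of_mass=com, localization_radius=radius,
        radial_fraction=min(frac, 1.0), radial_profile=prof, radial_bins=edges[1:],
    )
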