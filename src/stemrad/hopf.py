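"""Linear stability of E2 with delay and diffusion: Hopf analysis.

Perturbing E2 with Fourier modes ``exp(lambda t) cos(kx x) cos(ky y)`` turns
the linearised system into ``(A + B exp(-lambda tau) - lambda I) v = 0``,
where ``A`` collects the instantaneous couplings (including the ``-D k^2``
diffusion terms on the diagonal) and the rank-one ``B`` the two delayed
entries of the S-equation.  The characteristic equation is the transcendental
quartic::

    lambda^4 + C11 lambda^3 + C22 lambda^2 + C33 lambda + C44
        + (E11 lambda^2 + E22 lambda + E33) exp(-lambda tau) = 0.

Because the activator row decouples at E2 (``a2 = 0``), the quartic factors
exactly as ``(lambda + alpha + Da k^2) x (delayed cubic)``, which yields the
closed-form coefficients implemented in :func:`char_coefficients`; the tests
validate them against a numerically evaluated determinant.

Purely imaginary roots ``i omega`` satisfy a quartic in ``z = omega^2``;
for each admissible ``omega`` the crossing phase ``omega tau`` (mod 2 pi) is
uniquely determined by the real/imaginary split of the characteristic
equation, giving the delay branches ``tau_k^(j)``.  The crossing is a Hopf
point when the transversality sign -- the sign of ``Re (d lambda / d tau)``
at the crossing -- is positive.  :func:`critical_delay` assembles the minimal
such delay over a set of zero-flux spatial modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import consistent_m2, e2_stability_at_zero_delay, equilibrium_E2
from .parameters import ModelParameters

__all__ = [
    "CharCoefficients",
    "Crossing",
    "HopfResult",
    "jacobian_at_E2",
    "char_coefficients",
    "omega_roots",
    "crossing_trig",
    "critical_delays",
    "transversality",
    "critical_delay",
    "neumann_modes",
    "characteristic_root",
    "DEFAULT_M2",
]

#: microRNA level used for the published analysis (the initial-condition value).
DEFAULT_M2 = 0.08

_REAL_TOL = 1e-9
_POS_TOL = 1e-12


def _e2_ingredients(params: ModelParameters, m2: float) -> tuple[float, float, float, float]:
    """(S2, D2, w, u): equilibrium values and the delayed/m-row couplings.

    ``w = (2 d D2 / sigma)(1 - d/q0)`` is ``q'(m2) D2`` under the equilibrium
    substitution ``q(m2) = d``; ``u = (alpha / S0) m2`` is the magnitude of
    the m-equation's sensitivity to S.
    """
    eq = equilibrium_E2(params, m2)
    S2, D2 = eq.state.S, eq.state.D
    w = (2.0 * params.d * D2 / params.sigma) * (1.0 - params.d / params.q0)
    u = params.alpha / params.S0 * m2
    return S2, D2, w, u


def jacobian_at_E2(
    params: ModelParameters, m2: float = DEFAULT_M2, ksq: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous part A and delayed part B of the linearisation at E2.

    The characteristic matrix is ``A + B exp(-lambda tau) - lambda I``.
    ``ksq`` is the squared total wavenumber of the spatial mode (1/mm^2).
    """
    if ksq < 0:
        raise ValueError("ksq must be >= 0")
    S2, D2, w, u = _e2_ingredients(params, m2)
    c = 2.0 * S2 * params.eta / (1.0 + params.psi * D2)
    al = params.alpha
    A = np.array([
        [-params.epsilon - params.DS * ksq, 0.0, c, 0.0],
        [2.0 * params.epsilon, -2.0 * params.d - params.DD * ksq, -c, -w],
        [0.0, 0.0, -al - params.Da * ksq, 0.0],
        [-u, 0.0, 0.0, -al - params.Dm * ksq],
    ])
    B = np.zeros((4, 4))
    B[0, 1] = params.d
    B[0, 3] = w
    return A, B


@dataclass(frozen=True)
class CharCoefficients:
    """Coefficients of the delay characteristic quartic at one spatial mode."""

    C11: float
    C22: float
    C33: float
    C44: float
    E11: float
    E22: float
    E33: float
    ksq: float = 0.0

    def value(self, lam: complex, tau: float) -> complex:
        """Evaluate the characteristic function at ``lambda``."""
        poly = ((lam + self.C11) * lam + self.C22) * lam**2 + self.C33 * lam + self.C44
        delayed = (self.E11 * lam + self.E22) * lam + self.E33
        return poly + delayed * np.exp(-lam * tau)

    def omega_polynomial(self) -> np.ndarray:
        """Coefficients (descending) of the quartic in z = omega^2.

        Obtained by eliminating the trigonometric terms between the real and
        imaginary parts of the characteristic equation at ``lambda = i omega``.
        """
        C11, C22, C33, C44 = self.C11, self.C22, self.C33, self.C44
        E11, E22, E33 = self.E11, self.E22, self.E33
        return np.array([
            1.0,
            C11**2 - 2.0 * C22,
            C22**2 + 2.0 * C44 - 2.0 * C11 * C33 - E11**2,
            C33**2 + 2.0 * E11 * E33 - 2.0 * C22 * C44 - E22**2,
            C44**2 - E33**2,
        ])


def char_coefficients(
    params: ModelParameters, m2: float = DEFAULT_M2, ksq: float = 0.0
) -> CharCoefficients:
    """Closed-form expansion of ``det(lambda I - A - B exp(-lambda tau))``.

    With diagonal magnitudes ``p1 = eps + DS k^2``, ``p2 = 2d + DD k^2``,
    ``p3 = alpha + Da k^2``, ``p4 = alpha + Dm k^2`` the instantaneous part is
    the product ``(lambda + p1)...(lambda + p4)`` (the off-diagonal couplings
    form no instantaneous cycle), and the delayed part is
    ``(lambda + p3) [ (w u - 2 d eps) lambda + w u (d + DD k^2)
    - 2 d eps (alpha + Dm k^2) ]``, so that ``(lambda + p3)`` divides the
    whole quartic.
    """
    if ksq < 0:
        raise ValueError("ksq must be >= 0")
    _, _, w, u = _e2_ingredients(params, m2)
    wu = w * u
    eps, d, al = params.epsilon, params.d, params.alpha
    p1 = eps + params.DS * ksq
    p2 = 2.0 * d + params.DD * ksq
    p3 = al + params.Da * ksq
    p4 = al + params.Dm * ksq
    C11 = p1 + p2 + p3 + p4
    C22 = p1 * p2 + p1 * p3 + p1 * p4 + p2 * p3 + p2 * p4 + p3 * p4
    C33 = p1 * p2 * p3 + p1 * p2 * p4 + p1 * p3 * p4 + p2 * p3 * p4
    C44 = p1 * p2 * p3 * p4
    e1 = wu - 2.0 * d * eps
    e0 = wu * (d + params.DD * ksq) - 2.0 * d * eps * p4
    return CharCoefficients(
        C11=C11, C22=C22, C33=C33, C44=C44,
        E11=e1, E22=e0 + p3 * e1, E33=p3 * e0, ksq=ksq,
    )


def omega_roots(coeffs: CharCoefficients, real_tol: float = _REAL_TOL,
                pos_tol: float = _POS_TOL) -> list[float]:
    """Positive frequencies of purely imaginary characteristic roots.

    Solves the quartic in ``z = omega^2`` by companion-matrix eigenvalues and
    keeps real roots ``z > pos_tol`` (``|Im z| < real_tol * max(1, |z|)``).
    An empty list means no stability switch exists at this mode.
    """
    roots = np.roots(coeffs.omega_polynomial())
    out = [
        math.sqrt(z.real)
        for z in roots
        if abs(z.imag) < real_tol * max(1.0, abs(z)) and z.real > pos_tol
    ]
    return sorted(out)


def crossing_trig(coeffs: CharCoefficients, omega: float) -> tuple[float, float]:
    """(sin, cos) of ``omega tau`` at a purely imaginary root ``i omega``.

    Obtained by solving the 2x2 linear system formed by the real and
    imaginary parts of the characteristic equation; the pair is unique, which
    fixes the crossing phase mod 2 pi without case distinctions.
    """
    C11, C22, C33, C44 = coeffs.C11, coeffs.C22, coeffs.C33, coeffs.C44
    E11, E22, E33 = coeffs.E11, coeffs.E22, coeffs.E33
    r1 = C22 * omega**2 - C44 - omega**4
    r2 = C33 * omega - C11 * omega**3
    e = E33 - E11 * omega**2
    den = e**2 + (E22 * omega) ** 2
    if den == 0.0:
        raise ZeroDivisionError("degenerate coefficients: E-terms vanish at omega")
    sin = (E22 * omega * r1 + e * r2) / den
    cos = (e * r1 - E22 * omega * r2) / den
    return sin, cos


def critical_delays(coeffs: CharCoefficients, omega: float, j_max: int = 0) -> list[float]:
    """Delay branches ``tau^(j)``, j = 0..j_max, for a crossing frequency.

    ``tau^(j) = (theta + 2 pi j) / omega`` with ``theta = atan2(sin, cos)``
    normalised to [0, 2 pi).
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    sin, cos = crossing_trig(coeffs, omega)
    theta = math.atan2(sin, cos) % (2.0 * math.pi)
    return [(theta + 2.0 * math.pi * j) / omega for j in range(j_max + 1)]


def transversality(coeffs: CharCoefficients, omega: float, tau_c: float) -> int:
    """Sign of ``Re (d lambda / d tau)`` at the crossing (i omega, tau_c).

    Evaluates the real and imaginary parts of numerator and denominator of
    ``(d lambda / d tau)^(-1)`` at the crossing; +1 means the root pair moves
    into the right half-plane (a genuine destabilising Hopf crossing).
    """
    C11, C22, C33 = coeffs.C11, coeffs.C22, coeffs.C33
    E11, E22, E33 = coeffs.E11, coeffs.E22, coeffs.E33
    ct = math.cos(omega * tau_c)
    st = math.sin(omega * tau_c)
    BR = -E22 * omega**2 * ct + (E33 * omega - E11 * omega**3) * st
    BI = (E33 * omega - E11 * omega**3) * ct + E22 * omega**2 * st
    AR = E22 * ct - 3.0 * C11 * omega**2 + 2.0 * E11 * omega * st + C33
    AI = -4.0 * omega**3 + 2.0 * E11 * omega * ct + 2.0 * C22 * omega - E22 * st
    if BR == 0.0 and BI == 0.0:
        raise ZeroDivisionError("degenerate crossing: B-terms vanish")
    value = (AR * BR + AI * BI) / (BR**2 + BI**2)
    return 1 if value > 0 else (-1 if value < 0 else 0)


def neumann_modes(L: float = 100.0, n_max: int = 10) -> list[float]:
    """k^2 = 0 plus the lowest zero-flux mode wavenumbers of an L x L box.

    Modes are ``k^2 = (pi nx / L)^2 + (pi ny / L)^2``; the ``n_max`` smallest
    nonzero values are returned after the homogeneous mode.
    """
    vals = sorted(
        {
            (math.pi * nx / L) ** 2 + (math.pi * ny / L) ** 2
            for nx in range(6)
            for ny in range(6)
        }
        - {0.0}
    )
    return [0.0] + vals[:n_max]


@dataclass(frozen=True)
class Crossing:
    """One purely imaginary crossing of the characteristic equation."""

    ksq: float
    omega: float
    tau: float          # j = 0 branch
    sign: int           # transversality sign


@dataclass(frozen=True)
class HopfResult:
    """Outcome of the critical-delay search over a set of spatial modes."""

    crossings: list[Crossing] = field(default_factory=list)
    tau_c: float | None = None
    omega_at_min: float | None = None
    ksq_at_min: float | None = None

    @property
    def has_hopf(self) -> bool:
        return self.tau_c is not None

    def summary(self) -> str:
        if not self.has_hopf:
            return "no Hopf bifurcation for this parameter set"
        return (
            f"tau_c = {self.tau_c:.4f} yr at omega = {self.omega_at_min:.4f}/yr "
            f"(mode k^2 = {self.ksq_at_min:g}/mm^2)"
        )


def critical_delay(
    params: ModelParameters,
    m2: float = DEFAULT_M2,
    mode_set: list[float] | None = None,
) -> HopfResult:
    """Minimal delay with a destabilising purely imaginary crossing.

    For each squared wavenumber in ``mode_set`` (default: the homogeneous
    mode plus the ten lowest zero-flux modes of the 100 mm domain) all
    positive crossing frequencies and their j = 0 delay branches are
    computed; ``tau_c`` is the smallest branch with positive transversality.
    ``tau_c`` is None when no admissible crossing exists.
    """
    if not e2_stability_at_zero_delay(params, m2):
        raise ValueError("E2 is not stable at tau = 0 for these parameters")
    if mode_set is None:
        mode_set = neumann_modes()
    crossings: list[Crossing] = []
    for ksq in mode_set:
        coeffs = char_coefficients(params, m2, ksq)
        for omega in omega_roots(coeffs):
            tau0 = critical_delays(coeffs, omega, j_max=0)[0]
            sign = transversality(coeffs, omega, tau0)
            crossings.append(Crossing(ksq=ksq, omega=omega, tau=tau0, sign=sign))
    admissible = [c for c in crossings if c.sign > 0]
    if not admissible:
        return HopfResult(crossings=crossings)
    best = min(admissible, key=lambda c: c.tau)
    return HopfResult(
        crossings=crossings,
        tau_c=best.tau,
        omega_at_min=best.omega,
        ksq_at_min=best.ksq,
    )


def characteristic_root(
    coeffs: CharCoefficients,
    tau: float,
    lam0: complex,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> complex:
    """Newton refinement of a characteristic root from the initial guess lam0.

    Used as an independent continuation oracle: starting from the tau = 0
    spectrum (or from ``i omega`` at a crossing) the root can be tracked in
    tau and its real part compared with the transversality prediction.
    """
    lam = complex(lam0)
    for _ in range(max_iter):
        f = coeffs.value(lam, tau)
        # analytic derivative of the characteristic function
        dpoly = (4.0 * lam**3 + 3.0 * coeffs.C11 * lam**2
                 + 2.0 * coeffs.C22 * lam + coeffs.C33)
        q = (coeffs.E11 * lam + coeffs.E22) * lam + coeffs.E33
        dq = 2.0 * coeffs.E11 * lam + coeffs.E22
        df = dpoly + (dq - tau * q) * np.exp(-lam * tau)
        step = f / df
        lam -= step
        if abs(step) < tol * max(1.0, abs(lam)):
            break
    return lam
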