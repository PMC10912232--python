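"""Parameter containers and structured-text configuration.

Two parameter sets drive everything in the package:

* :class:`ModelParameters` -- the kinetic, feedback and transport constants of
  the four-species cancer stem cell (CSC) model: CSC concentration ``S``,
  differentiated cancer cell (DC) concentration ``D``, Wnt-beta catenin
  activator ``a`` and microRNA ``m``.  Time is measured in years, space in
  millimetres, concentrations in cells (or molecules) per cubic millimetre.
* :class:`RadioParameters` -- the linear-quadratic (LQ) radiobiology constants
  used by the fractionated-radiotherapy extension (sensitivities in 1/Gy and
  1/Gy^2, repair constant in 1/year, schedule quantities in years/days).

Both are plain frozen dataclasses; configuration files are YAML mappings whose
keys are exactly the field names.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParameters",
    "RadioParameters",
    "CANCER_PRESETS",
    "for_cancer",
    "load_model_parameters",
    "dump_model_parameters",
]


#: (q0, d) pairs in 1/year for the three cancers considered.
CANCER_PRESETS: dict[str, tuple[float, float]] = {
    "prostate": (87.6, 87.2),
    "lung": (109.97, 80.0),
    "breast": (70.39, 45.0),
}


@dataclass(frozen=True)
class ModelParameters:
    """Rate, feedback and diffusion constants of the CSC model.

    Defaults are the baseline parameter set with the prostate (q0, d) pair.
    ``alpha`` is used throughout as a first-order degradation rate (1/year);
    the source table lists it with a concentration unit, which is treated as a
    typographical slip.
    """

    eta: float = 1.0          # Wnt-beta feedback strength, mm^3/molecule
    psi: float = 0.5          # DC brake on symmetric division, mm^3/cell
    epsilon: float = 1.0      # CSC mitotic rate, 1/year
    q0: float = 87.6          # maximal dedifferentiation rate, 1/year
    m0: float = 0.05          # microRNA threshold concentration, molecule/mm^3
    d: float = 87.2           # DC death rate, 1/year
    alpha: float = 0.3        # degradation rate of a and m, 1/year
    beta: float = 1.0         # Wnt-beta self-renewal aggressiveness, mm^3/(cell*year)
    gamma: float = 1.0        # maximal microRNA production, molecule/(mm^3*year)
    sigma: float = 0.05       # sigmoid width of q(m), molecule/mm^3
    S0: float = 0.038         # CSC reference concentration, cell/mm^3
    DS: float = 0.031536      # CSC diffusivity, mm^2/year
    DD: float = 0.031536      # DC diffusivity, mm^2/year
    Da: float = 0.365         # activator diffusivity, mm^2/year
    Dm: float = 0.365         # microRNA diffusivity, mm^2/year
    tau: float = 0.0          # dedifferentiation delay, years

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"{f.name} must be finite, got {value!r}")
            if f.name == "tau":
                if value < 0:
                    raise ValueError(f"tau must be >= 0, got {value}")
            elif value <= 0:
                raise ValueError(f"{f.name} must be > 0, got {value}")

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def asdict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def for_cancer(name: str, **overrides: float) -> ModelParameters:
    """Baseline parameters with the (q0, d) pair of a named cancer."""
    try:
        q0, d = CANCER_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown cancer {name!r}; available: {sorted(CANCER_PRESETS)}"
        ) from None
    return ModelParameters(q0=q0, d=d).replace(**overrides)


@dataclass(frozen=True)
class RadioParameters:
    """Linear-quadratic radiotherapy parameters.

    ``n`` is the number of dose fractions per day, ``dose_per_fraction`` the
    physical dose per fraction in Gy.  ``tau_r`` (irradiation time of one
    fraction) and ``delta_tau_r`` (interval between fraction starts) are in
    years; ``K`` (repopulation compensation) is in Gy/day and ``T``, ``T_d``
    in days, the units in which these quantities are conventionally quoted.
    ``theta_can`` defaults to ``alpha_s / beta_s``.
    """

    alpha_s: float = 0.302        # single-hit sensitivity, 1/Gy
    beta_s: float = 0.0417        # two-hit sensitivity, 1/Gy^2
    delta: float = 25.0           # radiation kill coupling, 1/(year*Gy)
    mu: float = 3195.77           # sublethal-damage repair rate, 1/year
    dose_per_fraction: float = 0.02   # Gy
    n: int = 2                    # fractions per day
    tau_r: float = 9e-6           # fraction duration, years (~5 min)
    delta_tau_r: float = 6.9e-4   # inter-fraction interval, years (~6.04 h)
    K: float = 0.2                # repopulation dose rate, Gy/day
    T_d: float = 40.0             # repopulation kick-off time, days
    f: float = 1.4                # schedule factor (7/5 for 5 fractions/week)
    theta_late: float = 3.0       # alpha/beta ratio of late-responding tissue, Gy
    theta_can: float | None = None   # alpha/beta ratio of the tumour, Gy
    T: float = 45.0               # overall treatment time, days

    def __post_init__(self) -> None:
        positive = ("alpha_s", "beta_s", "mu", "K", "f", "theta_late",
                    "tau_r", "delta_tau_r")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dose_per_fraction < 0:
            raise ValueError("dose_per_fraction must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("n (fractions per day) must be a positive integer")
        if self.delta_tau_r < self.tau_r:
            raise ValueError("delta_tau_r must be >= tau_r (no overlapping fractions)")
        if self.theta_can is None:
            object.__setattr__(self, "theta_can", self.alpha_s / self.beta_s)
        if self.theta_can <= 0:
            raise ValueError("theta_can must be > 0")

    def replace(self, **changes: Any) -> "RadioParameters":
        if "theta_can" not in changes and changes.keys() & {"alpha_s", "beta_s"}:
            changes["theta_can"] = None
        return replace(self, **changes)

    def asdict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _check_keys(data: dict, cls: type, where: str) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_model_parameters(path: str | Path) -> ModelParameters:
    """Read a YAML mapping of parameter-symbol keys into :class:`ModelParameters`."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    _check_keys(data, ModelParameters, str(path))
    return ModelParameters(**data)


def dump_model_parameters(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.asdict(), sort_keys=False))
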