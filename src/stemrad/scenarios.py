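"""Named presets encoding the published analysis and figure set-ups."""

from __future__ import annotations

from .io import RunConfig
from .parameters import ModelParameters, RadioParameters, for_cancer
from .simulator import SimulationGrid

__all__ = ["builtin_scenarios", "scenario"]

_SLOW = dict(DS=0.0031536, DD=0.0031536, Da=0.0365, Dm=0.0365)
_FAST = dict(DS=0.031536, DD=0.031536, Da=0.365, Dm=0.365)
_TAU_C_PROSTATE = 11.8964   # published prostate critical delay (reference value)


def _grid() -> SimulationGrid:
    return SimulationGrid.from_spacing(L=100.0, dx=0.2)


def _rt(dose: float) -> RadioParameters:
    return RadioParameters(dose_per_fraction=dose, n=2,
                           tau_r=0.000009, delta_tau_r=0.00069)


def builtin_scenarios() -> dict[str, RunConfig]:
    """All presets; pattern runs use the full 100 mm domain at dx = 0.2 mm."""
    prostate = for_cancer("prostate")
    scenarios = {
        # critical-delay analysis inputs (no spatial grid needed)
        "table2_prostate": RunConfig(label="table2_prostate",
                                     model=for_cancer("prostate"), m2=0.08),
        "table2_lung": RunConfig(label="table2_lung",
                                 model=for_cancer("lung"), m2=0.08),
        "table2_breast": RunConfig(label="table2_breast",
                                   model=for_cancer("breast"), m2=0.08),
        # pattern formation at the published delays
        "fig3a": RunConfig(label="fig3a", grid=_grid(), t_end=16.0,
                           model=prostate.replace(tau=_TAU_C_PROSTATE, **_SLOW),
                           record_times=(16.0,)),
        "fig3b": RunConfig(label="fig3b", grid=_grid(), t_end=16.0,
                           model=prostate.replace(tau=_TAU_C_PROSTATE, **_FAST),
                           record_times=(16.0,)),
        "fig4": RunConfig(label="fig4", grid=_grid(), t_end=16.0,
                          model=prostate.replace(tau=6.8964, **_SLOW),
                          record_times=(16.0,)),
        "fig5": RunConfig(label="fig5", grid=_grid(), t_end=16.0,
                          model=prostate.replace(tau=14.8964, **_SLOW),
                          record_times=(16.0,)),
        # radiotherapy time-series and pattern experiments
        "fig7": RunConfig(label="fig7", grid=_grid(), t_end=16.0,
                          model=prostate.replace(tau=6.8964, **_SLOW),
                          radio=_rt(0.02), rt_start=6.8964),
        "fig8": RunConfig(label="fig8", grid=_grid(), t_end=16.0,
                          model=prostate.replace(tau=6.8964, **_SLOW),
                          radio=_rt(0.05), rt_start=6.8964),
        "fig9": RunConfig(label="fig9", grid=_grid(), t_end=16.0,
                          model=prostate.replace(tau=6.8964, **_SLOW),
                          radio=_rt(1.323), rt_start=6.8964),
        "fig10": RunConfig(label="fig10", grid=_grid(), t_end=16.0,
                           model=prostate.replace(tau=6.8964, **_SLOW),
                           radio=_rt(0.02), rt_start=6.8964,
                           record_times=(16.0,)),
        "fig11": RunConfig(label="fig11", grid=_grid(), t_end=16.0,
                           model=prostate.replace(tau=6.8964, **_SLOW),
                           radio=_rt(0.05), rt_start=6.8964,
                           record_times=(16.0,)),
        # TCP curve set-up (volumes 80000 and 250000 mm^3 are CLI inputs)
        "fig6_tcp": RunConfig(label="fig6_tcp", model=prostate,
                              radio=RadioParameters(n=2, T=45.0)),
    }
    return scenarios


def scenario(name: str) -> RunConfig:
    scenarios = builtin_scenarios()
    try:
        return scenarios[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(scenarios)}") from None
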