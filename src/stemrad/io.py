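"""Run configuration and deterministic structured-text output writers."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .parameters import ModelParameters, RadioParameters, _check_keys
from .simulator import SimulationGrid, SimulationResult

__all__ = ["RunConfig", "load_config", "save_config", "write_outputs"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved, serialisable description of one run."""

    label: str = "default"
    model: ModelParameters = field(default_factory=ModelParameters)
    radio: RadioParameters | None = None
    grid: SimulationGrid | None = None
    dt: float = 0.01
    t_end: float = 16.0
    record_times: tuple[float, ...] = ()
    probes: tuple[tuple[int, int], ...] = ()
    m2: float = 0.08
    rt_start: float | None = None     # radiotherapy onset (years), None = untreated
    rt_mode: str = "continuous"

    def to_dict(self) -> dict:
        out: dict = {
            "label": self.label,
            "model": self.model.asdict(),
            "dt": self.dt,
            "t_end": self.t_end,
            "record_times": list(self.record_times),
            "probes": [list(p) for p in self.probes],
            "m2": self.m2,
        }
        if self.radio is not None:
            out["radio"] = self.radio.asdict()
        if self.grid is not None:
            out["grid"] = {"L": self.grid.L, "nx": self.grid.nx, "ny": self.grid.ny}
        if self.rt_start is not None:
            out["rt_start"] = self.rt_start
            out["rt_mode"] = self.rt_mode
        return out

    @classmethod
    def from_dict(cls, data: dict, where: str = "<config>") -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError(f"{where}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
        kwargs: dict = {}
        model = data.get("model", {})
        _check_keys(model, ModelParameters, f"{where}.model")
        kwargs["model"] = ModelParameters(**model)
        if "radio" in data:
            _check_keys(data["radio"], RadioParameters, f"{where}.radio")
            kwargs["radio"] = RadioParameters(**data["radio"])
        if "grid" in data:
            kwargs["grid"] = SimulationGrid(**data["grid"])
        for key in ("label", "dt", "t_end", "m2", "rt_start", "rt_mode"):
            if key in data:
                kwargs[key] = data[key]
        if "record_times" in data:
            kwargs["record_times"] = tuple(float(t) for t in data["record_times"])
        if "probes" in data:
            kwargs["probes"] = tuple(tuple(int(i) for i in p) for p in data["probes"])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Omitted model/radio keys fall back to the baseline defaults; unknown keys
    are rejected with the offending names.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data, where=str(path))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def _write_table(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    rows = np.column_stack(columns)
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")


def write_outputs(result: SimulationResult, out_dir: str | Path,
                  config: RunConfig | None = None) -> list[Path]:
    """Write probe series, snapshots and a metadata sidecar to ``out_dir``.

    Identical configurations produce byte-identical files.  Returns the list
    of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    header = ["t", "S_mean", "D_mean", "a_mean", "m_mean"]
    cols = [result.t] + [result.means[:, i] for i in range(4)]
    for (i, j), values in sorted(result.probes.items()):
        for ci, comp in enumerate("SDam"):
            header.append(f"{comp}_{i}_{j}")
            cols.append(values[:, ci])
    series = out / "series.tsv"
    _write_table(series, header, cols)
    written.append(series)

    for t, snap in sorted(result.snapshots.items()):
        for comp in "SDam":
            fld = np.atleast_2d(np.asarray(getattr(snap, comp), float))
            path = out / f"snapshot_{comp}_t{t:g}.tsv"
            np.savetxt(path, fld, fmt=_FLOAT_FMT, delimiter="\t")
            written.append(path)

    meta: dict = {"tool": "stemrad", "version": __version__}
    if config is not None:
        meta["config"] = config.to_dict()
    elif result.params is not None:
        meta["config"] = {"model": result.params.asdict()}
    if result.warnings:
        meta["warnings"] = list(result.warnings)
    sidecar = out / "metadata.yaml"
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    written.append(sidecar)
    return written
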