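"""Catalogue of ready-made simulation protocols.

Each scenario ships as a TOML data file (diffable, same flat key/value format
as user configs) specifying the full parameter set, numerics, engine options
and, where a protocol is a one-dimensional sweep or a release train, the
sweep/train metadata.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .engine import EngineOptions
from .params import NumericsConfig, SimulationParameters

__all__ = ["Scenario", "list_scenarios", "build_scenario", "scenario_names"]


@dataclass
class Scenario:
    name: str
    description: str
    params: SimulationParameters
    numerics: NumericsConfig
    options: EngineOptions
    protocol: str = "single"            # single | train | random_release
    sweep: dict | None = None           # {"param": ..., "values": [...]}
    frequency_hz: float | None = None
    n_events: int | None = None
    targets: list[str] = field(default_factory=list)

    def to_toml(self) -> str:
        lines = ["[scenario]", f'name = "{self.name}"',
                 f'description = "{self.description}"',
                 f'protocol = "{self.protocol}"']
        if self.frequency_hz is not None:
            lines.append(f"frequency_hz = {self.frequency_hz}")
        if self.n_events is not None:
            lines.append(f"n_events = {self.n_events}")
        if self.targets:
            lines.append("targets = [" + ", ".join(f'"{t}"' for t in self.targets) + "]")
        lines.append("")
        lines.append("[params]")
        for f_ in dataclasses.fields(self.params):
            v = getattr(self.params, f_.name)
            lines.append(f"{f_.name} = {v!r}" if isinstance(v, float) else f"{f_.name} = {v}")
        lines.append("")
        lines.append("[numerics]")
        for f_ in dataclasses.fields(self.numerics):
            v = getattr(self.numerics, f_.name)
            if v is None:
                continue
            lines.append(f"{f_.name} = {v!r}" if isinstance(v, float) else f"{f_.name} = {v}")
        lines.append("")
        lines.append("[engine]")
        for f_ in dataclasses.fields(self.options):
            v = getattr(self.options, f_.name)
            lines.append(f"{f_.name} = {'true' if v else 'false'}")
        if self.sweep:
            lines.append("")
            lines.append("[sweep]")
            lines.append(f'param = "{self.sweep["param"]}"')
            lines.append(f'values = {list(self.sweep["values"])}')
        return "\n".join(lines) + "\n"


def _parse(raw: dict) -> Scenario:
    meta = raw.get("scenario", {})
    return Scenario(
        name=meta.get("name", "unnamed"),
        description=meta.get("description", ""),
        params=SimulationParameters(**raw.get("params", {})),
        numerics=NumericsConfig(**raw.get("numerics", {})),
        options=EngineOptions(**raw.get("engine", {})),
        protocol=meta.get("protocol", "single"),
        sweep=raw.get("sweep"),
        frequency_hz=meta.get("frequency_hz"),
        n_events=meta.get("n_events"),
        targets=list(meta.get("targets", [])),
    )


def _files():
    return resources.files("nanosyn.scenario_data")


def scenario_names() -> list[str]:
    return sorted(p.name[:-5] for p in _files().iterdir() if p.name.endswith(".toml"))


def list_scenarios() -> dict[str, str]:
    """Mapping of scenario name to one-line description."""
    out = {}
    for name in scenario_names():
        out[name] = build_scenario(name).description
    return out


def build_scenario(name: str) -> Scenario:
    """Load one scenario by name; raises with the list of valid names otherwise."""
    path = _files() / f"{name}.toml"
    if not path.is_file():
        raise KeyError(f"unknown scenario {name!r}; valid names: {', '.join(scenario_names())}")
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    sc = _parse(raw)
    sc.name = name
    return sc


def load_scenario_file(path: str | Path) -> Scenario:
    """Parse a scenario/config TOML from an arbitrary path."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return _parse(raw)
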