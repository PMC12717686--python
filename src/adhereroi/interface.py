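"""Configuration I/O, fixture generation, and run metadata.

Config files (JSON or YAML) have two top-level keys:

``parameters``
    Overrides for :class:`~adhereroi.params.ModelParameters` fields.
``scenarios``
    A list of scenario records (:class:`~adhereroi.params.ScenarioConfig`
    fields; ``name`` and ``shape`` required).

Unknown keys anywhere are an error — silent typos in policy configs are
worse than a hard failure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .params import (
    ModelParameters,
    ScenarioConfig,
    default_parameters,
    scenario_table,
    validate,
)

__all__ = ["RunConfig", "load_config", "generate_fixtures", "run_metadata"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


@dataclass
class RunConfig:
    parameters: ModelParameters = field(default_factory=default_parameters)
    scenarios: list[ScenarioConfig] = field(default_factory=scenario_table)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "scenarios": [s.to_dict() for s in self.scenarios],
        }

    def scenario(self, name: str) -> ScenarioConfig:
        """Look up a scenario by (case-insensitive prefix of its) name."""
        needle = name.lower().replace("_", " ")
        for s in self.scenarios:
            if s.name.lower().startswith(needle):
                return s
        raise KeyError(
            f"no scenario named {name!r}; available: "
            + ", ".join(s.name for s in self.scenarios)
        )


def _parse(path: Path) -> dict:
    text = path.read_text()
    if not text.strip():
        return {}
    if path.suffix.lower() == ".json":
        return json.loads(text)
    # YAML is a superset of JSON, so it also covers extensionless files
    data = yaml.safe_load(text)
    return data or {}


def load_config(path) -> RunConfig:
    """Read a JSON/YAML config, merge with defaults, and validate.

    An empty file yields pure defaults. Unknown keys raise a ``ValueError``
    naming the offending key and file.
    """
    path = Path(path)
    data = _parse(path)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    unknown = set(data) - {"parameters", "scenarios"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level key {sorted(unknown)[0]!r}")

    p_over = data.get("parameters") or {}
    bad = set(p_over) - _PARAM_FIELDS
    if bad:
        raise ValueError(f"{path}: unknown parameter key {sorted(bad)[0]!r}")
    params = default_parameters().replace(**p_over)

    scen_records = data.get("scenarios")
    if scen_records is None:
        scenarios = scenario_table()
    else:
        scenarios = []
        for rec in scen_records:
            bad = set(rec) - _SCENARIO_FIELDS
            if bad:
                raise ValueError(f"{path}: unknown scenario key {sorted(bad)[0]!r}")
            scenarios.append(ScenarioConfig(**rec))

    for s in scenarios:
        validate(params, s)
    return RunConfig(parameters=params, scenarios=scenarios)


def generate_fixtures(output_dir) -> list[Path]:
    """Write the canonical scenario-table config and a small smoke-test
    config (coarse design grid, 200 Monte Carlo draws) into ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table2 = out / "table2_scenarios.json"
    table2.write_text(
        json.dumps(RunConfig().to_dict(), indent=2, sort_keys=True) + "\n"
    )

    smoke = out / "smoke.yaml"
    cfg = RunConfig(
        parameters=default_parameters().replace(grid_step=0.05),
        scenarios=scenario_table(),
    )
    smoke.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return [table2, smoke]


def run_metadata(params: ModelParameters, seed: int | None, extra: dict | None = None) -> dict:
    """Sidecar metadata written alongside every CLI output."""
    meta = {
        "package": "adhereroi",
        "version": __version__,
        "seed": seed,
        "grid_step": params.grid_step,
        "parameters": params.to_dict(),
    }
    if extra:
        meta.update(extra)
    return meta
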