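"""Flat key-value run configuration for the screening pipeline.

The config file format is deliberately simple: one ``key = value`` pair per
line, ``#`` comments, a ``schema_version`` guard, and strict rejection of
unknown keys.  Scenario names resolve to complete defaults so a config file
only needs to state deviations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

SCHEMA_VERSION = 1

# Per-scenario defaults: the component count follows the screening protocol
# (six components for pooled dilution/spiked runs, four for in-vivo runs);
# the background-smoothing penalty is matched to each scenario's background
# amplitude and curvature (the near-flat water background tolerates heavy
# smoothing, the strongly curved urine fluorescence needs a gentler one).
_SCENARIO_DEFAULTS = {
    "water_dilution": {"n_components": 6, "smooth_lambda": 1e6},
    "spiked_urine": {"n_components": 6, "smooth_lambda": 1e5},
    "in_vivo": {"n_components": 4, "smooth_lambda": 1e5},
}


@dataclass(frozen=True)
class RunConfig:
    scenario: str = "water_dilution"
    seed: int = 1
    analyte: str = "enrofloxacin"
    n_components: int = 6
    max_iter: int = 500
    tol: float = 1e-6
    snr_threshold: float = 3.0
    window_cm1: float = 8.0
    match_threshold: float = 0.7
    mrl_ppm: float = 100.0
    guard: float = 1.5
    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    smooth_lambda: float = 1e5
    detection_rule: float = 1.0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIO_DEFAULTS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"config schema_version {self.schema_version} != {SCHEMA_VERSION}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable provenance hash of the fully resolved configuration."""
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def write(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")


def default_config(scenario: str, seed: int = 1, **overrides) -> RunConfig:
    if scenario not in _SCENARIO_DEFAULTS:
        raise ValueError(f"unknown scenario {scenario!r}")
    kw = dict(_SCENARIO_DEFAULTS[scenario])
    kw.update(overrides)
    return RunConfig(scenario=scenario, seed=seed, **kw)


_FIELD_TYPES = {f: t for f, t in RunConfig.__annotations__.items()}


def parse_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value config file; unknown keys are rejected."""
    path = Path(path)
    values: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ann = _FIELD_TYPES[key]
        if ann == "int":
            values[key] = int(raw)
        elif ann == "float":
            values[key] = float(raw)
        else:
            values[key] = raw
    scenario = values.pop("scenario", "water_dilution")
    seed = values.pop("seed", 1)
    return default_config(scenario, seed=int(seed), **values)
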