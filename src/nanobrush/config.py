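"""Run configuration: a structured YAML file with validated blocks.

Shipped presets:

* ``desk-flat`` / ``desk-cylinder`` — reduced-scale systems sized for a
  single workstation CPU, used by the test-suite and the acceptance script;
* ``paper-flat`` / ``paper-cylinder`` — the full published protocol
  (100/400 chains of 100 beads, grafting density 0.0625, dt = 0.005 tau,
  Langevin damping 1/tau, 4e6 + 1e6 steps, five replicate seeds).  These are
  cluster-sized jobs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised with the offending key path in the message."""


@dataclass
class RunConfig:
    scale: str
    geometry: dict
    force_field: dict
    population: dict
    integrator: dict
    sweep: dict
    seeds: list[int]

    def as_dict(self) -> dict:
        return {
            "scale": self.scale, "geometry": self.geometry,
            "force_field": self.force_field, "population": self.population,
            "integrator": self.integrator, "sweep": self.sweep,
            "seeds": self.seeds,
        }


PRESETS: dict[str, dict] = {
    "desk-flat": {
        "scale": "desk",
        "geometry": {"kind": "planar_slab", "sigma_g": 0.0625, "Lz": 60.0},
        "force_field": {"sigma_n": 1.0, "eps_b": 1.0, "shift_nm": False},
        "population": {"n_chains": 16, "N": 40, "n_np": 384},
        "integrator": {"T": 1.0, "dt": 0.005, "gamma": 1.0,
                       "n_steps_equil": 80_000, "n_steps_prod": 40_000,
                       "snapshot_stride": 1000, "log_stride": 1000},
        "sweep": {"T": [1.0], "n_np": [384]},
        "seeds": [1, 2, 3, 4, 5],
    },
    "desk-cylinder": {
        "scale": "desk",
        "geometry": {"kind": "cylinder_in_box", "sigma_g": 0.0625,
                     "R": 8.0, "box_pad": 6.0},
        "force_field": {"sigma_n": 1.0, "eps_b": 1.0, "shift_nm": False},
        "population": {"n_chains": 24, "N": 16, "n_np": 120},
        "integrator": {"T": 1.0, "dt": 0.005, "gamma": 1.0,
                       "n_steps_equil": 40_000, "n_steps_prod": 20_000,
                       "snapshot_stride": 1000, "log_stride": 1000},
        "sweep": {"T": [1.0], "n_np": [120]},
        "seeds": [1, 2, 3],
    },
    "paper-flat": {
        "scale": "paper",
        "geometry": {"kind": "planar_slab", "sigma_g": 0.0625, "Lz": 150.0},
        "force_field": {"sigma_n": 1.0, "eps_b": 1.5, "shift_nm": False},
        "population": {"n_chains": 100, "N": 100, "n_np": 3000},
        "integrator": {"T": 1.0, "dt": 0.005, "gamma": 1.0,
                       "n_steps_equil": 4_000_000, "n_steps_prod": 1_000_000,
                       "snapshot_stride": 10_000, "log_stride": 1000},
        "sweep": {"T": [1.0, 1.25, 1.5, 1.75], "n_np": [3000]},
        "seeds": [1, 2, 3, 4, 5],
    },
    "paper-cylinder": {
        "scale": "paper",
        "geometry": {"kind": "cylinder_in_box", "sigma_g": 0.0625,
                     "R": 45.0, "box_pad": 10.0},
        "force_field": {"sigma_n": 1.0, "eps_b": 1.0, "shift_nm": False},
        "population": {"n_chains": 400, "N": 100, "n_np": 30_000},
        "integrator": {"T": 1.0, "dt": 0.005, "gamma": 1.0,
                       "n_steps_equil": 4_000_000, "n_steps_prod": 1_000_000,
                       "snapshot_stride": 10_000, "log_stride": 1000},
        "sweep": {"T": [0.9, 1.0, 1.1], "n_np": [30_000]},
        "seeds": [1, 2, 3, 4, 5],
    },
}

_REQUIRED = {
    "geometry": {"kind", "sigma_g"},
    "force_field": {"sigma_n", "eps_b"},
    "population": {"n_chains", "N", "n_np"},
    "integrator": {"T", "dt", "gamma", "n_steps_equil", "n_steps_prod"},
}

_POSITIVE = [
    ("geometry", "sigma_g"), ("force_field", "sigma_n"),
    ("integrator", "T"), ("integrator", "dt"),
]
_NON_NEGATIVE = [
    ("force_field", "eps_b"), ("integrator", "gamma"),
    ("population", "n_np"), ("population", "n_chains"),
    ("integrator", "n_steps_equil"), ("integrator", "n_steps_prod"),
]


def validate(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    for block, keys in _REQUIRED.items():
        if block not in raw or not isinstance(raw[block], dict):
            raise ConfigError(f"missing or malformed block: {block}")
        for key in keys:
            if key not in raw[block]:
                raise ConfigError(f"missing key: {block}.{key}")
    geom = raw["geometry"]
    if geom["kind"] not in ("planar_slab", "cylinder_in_box"):
        raise ConfigError(f"invalid value: geometry.kind = {geom['kind']!r}")
    if geom["kind"] == "cylinder_in_box" and "R" not in geom:
        raise ConfigError("missing key: geometry.R (required for cylinder)")
    for block, key in _POSITIVE:
        if not raw[block][key] > 0:
            raise ConfigError(f"invalid value: {block}.{key} must be > 0")
    for block, key in _NON_NEGATIVE:
        if raw[block][key] < 0:
            raise ConfigError(f"invalid value: {block}.{key} must be >= 0")
    if raw["population"]["N"] < 1:
        raise ConfigError("invalid value: population.N must be >= 1")
    seeds = raw.get("seeds", [0])
    if not seeds or not all(isinstance(s, int) for s in seeds):
        raise ConfigError("invalid value: seeds must be a non-empty integer list")
    sweep = raw.get("sweep", {})
    sweep.setdefault("T", [raw["integrator"]["T"]])
    sweep.setdefault("n_np", [raw["population"]["n_np"]])
    return RunConfig(
        scale=raw.get("scale", "desk"),
        geometry=copy.deepcopy(geom),
        force_field=copy.deepcopy(raw["force_field"]),
        population=copy.deepcopy(raw["population"]),
        integrator=copy.deepcopy(raw["integrator"]),
        sweep=copy.deepcopy(sweep),
        seeds=list(seeds),
    )


def get_preset(name: str) -> RunConfig:
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return validate(copy.deepcopy(PRESETS[name]))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, dict) and "preset" in raw:
        base = copy.deepcopy(PRESETS.get(raw["preset"]))
        if base is None:
            raise ConfigError(f"unknown preset {raw['preset']!r}")
        for block, val in raw.items():
            if block == "preset":
                continue
            if isinstance(val, dict) and isinstance(base.get(block), dict):
                base[block].update(val)
            else:
                base[block] = val
        raw = base
    return validate(raw)
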