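"""Domain geometry, discretization, parameter loading and reproducibility presets.

The computational domain is a cuboid discretized on a node-centered lattice:
node ``(i, j, k)`` sits at physical position ``index * spacing`` with node
``(0, 0, 0)`` at the domain corner, so ``spacing = extent / (shape - 1)`` per
axis.  The full-size domain is a 10 x 10 x 8 mm cuboid on 201 x 201 x 161
nodes (0.05 mm spacing); smaller presets keep the same spacing.

All model constants live in a :class:`ParameterTable` loaded from the shipped
YAML file, where every value carries a provenance tag (``literature``,
``reconstructed`` or ``fallback``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid domain geometry, unknown presets or bad parameters."""


@dataclass(frozen=True)
class Grid3D:
    """Node-centered cuboid lattice."""

    extent_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.extent_mm) != 3 or len(self.shape) != 3:
            raise ConfigurationError("extent and shape must be length-3")
        if any(e <= 0 for e in self.extent_mm):
            raise ConfigurationError(f"non-positive extent: {self.extent_mm}")
        if any(int(n) < 2 for n in self.shape):
            raise ConfigurationError(f"every axis needs >= 2 nodes, got {self.shape}")
        object.__setattr__(self, "extent_mm", tuple(float(e) for e in self.extent_mm))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return tuple(e / (n - 1) for e, n in zip(self.extent_mm, self.shape))

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def to_dict(self) -> dict[str, Any]:
        return {"extent_mm": list(self.extent_mm), "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Grid3D":
        return cls(tuple(d["extent_mm"]), tuple(d["shape"]))


def build_grid(extent_mm, shape) -> Grid3D:
    """Build a node-centered grid; spacing follows ``extent / (shape - 1)``."""
    return Grid3D(tuple(extent_mm), tuple(shape))


# Parameters that must be strictly positive for the model to make sense.
_STRICTLY_POSITIVE = (
    "phi", "k_ap", "k_ac", "k_qc", "vitality_ch", "energy_ch", "c_ac_ch",
    "c_o2_ch", "c_g_ch", "c_co2_ch", "k_o2_uptake", "k_g_uptake",
    "plasma_viscosity", "hydraulic_conductivity", "Lp_base",
    "ac_half_life_days", "ag_half_life_days",
)


class ParameterTable:
    """Flat table of model constants with per-value provenance.

    Values are attributes (``params.D_o2``); ``params.provenance`` maps each
    name to its origin tag.  Unknown keys are rejected on override to catch
    typos in ``--set`` flags.
    """

    def __init__(self, values: dict[str, float], provenance: dict[str, str]):
        self._values = dict(values)
        self.provenance = dict(provenance)
        self._validate()

    def _validate(self) -> None:
        v = self._values
        for name in _STRICTLY_POSITIVE:
            if v[name] <= 0:
                raise ConfigurationError(f"parameter {name} must be > 0, got {v[name]}")
        for name in v:
            if name.startswith("D_") and v[name] < 0:
                raise ConfigurationError(f"diffusivity {name} must be >= 0")
        if not (0.0 < v["retardation_factor"] <= 1.0):
            raise ConfigurationError("retardation_factor must lie in (0, 1]")

    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["_values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def keys(self):
        return self._values.keys()

    def with_overrides(self, **overrides: float) -> "ParameterTable":
        values = dict(self._values)
        prov = dict(self.provenance)
        for key, val in overrides.items():
            if key not in values:
                raise ConfigurationError(f"unknown parameter: {key!r}")
            values[key] = type(values[key])(val)
            prov[key] = "override"
        return ParameterTable(values, prov)

    def to_dict(self) -> dict[str, Any]:
        return {
            name: {"value": val, "provenance": self.provenance.get(name, "fallback")}
            for name, val in sorted(self._values.items())
        }

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "ParameterTable":
        values, prov = {}, {}
        for name, entry in mapping.items():
            if isinstance(entry, dict):
                values[name] = entry["value"]
                prov[name] = entry.get("provenance", "fallback")
            else:
                values[name] = entry
                prov[name] = "fallback"
        return cls(values, prov)

    @classmethod
    def default(cls) -> "ParameterTable":
        text = (
            importlib.resources.files("tmesim")
            .joinpath("data/parameters.yaml")
            .read_text()
        )
        doc = yaml.safe_load(text)
        return cls.from_mapping(doc["parameters"])

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterTable) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterTable({len(self._values)} parameters)"


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run bit-exactly."""

    grid: Grid3D
    params: ParameterTable
    regimen: str = "none"
    seed: int = 0
    growth_days: float = 36.0
    treatment_days: float = 42.0
    dt_cell_days: float = 0.05
    output_every_steps: int = 10
    preset: str = "custom"
    tumor_seed_radius_mm: float = 0.2

    @property
    def total_days(self) -> float:
        return self.growth_days + self.treatment_days

    def to_dict(self) -> dict[str, Any]:
        return {
            "grid": self.grid.to_dict(),
            "params": self.params.to_dict(),
            "regimen": self.regimen,
            "seed": self.seed,
            "growth_days": self.growth_days,
            "treatment_days": self.treatment_days,
            "dt_cell_days": self.dt_cell_days,
            "output_every_steps": self.output_every_steps,
            "preset": self.preset,
            "tumor_seed_radius_mm": self.tumor_seed_radius_mm,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        return cls(
            grid=Grid3D.from_dict(d["grid"]),
            params=ParameterTable.from_mapping(d["params"]),
            regimen=d.get("regimen", "none"),
            seed=int(d.get("seed", 0)),
            growth_days=float(d.get("growth_days", 36.0)),
            treatment_days=float(d.get("treatment_days", 42.0)),
            dt_cell_days=float(d.get("dt_cell_days", 0.05)),
            output_every_steps=int(d.get("output_every_steps", 10)),
            preset=d.get("preset", "custom"),
            tumor_seed_radius_mm=float(d.get("tumor_seed_radius_mm", 0.2)),
        )

    def serialize(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def parse(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimulationConfig) and self.to_dict() == other.to_dict()
        )


#: Preset geometries.  All share the 0.05 mm node spacing of the full domain.
_PRESETS = {
    # published geometry and protocol: growth to day 36, treatment to day 78
    "full": dict(extent=(10.0, 10.0, 8.0), shape=(201, 201, 161),
                 growth_days=36.0, treatment_days=42.0, seed_radius=0.2),
    # 2 x 2 x 1.6 mm work-desk domain, shortened protocol
    "desk": dict(extent=(2.0, 2.0, 1.6), shape=(41, 41, 33),
                 growth_days=3.0, treatment_days=3.0, seed_radius=0.15),
    # compact domain for end-to-end experiments in test/acceptance budgets
    "mini": dict(extent=(0.8, 0.8, 0.6), shape=(17, 17, 13),
                 growth_days=2.5, treatment_days=8.0, seed_radius=0.12),
    # 9^3 fixture for operation-level tests
    "unit": dict(extent=(0.4, 0.4, 0.4), shape=(9, 9, 9),
                 growth_days=0.5, treatment_days=0.5, seed_radius=0.08),
}


def make_preset(name: str, seed: int = 0, regimen: str = "none") -> SimulationConfig:
    """Return a reproducibility preset: ``full``, ``desk``, ``mini`` or ``unit``."""
    try:
        p = _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return SimulationConfig(
        grid=build_grid(p["extent"], p["shape"]),
        params=ParameterTable.default(),
        regimen=regimen,
        seed=seed,
        growth_days=p["growth_days"],
        treatment_days=p["treatment_days"],
        preset=name,
        tumor_seed_radius_mm=p["seed_radius"],
    )
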