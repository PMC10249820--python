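"""End-to-end driver: the hybrid continuous-discrete simulation loop.

Each macro (cellular) step of ``dt_cell`` days executes, in order:

1. plasma drug concentrations from the treatment schedules;
2. tissue-scale continuum: vascular network flow, interstitial fluid
   pressure and velocity (quasi-steady re-solve);
3. molecular fields advanced by explicit substeps at the stability bound;
4. cellular features and the tumor lattice (vitality, energy, phenotypes,
   migration, division);
5. the endothelial lattice (branching, tip migration, sprout extension);
6. vessel remodeling (shear adaptation, compression collapse, stalk-cell
   death) feeding back into the next continuum solve.

Runs are reproducible: identical config + seed give bit-identical
trajectories.  Checkpoints capture the full state and can seed treatment
comparisons from a shared grown tumor, the protocol used for the
regimen-comparison experiments.
"""

from __future__ import annotations

import copy
import json
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vtkio
from .fields import ReactionContext, ScalarFieldSet, stable_dt, step_species
from .flow import FlowState, solve_ifp, solve_network_flow
from .grid import SimulationConfig
from .metrics import MetricsRecorder, tumor_region_mask
from .treatment import make_schedule
from .tumor import CellLattice, step_tumor
from .vessels import VesselNetwork


@dataclass
class RunManifest:
    """Reproducibility record for one run."""

    config_hash: str
    seed: int
    regimen: str
    start_day: float
    end_day: float
    output_dir: str | None = None
    checkpoint: str | None = None
    metrics_csv: str | None = None
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


class Simulation:
    """Mutable simulation state plus the stepping loop."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.grid = config.grid
        self.params = config.params
        self.rng = np.random.default_rng(config.seed)
        self.fields = ScalarFieldSet.initial(self.grid)
        self.lattice = CellLattice.seeded(self.grid, config.tumor_seed_radius_mm)
        self.network = VesselNetwork(self.grid, self.params)
        self.network.update_perfusion()
        self.flow = FlowState()
        self.schedules = make_schedule(
            config.regimen, self.params,
            start_day=config.growth_days, end_day=config.total_days,
        )
        self.recorder = MetricsRecorder(self.params, self.grid.spacing_mm)
        self.t_days = 0.0
        self.step_index = 0

    # -- plumbing ----------------------------------------------------------
    def set_regimen(self, regimen: str) -> None:
        self.config = self.config.replace(regimen=regimen)
        self.schedules = make_schedule(
            regimen, self.params,
            start_day=self.config.growth_days, end_day=self.config.total_days,
        )

    def plasma_at(self, t: float) -> dict[str, float]:
        p = self.params
        plasma = {"o2": p.c_o2_plasma, "g": p.c_g_plasma, "co2": p.c_co2_plasma,
                  "ac": 0.0, "ag": 0.0}
        for drug, sched in self.schedules.items():
            plasma[drug] = sched.concentration(t)
        return plasma

    def _context(self, plasma: dict[str, float], flow_solved: bool) -> ReactionContext:
        return ReactionContext(
            params=self.params,
            live_mask=self.lattice.live_mask,
            necrotic_mask=self.lattice.necrotic_mask,
            tip_mask=self.network.tip_mask(),
            vessel_mask=self.network.vessel_mask(),
            area_density=self.network.area_density(),
            plasma=plasma,
            transvascular_flux=self.flow.transvascular_flux,
            flow_solved=flow_solved,
        )

    # -- the macro step ----------------------------------------------------
    def step(self) -> None:
        cfg = self.config
        dt_cell = cfg.dt_cell_days

        # tissue-scale continuum (quasi-steady)
        self.flow = solve_network_flow(
            self.network, self.params, fields=self.fields, ifp=self.flow.ifp
        )
        tumor_mask = tumor_region_mask(self.lattice)
        self.flow = solve_ifp(self.fields, self.network, self.flow, self.params,
                              self.grid, tumor_mask)

        # molecular substeps at the stability bound
        dt_sub = stable_dt(self.grid.spacing_mm, self.params, self.flow.velocity)
        n_sub = max(1, math.ceil(dt_cell / dt_sub))
        dt_sub = dt_cell / n_sub
        for k in range(n_sub):
            t = self.t_days + k * dt_sub
            ctx = self._context(self.plasma_at(t), flow_solved=True)
            step_species(self.fields, self.flow.velocity, ctx, dt_sub,
                         step=self.step_index)
            self.recorder.delivery.accumulate(self.fields, self.lattice, dt_sub)

        # tumor lattice (vitality, energy, phenotype, migration, division)
        step_tumor(self.lattice, self.fields, self.rng, dt_cell, self.params,
                   self.grid.spacing_mm[0])

        # endothelial lattice: branching, tip migration, extension
        self.network.step_branching(self.fields, self.rng)
        self.network.step_tips(self.fields, self.lattice, self.rng, dt_cell)

        # remodeling feeds back into the next flow solve
        self.network.remodel(self.lattice, self.fields, self.rng, dt_cell)

        self.t_days += dt_cell
        self.step_index += 1

    def run(self, until_days: float | None = None,
            out_dir: str | Path | None = None) -> RunManifest:
        cfg = self.config
        end = cfg.total_days if until_days is None else until_days
        start = self.t_days
        if self.step_index == 0:
            self.record()
        while self.t_days < end - 1e-9:
            self.step()
            if self.step_index % cfg.output_every_steps == 0:
                self.record()
        if not self.recorder.rows or \
                self.recorder.rows[-1]["time_days"] < self.t_days - 1e-9:
            self.record()
        manifest = RunManifest(
            config_hash=cfg.config_hash(), seed=cfg.seed, regimen=cfg.regimen,
            start_day=start, end_day=self.t_days,
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            csv = out / "metrics.csv"
            self.recorder.to_dataframe().to_csv(csv, index=False)
            ckpt = out / "final.ckpt"
            self.save_checkpoint(ckpt)
            vtkio.write_structured_points(
                out / "fields.vtk",
                {s: self.fields[s] for s in ("o2", "v", "ac")}
                | {"phenotype": self.lattice.phenotype.astype(float)},
                self.grid.spacing_mm,
            )
            vtkio.write_network(out / "network.vtk", self.network,
                                self.grid.spacing_mm)
            manifest.output_dir = str(out)
            manifest.metrics_csv = str(csv)
            manifest.checkpoint = str(ckpt)
            (out / "manifest.json").write_text(manifest.to_json())
        return manifest

    def record(self) -> dict:
        return self.recorder.record(self.t_days, self.fields, self.lattice,
                                    self.flow)

    # -- checkpointing -----------------------------------------------------
    def save_checkpoint(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load_checkpoint(cls, path) -> "Simulation":
        with open(path, "rb") as fh:
            sim = pickle.load(fh)
        if not isinstance(sim, cls):
            raise TypeError("not a simulation checkpoint")
        return sim

    def clone(self) -> "Simulation":
        return copy.deepcopy(self)


def run(config: SimulationConfig, out_dir=None) -> RunManifest:
    """Run a full simulation per the config; returns the manifest."""
    sim = Simulation(config)
    return sim.run(out_dir=out_dir)


def grow_baseline(config: SimulationConfig) -> Simulation:
    """Untreated growth to the treatment start day (the shared checkpoint)."""
    sim = Simulation(config.replace(regimen="none"))
    sim.run(until_days=config.growth_days)
    return sim


def compare_regimens(config: SimulationConfig, regimens=("mtd", "m", "aa+mtd", "aa+m"),
                     seeds=(0, 1, 2), baseline: Simulation | None = None,
                     ) -> pd.DataFrame:
    """Paired-seed regimen comparison from a shared grown-tumor checkpoint.

    For each seed, one untreated tumor is grown to the treatment start day;
    every regimen then continues from an identical copy of that state (same
    RNG stream), so differences are attributable to treatment alone.  Returns
    one row per (regimen, seed) with end-point metrics.
    """
    rows = []
    for seed in seeds:
        if baseline is not None and len(seeds) == 1:
            base = baseline
        else:
            base = grow_baseline(config.replace(seed=int(seed)))
        for regimen in regimens:
            sim = base.clone()
            sim.set_regimen(regimen)
            sim.run()
            endpoint = dict(sim.recorder.rows[-1])
            # tumor IFP compared as its time-average over the treatment window
            window = [
                r["mean_tumor_ifp"] for r in sim.recorder.rows
                if r["time_days"] >= config.growth_days - 1e-9
                and r["mean_tumor_ifp"] == r["mean_tumor_ifp"]
            ]
            endpoint["mean_tumor_ifp_window"] = float(np.mean(window)) if window \
                else float("nan")
            rows.append({"regimen": regimen, "seed": int(seed), **endpoint})
    return pd.DataFrame(rows)


def fold_ratios_vs_aam(comparison: pd.DataFrame) -> dict[str, float]:
    """End-point viable-cell fold ratios relative to the AA+M combination,
    averaged over paired seeds."""
    viable = comparison.groupby("regimen")["viable"].mean()
    ref = max(float(viable.get("aa+m", np.nan)), 1e-30)
    return {
        reg: float(viable[reg]) / ref
        for reg in viable.index if reg != "aa+m"
    }
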