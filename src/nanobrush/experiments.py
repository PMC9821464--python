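"""Experiment orchestration: state-point runs, sweeps, replicate reduction.

A *state point* is one (T, eps_b, sigma_n, n_np) condition; it is simulated
with several independent replicate seeds, each replicate built fresh from a
fully stretched initial configuration, and reduced to a
:class:`~nanobrush.observables.BrushStatePoint` carrying the replicate mean
and standard deviation of the brush height h and solution concentration c.
"""

from __future__ import annotations

import itertools

import numpy as np

from .config import RunConfig
from .engine import IntegratorParams, Trajectory, run
from .force_field import ForceField
from .geometry import Geometry
from .observables import BrushStatePoint, state_point
from .system import ParticleSystem, build_cylinder, build_planar


def derive_seed(base: int, *indices: int) -> int:
    """Deterministic child seed (< 2**31) from a base seed and indices."""
    ss = np.random.SeedSequence([int(base)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def force_field_from_config(cfg: RunConfig) -> ForceField:
    ffb = cfg.force_field
    return ForceField(sigma_n=float(ffb["sigma_n"]), eps_b=float(ffb["eps_b"]),
                      shift_nm=bool(ffb.get("shift_nm", False)))


def integrator_from_config(cfg: RunConfig, T: float, seed: int
                           ) -> IntegratorParams:
    ib = cfg.integrator
    return IntegratorParams(
        dt=float(ib["dt"]), gamma=float(ib["gamma"]), T=float(T),
        seed=int(seed),
        n_steps_equil=int(ib["n_steps_equil"]),
        n_steps_prod=int(ib["n_steps_prod"]),
        snapshot_stride=int(ib.get("snapshot_stride", 1000)),
        log_stride=int(ib.get("log_stride", 1000)),
        skin=float(ib.get("skin", 0.4)),
        dt_equil=(float(ib["dt_equil"]) if ib.get("dt_equil") else None))


def build_from_config(cfg: RunConfig, T: float, n_np: int, seed: int
                      ) -> tuple[ParticleSystem, Geometry]:
    g = cfg.geometry
    p = cfg.population
    sigma_n = float(cfg.force_field["sigma_n"])
    if g["kind"] == "planar_slab":
        return build_planar(
            n_chains=int(p["n_chains"]), N=int(p["N"]),
            sigma_g=float(g["sigma_g"]), n_np=int(n_np), sigma_n=sigma_n,
            Lz=float(g["Lz"]) if "Lz" in g else None, T=T, seed=seed)
    return build_cylinder(
        n_chains=int(p["n_chains"]), N=int(p["N"]),
        sigma_g=float(g["sigma_g"]), R=float(g["R"]), n_np=int(n_np),
        sigma_n=sigma_n, box_pad=float(g.get("box_pad", 10.0)), T=T,
        seed=seed)


def run_replicate(cfg: RunConfig, T: float, n_np: int, seed: int
                  ) -> Trajectory:
    """Build and integrate one replicate of a state point."""
    sys_, geom = build_from_config(cfg, T, n_np, derive_seed(seed, 0))
    ff = force_field_from_config(cfg)
    ip = integrator_from_config(cfg, T, derive_seed(seed, 1))
    return run(sys_, ff, geom, ip)


def run_state_point(cfg: RunConfig, T: float, n_np: int,
                    seeds: list[int] | None = None
                    ) -> tuple[BrushStatePoint, list[Trajectory]]:
    """Run all replicates of one state point and reduce to (h, c)."""
    seeds = cfg.seeds if seeds is None else seeds
    trajs = [run_replicate(cfg, T, n_np, s) for s in seeds]
    ff = force_field_from_config(cfg)
    sp = state_point(trajs, T=T, eps_b=ff.eps_b, sigma_n=ff.sigma_n)
    return sp, trajs


def sweep_conditions(cfg: RunConfig):
    """All (T, n_np) pairs of the configured sweep."""
    return list(itertools.product(cfg.sweep["T"], cfg.sweep["n_np"]))


def run_sweep(cfg: RunConfig) -> list[BrushStatePoint]:
    """Run the whole configured sweep; one BrushStatePoint per condition."""
    return [run_state_point(cfg, T, n_np)[0]
            for T, n_np in sweep_conditions(cfg)]
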