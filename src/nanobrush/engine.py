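"""NVT Langevin dynamics driver and trajectory container.

The integrator is velocity Verlet with a BAOAB-split Langevin thermostat
(damping ``gamma = 1/tau``, time step ``dt = 0.005 tau`` by convention); with
``gamma = 0`` it reduces exactly to NVE velocity Verlet.  A run consists of an
equilibration phase followed by a production phase; snapshots are recorded at
a fixed stride during production only, and a thermodynamic log (instantaneous
temperature and energy components) is kept throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .errors import (BondOverstretchError, GeometryError,
                     IntegrationBlowupError)
from .force_field import ForceField
from .geometry import PLANAR, Geometry
from .system import ParticleSystem


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin NVT parameters in reduced units."""

    dt: float = 0.005
    gamma: float = 1.0
    T: float = 1.0
    seed: int = 0
    n_steps_equil: int = 0
    n_steps_prod: int = 0
    snapshot_stride: int = 1000
    log_stride: int = 1000
    skin: float = 0.4
    #: optional coarser time step for the equilibration phase only (the
    #: equilibrium ensemble does not depend on the path taken to reach it)
    dt_equil: float | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt_equil is not None and self.dt_equil <= 0:
            raise ValueError("dt_equil must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.T <= 0:
            raise ValueError("T must be positive")


@dataclass
class Trajectory:
    """Production snapshots plus the metadata needed for analysis."""

    steps: np.ndarray              # (S,) global step index per snapshot
    positions: np.ndarray          # (S, n, 3)
    species: np.ndarray            # (n,)
    geometry: Geometry
    chains: np.ndarray             # (n_chains, N)
    graft_anchors: np.ndarray      # (n_chains, 3)
    thermo: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]


def _geom_args(geom: Geometry):
    if geom.kind == PLANAR:
        return 0, 0.0, 0.0, 0.0
    cy, cz = geom.axis_center
    return 1, float(geom.R), cy, cz


def _ff_args(ff: ForceField):
    return (
        ff.sigma_m, ff.sigma_n, ff.epsilon, ff.eps_b, ff.delta,
        ff.rc_m ** 2, ff.rc_n ** 2, ff.r_cut_nm ** 2, ff.nm_shift_energy,
        ff.fene_k, ff.fene_r0,
    )


def _list_cutoff(sys_: ParticleSystem, ff: ForceField, skin: float) -> float:
    return ff.max_cutoff(sys_.n_nanoparticles > 0) + skin


def _use_cells(geom: Geometry, cutoff: float, n: int) -> bool:
    if n < 512:
        return False
    per = geom.periodic
    for d in range(3):
        if per[d] and int(geom.box[d] / cutoff) < 3:
            return False
    return True


def neighbor_pairs(sys_: ParticleSystem, geom: Geometry, cutoff: float
                   ) -> np.ndarray:
    """All particle pairs within ``cutoff`` (minimum image), as (m, 2) indices."""
    per = geom.periodic
    box = np.asarray(geom.box, dtype=float)
    use_cells = _use_cells(geom, cutoff, sys_.n_particles)
    c2 = float(cutoff) ** 2
    return K.build_pairs(sys_.positions, sys_.species, box, bool(per[0]),
                         bool(per[1]), bool(per[2]), float(cutoff),
                         c2, c2, c2, use_cells)


def compute_forces(sys_: ParticleSystem, ff: ForceField, geom: Geometry,
                   include_wall: bool = True):
    """Forces and energy components of the current configuration.

    Returns ``(forces, energies)`` with energies a dict of ``pair``, ``bond``,
    ``wall`` terms.  Useful for force-balance checks and as the all-pairs
    reference in tests.
    """
    per = geom.periodic
    box = np.asarray(geom.box, dtype=float)
    cutoff = _list_cutoff(sys_, ff, 0.0) + 1e-9
    pairs = neighbor_pairs(sys_, geom, cutoff)
    f = np.zeros_like(sys_.positions)
    gc, R, cy, cz = _geom_args(geom)
    (sig_m, sig_n, eps, eps_b, delta, rc2_mm, rc2_nn, rc2_nm, shift_e,
     fene_k, fene_r0) = _ff_args(ff)
    e_pair, st1 = K.pair_forces(sys_.positions, sys_.species, pairs, box,
                                bool(per[0]), bool(per[1]), bool(per[2]),
                                sig_m, sig_n, eps, eps_b, delta,
                                rc2_mm, rc2_nn, rc2_nm, shift_e, f)
    e_bond, maxb = K.bond_forces(sys_.positions, sys_.bonds, box,
                                 bool(per[0]), bool(per[1]), bool(per[2]),
                                 fene_k, fene_r0, f)
    e_wall = 0.0
    if include_wall:
        e_wall, st2 = K.wall_forces(sys_.positions, sys_.species, sys_.frozen,
                                    gc, box[2], R, cy, cz, geom.wall_eps,
                                    sig_m, sig_n, f)
    if maxb >= ff.fene_r0:
        raise BondOverstretchError(f"bond length {maxb:.6g} >= r0")
    return f, {"pair": e_pair, "bond": e_bond, "wall": e_wall}


def potential_energy(sys_: ParticleSystem, ff: ForceField, geom: Geometry
                     ) -> float:
    _, e = compute_forces(sys_, ff, geom)
    return e["pair"] + e["bond"] + e["wall"]


def kinetic_energy(sys_: ParticleSystem) -> float:
    v = sys_.velocities[~sys_.frozen]
    return 0.5 * float(np.sum(v * v))


def max_pair_energy(sys_: ParticleSystem, ff: ForceField, geom: Geometry
                    ) -> float:
    per = geom.periodic
    box = np.asarray(geom.box, dtype=float)
    (sig_m, sig_n, eps, eps_b, delta, rc2_mm, rc2_nn, rc2_nm, shift_e,
     _, _) = _ff_args(ff)
    return K.max_pair_energy_kernel(sys_.positions, sys_.species, box,
                                    bool(per[0]), bool(per[1]), bool(per[2]),
                                    sig_m, sig_n, eps, eps_b, delta,
                                    rc2_mm, rc2_nn, rc2_nm, shift_e)


_STATUS_MSG = {
    K.BOND_OVERSTRETCH: "FENE bond reached its maximum extension r0",
    K.CORE_BREACH: "hard-core breach (particle inside a repulsive core or wall)",
    K.NON_FINITE: "non-finite coordinate",
}


def _advance(sys_: ParticleSystem, ff: ForceField, geom: Geometry,
             ip: IntegratorParams, n_steps: int, seed: int, step0: int,
             snap_stride: int, dt: float | None = None):
    """Integrate ``n_steps`` in place; return (snaps, snap_steps, log)."""
    per = geom.periodic
    box = np.asarray(geom.box, dtype=float)
    gc, R, cy, cz = _geom_args(geom)
    ffa = _ff_args(ff)
    cutoff = _list_cutoff(sys_, ff, ip.skin)
    max_rc = ff.max_cutoff(sys_.n_nanoparticles > 0)
    for d in range(3):
        if per[d] and box[d] < 2.0 * max_rc:
            raise GeometryError(
                f"periodic box length {box[d]:.3g} along axis {d} is below "
                f"twice the interaction cutoff {max_rc:.3g}: the minimum-"
                "image convention would miss interactions")
    use_cells = _use_cells(geom, cutoff, sys_.n_particles)

    n_snap = n_steps // snap_stride if snap_stride > 0 else 0
    snaps = np.zeros((n_snap, sys_.n_particles, 3))
    snap_steps = np.zeros(n_snap, dtype=np.int64)
    n_log = n_steps // ip.log_stride if ip.log_stride > 0 else 0
    log = np.zeros((n_log, 5))

    lc2_mm = (ff.rc_m + ip.skin) ** 2
    lc2_nn = (ff.rc_n + ip.skin) ** 2
    lc2_nm = (ff.r_cut_nm + ip.skin) ** 2
    status, step = K.run_langevin(
        sys_.positions, sys_.velocities, sys_.species, sys_.frozen,
        sys_.bonds, box, bool(per[0]), bool(per[1]), bool(per[2]),
        gc, R, cy, cz, geom.wall_eps, *ffa,
        (ip.dt if dt is None else dt), ip.gamma, ip.T, n_steps, seed, step0,
        snap_stride, snaps, snap_steps,
        ip.log_stride, log, cutoff, lc2_mm, lc2_nn, lc2_nm, ip.skin,
        use_cells)
    if status == K.BOND_OVERSTRETCH:
        raise BondOverstretchError(f"at step {step}: {_STATUS_MSG[status]}")
    if status != K.OK:
        raise IntegrationBlowupError(f"at step {step}: {_STATUS_MSG[status]}",
                                     step=step)
    return snaps, snap_steps, log


def _phase_seeds(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    a, b = ss.generate_state(2)
    return int(a % (2**31 - 1)), int(b % (2**31 - 1))


def step(sys_: ParticleSystem, ff: ForceField, geom: Geometry,
         ip: IntegratorParams) -> ParticleSystem:
    """One integration step; returns an updated copy of the system."""
    out = sys_.copy()
    s_eq, _ = _phase_seeds(ip.seed)
    _advance(out, ff, geom, ip, 1, s_eq, 0, 0)
    return out


def run(sys_: ParticleSystem, ff: ForceField, geom: Geometry,
        ip: IntegratorParams) -> Trajectory:
    """Equilibrate then produce; snapshots recorded during production only.

    The input system is not modified.  Two runs with identical inputs and
    seeds produce identical snapshot streams.
    """
    work = sys_.copy()
    s_eq, s_pr = _phase_seeds(ip.seed)
    logs = []
    if ip.n_steps_equil > 0:
        _, _, log_eq = _advance(work, ff, geom, ip, ip.n_steps_equil,
                                s_eq, 0, 0, dt=ip.dt_equil)
        logs.append(log_eq)
    snaps, snap_steps, log_pr = _advance(
        work, ff, geom, ip, ip.n_steps_prod, s_pr, ip.n_steps_equil,
        ip.snapshot_stride if ip.n_steps_prod > 0 else 0)
    logs.append(log_pr)
    log = np.vstack(logs) if logs else np.zeros((0, 5))
    thermo = pd.DataFrame(
        log, columns=["step", "T_inst", "E_pair", "E_bond", "E_wall"])
    thermo["step"] = thermo["step"].astype(np.int64)
    anchors_now = (work.positions[work.chains[:, 0]]
                   if work.chains.size else np.zeros((0, 3)))
    # graft anchors must not have moved during the run
    if work.chains.size:
        drift = np.abs(anchors_now - sys_.graft_anchors).max()
        if drift > 0:
            raise IntegrationBlowupError(f"graft anchors moved by {drift:.3g}")
    return Trajectory(
        steps=snap_steps, positions=snaps, species=work.species.copy(),
        geometry=geom, chains=work.chains.copy(),
        graft_anchors=sys_.graft_anchors.copy(), thermo=thermo)


def final_state(sys_: ParticleSystem, ff: ForceField, geom: Geometry,
                ip: IntegratorParams) -> ParticleSystem:
    """Integrate equilibration + production and return the final system state."""
    work = sys_.copy()
    s_eq, s_pr = _phase_seeds(ip.seed)
    if ip.n_steps_equil > 0:
        _advance(work, ff, geom, ip, ip.n_steps_equil, s_eq, 0, 0,
                 dt=ip.dt_equil)
    if ip.n_steps_prod > 0:
        _advance(work, ff, geom, ip, ip.n_steps_prod, s_pr,
                 ip.n_steps_equil, 0)
    return work
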