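"""Initial-configuration builders.

Chains start fully stretched away from the grafting surface (bond length
0.97 sigma_m, near the minimum of the combined FENE + WCA bond energy), which
keeps the system from starting in a metastable entangled state.  Grafting
points are drawn by random sequential insertion with a minimum separation of
one monomer diameter.  Nanoparticles are inserted at random in the solution
region (above the stretched chains in the slab; outside the cylinder in the
pore geometry) without overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, PackingError
from .force_field import MONOMER, NANOPARTICLE, ForceField
from .geometry import CYLINDER, PLANAR, Geometry

#: Initial bond length for stretched chains (near the FENE+WCA minimum).
BOND0 = 0.97

#: Retry budget for random sequential insertion.
MAX_INSERT_TRIES = 1_000_000


@dataclass
class ParticleSystem:
    """Positions, velocities, species, chain topology and graft anchors.

    Monomers are listed first, chain by chain (each chain contiguous, bead 0
    at the graft anchor), followed by nanoparticles.  Bead 0 of every chain
    is frozen: it is never integrated or thermostatted.
    """

    positions: np.ndarray          # (n, 3)
    velocities: np.ndarray         # (n, 3)
    species: np.ndarray            # (n,) int8, MONOMER or NANOPARTICLE
    chains: np.ndarray             # (n_chains, N) int32 indices into positions
    graft_anchors: np.ndarray      # (n_chains, 3)
    frozen: np.ndarray             # (n,) bool

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def chain_length(self) -> int:
        return self.chains.shape[1] if self.chains.size else 0

    @property
    def n_monomers(self) -> int:
        return int(np.sum(self.species == MONOMER))

    @property
    def n_nanoparticles(self) -> int:
        return int(np.sum(self.species == NANOPARTICLE))

    @property
    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) adjacent-bead index pairs across all chains."""
        if self.chains.size == 0 or self.chain_length < 2:
            return np.zeros((0, 2), dtype=np.int32)
        left = self.chains[:, :-1].ravel()
        right = self.chains[:, 1:].ravel()
        return np.stack([left, right], axis=1).astype(np.int32)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(), self.velocities.copy(), self.species.copy(),
            self.chains.copy(), self.graft_anchors.copy(), self.frozen.copy(),
        )


def maxwell_boltzmann_velocities(n, T, frozen, rng) -> np.ndarray:
    """Gaussian velocities at temperature T (m = kB = 1); frozen rows zeroed."""
    v = rng.normal(0.0, np.sqrt(T), size=(n, 3))
    v[frozen] = 0.0
    return v


def _insert_with_min_sep(rng, n, sample, min_sep, geom: Geometry, what: str):
    """Random sequential insertion of n points with a minimum pair separation."""
    pts = np.zeros((n, 3))
    placed = 0
    tries = 0
    min_sep2 = min_sep * min_sep
    box = np.asarray(geom.box)
    per = geom.periodic
    while placed < n:
        if tries >= MAX_INSERT_TRIES:
            raise PackingError(
                f"could not place {n} {what} with separation {min_sep} "
                f"after {tries} tries"
            )
        tries += 1
        cand = sample()
        dr = cand[None, :] - pts[:placed]
        for d in range(3):
            if per[d]:
                dr[:, d] -= box[d] * np.round(dr[:, d] / box[d])
        if placed and float(np.min(np.einsum("ij,ij->i", dr, dr))) < min_sep2:
            continue
        pts[placed] = cand
        placed += 1
    return pts


def build_planar(
    n_chains: int,
    N: int,
    sigma_g: float = 0.0625,
    n_np: int = 0,
    sigma_n: float = 1.0,
    Lz: float | None = None,
    T: float = 1.0,
    seed: int = 0,
    wall_eps: float = 1.0,
) -> tuple[ParticleSystem, Geometry]:
    """Plane-grafted brush in a slab with walls at z=0 and z=Lz.

    The lateral box size follows from the grafting density:
    ``Lx = Ly = sqrt(n_chains / sigma_g)``.  ``Lz`` defaults to ``1.5*N`` so
    the stretched initial chains fit and a solution reservoir remains above
    the brush.
    """
    if n_chains < 0 or N < 1 or n_np < 0:
        raise ValueError("counts must be non-negative (N >= 1)")
    rng = np.random.default_rng(seed)
    if n_chains > 0:
        L = float(np.sqrt(n_chains / sigma_g))
    else:
        L = float(np.sqrt(max(n_np, 1)))  # chain-free box: arbitrary square side
    if Lz is None:
        Lz = 1.5 * N if n_chains > 0 else L  # chain-free: cubic gas box
    chain_top = BOND0 * (N - 1)
    if n_chains > 0 and Lz < chain_top + 2.0:
        raise GeometryError(
            f"Lz = {Lz} cannot hold stretched chains of extent {chain_top:.3g}"
        )
    geom = Geometry(kind=PLANAR, box=(L, L, float(Lz)), sigma_g=sigma_g,
                    wall_eps=wall_eps)

    def sample_graft():
        return np.array([rng.uniform(0, L), rng.uniform(0, L), 0.0])

    anchors = _insert_with_min_sep(rng, n_chains, sample_graft, 1.0, geom,
                                   "graft points")

    n_mono = n_chains * N
    n_total = n_mono + n_np
    pos = np.zeros((n_total, 3))
    species = np.zeros(n_total, dtype=np.int8)
    species[n_mono:] = NANOPARTICLE
    chains = np.arange(n_mono, dtype=np.int32).reshape(n_chains, N) \
        if n_chains else np.zeros((0, N), dtype=np.int32)
    frozen = np.zeros(n_total, dtype=bool)

    for c in range(n_chains):
        idx = chains[c]
        pos[idx] = anchors[c]
        pos[idx, 2] = BOND0 * np.arange(N)
        frozen[idx[0]] = True

    # nanoparticles: uniform in the reservoir above the stretched chains
    z_lo = (chain_top + max(1.0, sigma_n)) if n_chains else max(1.0, sigma_n)
    z_hi = Lz - max(1.0, sigma_n)
    if n_np > 0:
        if z_hi <= z_lo:
            raise GeometryError("no solution region above the chains for nanoparticles")

        def sample_np():
            return np.array([
                rng.uniform(0, L), rng.uniform(0, L), rng.uniform(z_lo, z_hi)
            ])

        pos[n_mono:] = _insert_with_min_sep(rng, n_np, sample_np, sigma_n, geom,
                                            "nanoparticles")

    vel = maxwell_boltzmann_velocities(n_total, T, frozen, rng)
    anchors_arr = anchors if n_chains else np.zeros((0, 3))
    sys_ = ParticleSystem(pos, vel, species, chains, anchors_arr, frozen)
    return sys_, geom


def build_cylinder(
    n_chains: int,
    N: int,
    sigma_g: float = 0.0625,
    R: float = 45.0,
    n_np: int = 0,
    sigma_n: float = 1.0,
    box_pad: float = 10.0,
    T: float = 1.0,
    seed: int = 0,
    wall_eps: float = 1.0,
) -> tuple[ParticleSystem, Geometry]:
    """Inside-grafted cylindrical brush immersed in a fully periodic box.

    The cylinder length along x follows from the grafting density:
    ``L_cyl = n_chains / (sigma_g * 2 pi R)``; the box cross-section is
    ``2R + 2*box_pad`` so a solution annulus surrounds the (nanoparticle-
    permeable) cylinder surface.  Chains start stretched along the inward
    radial direction; beads that would overshoot the axis continue along the
    axis direction with a small transverse jitter.
    """
    if n_chains < 1 or N < 1 or n_np < 0:
        raise ValueError("cylinder build requires n_chains >= 1, N >= 1, n_np >= 0")
    rng = np.random.default_rng(seed)
    L_cyl = n_chains / (sigma_g * 2.0 * np.pi * R)
    side = 2.0 * R + 2.0 * box_pad
    geom = Geometry(kind=CYLINDER, box=(float(L_cyl), side, side), sigma_g=sigma_g,
                    R=R, wall_eps=wall_eps)
    cy, cz = geom.axis_center

    def sample_graft():
        th = rng.uniform(0, 2 * np.pi)
        return np.array([
            rng.uniform(0, L_cyl), cy + R * np.cos(th), cz + R * np.sin(th)
        ])

    anchors = _insert_with_min_sep(rng, n_chains, sample_graft, 1.0, geom,
                                   "graft points")

    n_mono = n_chains * N
    n_total = n_mono + n_np
    pos = np.zeros((n_total, 3))
    species = np.zeros(n_total, dtype=np.int8)
    species[n_mono:] = NANOPARTICLE
    chains = np.arange(n_mono, dtype=np.int32).reshape(n_chains, N)
    frozen = np.zeros(n_total, dtype=bool)

    # Chains start stretched along the inward radial direction.  Straight
    # rays converge near the axis, so each chain folds into a radial
    # zigzag: inward ray to rho_stop (chosen so the combined ray density
    # stays physical), an axial U-turn step, an outward ray to R-1, and so
    # on.  Any bead whose deterministic position would clash with already
    # placed beads falls back to a bonded random-walk step.
    rho_stop = max(0.5, n_chains / (2.0 * np.pi * L_cyl * BOND0 * 0.7))
    if rho_stop > 0.8 * R:
        raise GeometryError(
            "cylinder too short for stretched starts: ray density near the "
            "axis would be unphysical")
    placed = np.zeros((n_mono, 3))
    state = {"n": 0, "rng": rng}  # beads committed so far; layout RNG stream

    def _too_close(p, min_sep):
        if state["n"] == 0:
            return False
        dr = p[None, :] - placed[: state["n"]]
        dr[:, 0] -= L_cyl * np.round(dr[:, 0] / L_cyl)
        return bool(np.min(np.einsum("ij,ij->i", dr, dr)) < min_sep**2)

    def _cart(x, rho, theta):
        return np.array([x, cy + rho * np.cos(theta), cz + rho * np.sin(theta)])

    def _walk_step(p, tries):
        """Bonded random-walk step avoiding placed beads; None if stuck."""
        for attempt in range(tries):
            d = state["rng"].normal(size=3)
            d *= BOND0 / np.linalg.norm(d)
            cand = p + d
            if np.hypot(cand[1] - cy, cand[2] - cz) > R - 0.9:
                continue
            if not _too_close(cand, 0.85 if attempt < tries // 2 else 0.8):
                return cand
        return None

    def _try_place_chain(idx, a):
        """One attempt at laying out a chain; returns False when jammed.

        All graft anchors are pre-seeded into ``placed`` (indices
        0..n_chains-1), so candidates are checked against chains not yet
        laid out as well.
        """
        theta = float(np.arctan2(a[2] - cz, a[1] - cy))
        x, rho, radial_dir = float(a[0]), float(R), -1.0
        # per-chain turn radii spread the zigzag strands over the whole
        # annulus so no radial band saturates
        rho_in = rho_stop + state["rng"].uniform(
            0.0, max(0.0, 0.55 * R - rho_stop))
        rho_out = R - 1.0 - state["rng"].uniform(0.0, 0.25 * R)
        rho_out = max(rho_out, rho_in + 2.0 * BOND0)
        p = a.copy()
        pos[idx[0]] = p
        backtracks = 0
        j = 1
        while j < N:
            cand_rho = rho + radial_dir * BOND0
            if (radial_dir < 0 and cand_rho < rho_in) or \
                    (radial_dir > 0 and cand_rho > rho_out):
                cand = _cart(x + BOND0, rho, theta)  # axial U-turn step
                flip = True
            else:
                cand = _cart(x, cand_rho, theta)
                flip = False
            if _too_close(cand, 0.85):
                flip = False
                # blocked: shift to a neighbouring axial lane (only while
                # clear of the wall), else take a bonded random-walk step;
                # back up a few beads when stuck
                lane_ok = False
                if rho <= R - 0.9:
                    for lane in (1.0, -1.0):
                        cand = _cart(x + lane * BOND0, rho, theta)
                        if not _too_close(cand, 0.85):
                            lane_ok = True
                            break
                if not lane_ok:
                    cand = _walk_step(p, 600)
                    if cand is None:
                        nback = min(6, j - 1)
                        if nback == 0 or backtracks >= 300:
                            state["n"] -= j - 1  # roll the chain back
                            return False
                        backtracks += 1
                        j -= nback
                        state["n"] -= nback
                        p = pos[idx[j - 1]].copy()
                        x = float(p[0])
                        rho = float(np.hypot(p[1] - cy, p[2] - cz))
                        theta = float(np.arctan2(p[2] - cz, p[1] - cy))
                        continue
            if flip:
                radial_dir = -radial_dir
            p = cand
            x = float(p[0])
            rho = float(np.hypot(p[1] - cy, p[2] - cz))
            theta = float(np.arctan2(p[2] - cz, p[1] - cy))
            pos[idx[j]] = p
            placed[state["n"]] = p
            state["n"] += 1
            j += 1
        return True

    # Greedy sequential placement can occasionally jam late in a crowded
    # layout; retry the whole layout with a fresh (seed-derived) stream.
    for layout_attempt in range(8):
        state["rng"] = np.random.default_rng(rng.integers(2**63))
        if layout_attempt >= 4:
            # a rare anchor constellation can jam every layout; redraw it
            anchors = _insert_with_min_sep(state["rng"], n_chains,
                                           sample_graft, 1.0, geom,
                                           "graft points")
        # all anchors are obstacles from the start (chains are laid
        # sequentially but must avoid chains not yet placed)
        placed[:n_chains] = anchors
        state["n"] = n_chains
        ok = True
        for c in range(n_chains):
            for _ in range(20):
                if _try_place_chain(chains[c], anchors[c]):
                    break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise PackingError("could not fold the chains inside the cylinder")
    for c in range(n_chains):
        frozen[chains[c][0]] = True
    pos[:n_mono] = geom.wrap(pos[:n_mono])

    if n_np > 0:
        # clearance past the anchors sitting exactly on the wall surface
        rho_min = R + 0.5 * (sigma_n + 1.0) + 0.1
        if rho_min >= side / 2.0 - sigma_n:
            raise GeometryError("box_pad too small to hold nanoparticles outside R")

        def sample_np():
            while True:
                p = np.array([
                    rng.uniform(0, L_cyl),
                    rng.uniform(0, side),
                    rng.uniform(0, side),
                ])
                if np.hypot(p[1] - cy, p[2] - cz) > rho_min:
                    return p

        pos[n_mono:] = _insert_with_min_sep(rng, n_np, sample_np, sigma_n, geom,
                                            "nanoparticles")

    vel = maxwell_boltzmann_velocities(n_total, T, frozen, rng)
    sys_ = ParticleSystem(pos, vel, species, chains, anchors, frozen)
    return sys_, geom


def build_wall(geom: Geometry, ff: ForceField) -> dict:
    """Describe the confining-wall interactions of a geometry.

    Planar slabs repel both species at z = 0 and z = Lz through the purely
    repulsive WCA form acting on the distance to the wall (length scale: the
    species' own diameter).  The cylindrical surface repels monomers only
    and is transparent to nanoparticles (permeable wall).  The returned
    description is what the engine's wall kernel implements.
    """
    from .geometry import CYLINDER, PLANAR
    from .force_field import RC_WCA
    if geom.kind == PLANAR:
        return {
            "kind": "planar_pair_of_walls",
            "positions_z": (0.0, geom.box[2]),
            "form": "wca_on_distance",
            "acts_on": {"monomer": ff.sigma_m, "nanoparticle": ff.sigma_n},
            "cutoffs": {"monomer": RC_WCA * ff.sigma_m,
                        "nanoparticle": RC_WCA * ff.sigma_n},
            "epsilon": geom.wall_eps,
        }
    return {
        "kind": "cylindrical_surface",
        "R": geom.R,
        "form": "wca_on_distance_inside",
        "acts_on": {"monomer": ff.sigma_m},
        "cutoffs": {"monomer": RC_WCA * ff.sigma_m},
        "permeable_to": ["nanoparticle"],
        "epsilon": geom.wall_eps,
    }


def check_overlaps(sys_: ParticleSystem, ff: ForceField, geom: Geometry,
                   threshold: float = 50.0) -> float:
    """Return the largest non-bonded pair energy; raise if above threshold.

    Used as a post-build sanity check that random insertion produced a
    mechanically safe starting state.
    """
    from .engine import max_pair_energy  # deferred: engine imports this module

    worst = max_pair_energy(sys_, ff, geom)
    if worst > threshold:
        raise PackingError(
            f"initial configuration has pair energy {worst:.3g} > {threshold}"
        )
    return worst
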