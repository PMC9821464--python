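"""Trajectory and table I/O.

Two plain-text trajectory dialects are supported, both written with 17
significant digits so a write/read cycle reproduces coordinates bit-for-bit:

* species-tagged XYZ (element symbols ``M`` monomer, ``N`` nanoparticle);
* a LAMMPS-dump-compatible dialect
  (``ITEM: TIMESTEP / NUMBER OF ATOMS / BOX BOUNDS pp pp ff|pp / ATOMS id
  type x y z``, types 1 = monomer, 2 = nanoparticle).

Tables (thermodynamic logs, profiles, h–c diagrams) are tab-separated text
with ``#``-prefixed provenance headers.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .force_field import MONOMER, NANOPARTICLE
from .geometry import CYLINDER, PLANAR, Geometry
from .engine import Trajectory

_XYZ_TAG = {MONOMER: "M", NANOPARTICLE: "N"}
_XYZ_CODE = {"M": MONOMER, "N": NANOPARTICLE, "W": 2}
_DUMP_TYPE = {MONOMER: 1, NANOPARTICLE: 2}

_F = "{:.17g}"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(**meta) -> str:
    lines = [f"# nanobrush {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_xyz(path, traj: Trajectory) -> None:
    tags = [_XYZ_TAG[int(s)] for s in traj.species]
    with open(path, "w") as fh:
        for fr in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            box = " ".join(_F.format(b) for b in traj.geometry.box)
            fh.write(f'step={traj.steps[fr]} box="{box}"\n')
            for i, tag in enumerate(tags):
                x, y, z = traj.positions[fr, i]
                fh.write(f"{tag} {_F.format(x)} {_F.format(y)} {_F.format(z)}\n")


def read_xyz(path):
    """Read a species-tagged XYZ file -> (steps, box, species, positions)."""
    steps, frames = [], []
    species = None
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k].strip())
        comment = lines[k + 1]
        step = 0
        for tok in comment.split():
            if tok.startswith("step="):
                step = int(tok[5:])
            if tok.startswith('box="'):
                rest = comment.split('box="', 1)[1].split('"', 1)[0]
                box = tuple(float(x) for x in rest.split())
        steps.append(step)
        sp, pos = [], []
        for row in lines[k + 2: k + 2 + n]:
            tag, x, y, z = row.split()
            sp.append(_XYZ_CODE[tag])
            pos.append((float(x), float(y), float(z)))
        if species is None:
            species = np.array(sp, dtype=np.int8)
        frames.append(np.array(pos))
        k += 2 + n
    return (np.array(steps, dtype=np.int64), box, species,
            np.array(frames))


def write_lammps_dump(path, traj: Trajectory) -> None:
    geom = traj.geometry
    flags = "pp pp ff" if geom.kind == PLANAR else "pp pp pp"
    with open(path, "w") as fh:
        for fr in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{traj.steps[fr]}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n_particles}\n")
            fh.write(f"ITEM: BOX BOUNDS {flags}\n")
            for b in geom.box:
                fh.write(f"0 {_F.format(b)}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i in range(traj.n_particles):
                x, y, z = traj.positions[fr, i]
                fh.write(f"{i + 1} {_DUMP_TYPE[int(traj.species[i])]} "
                         f"{_F.format(x)} {_F.format(y)} {_F.format(z)}\n")


def read_lammps_dump(path):
    """Read the dump dialect -> (steps, box, periodic_flags, species, positions)."""
    steps, frames = [], []
    species = None
    box = None
    flags = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        assert lines[k].startswith("ITEM: TIMESTEP")
        steps.append(int(lines[k + 1]))
        assert lines[k + 2].startswith("ITEM: NUMBER OF ATOMS")
        n = int(lines[k + 3])
        assert lines[k + 4].startswith("ITEM: BOX BOUNDS")
        flags = lines[k + 4].split("BOX BOUNDS", 1)[1].split()
        bounds = [lines[k + 5 + d].split() for d in range(3)]
        box = tuple(float(b[1]) - float(b[0]) for b in bounds)
        assert lines[k + 8].startswith("ITEM: ATOMS")
        sp = np.zeros(n, dtype=np.int8)
        pos = np.zeros((n, 3))
        for row in lines[k + 9: k + 9 + n]:
            iid, typ, x, y, z = row.split()
            i = int(iid) - 1
            sp[i] = MONOMER if int(typ) == 1 else NANOPARTICLE
            pos[i] = (float(x), float(y), float(z))
        species = sp
        frames.append(pos)
        k += 9 + n
    periodic = tuple(f == "pp" for f in flags)
    return (np.array(steps, dtype=np.int64), box, periodic, species,
            np.array(frames))


def trajectory_from_dump(path, sigma_g: float, n_chains: int, N: int,
                         R: float | None = None) -> Trajectory:
    """Rebuild an analyzable Trajectory from a dump file plus topology counts.

    Monomers are assumed contiguous and chain-ordered (the builder's layout);
    graft anchors are taken from the first frame's chain-head positions,
    which are frozen during dynamics.
    """
    steps, box, periodic, species, frames = read_lammps_dump(path)
    kind = PLANAR if not periodic[2] else CYLINDER
    geom = Geometry(kind=kind, box=box, sigma_g=sigma_g, R=R)
    chains = (np.arange(n_chains * N, dtype=np.int32).reshape(n_chains, N)
              if n_chains else np.zeros((0, N), dtype=np.int32))
    anchors = (frames[0][chains[:, 0]] if n_chains
               else np.zeros((0, 3)))
    return Trajectory(steps=steps, positions=frames, species=species,
                      geometry=geom, chains=chains, graft_anchors=anchors,
                      thermo=pd.DataFrame())


def write_table(path, df: pd.DataFrame, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(**meta))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_profile(path, profile, **meta) -> None:
    df = pd.DataFrame({
        "bin_lo": profile.bin_edges[:-1],
        "bin_hi": profile.bin_edges[1:],
        "value": profile.values,
    })
    write_table(path, df, mode=profile.mode,
                normalization_constant=profile.normalization_constant, **meta)
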