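"""Interaction model for the bead–spring brush / nanoparticle system.

All quantities are expressed in reduced Lennard-Jones units
(``sigma_m = epsilon = m = kB = 1``; time unit ``tau = sigma*(m/epsilon)**0.5``).

Three interactions define the model:

* ``u_mm`` — a truncated-and-shifted (WCA-type) Lennard-Jones repulsion
  between all monomer pairs, cut at ``rc_m = 2**(1/6)*sigma_m`` so it is
  purely repulsive.  Nanoparticle–nanoparticle pairs use the same form with
  ``sigma_m`` replaced by ``sigma_n``.
* ``u_fene`` — the finitely extensible nonlinear elastic bond between
  adjacent monomers of a chain, diverging at the maximum extension ``r0``.
  Bonded monomers feel the FENE spring *in addition to* ``u_mm``
  (Kremer–Grest convention).
* ``u_nm`` — a centre-shifted Lennard-Jones attraction between monomers and
  nanoparticles, ``4*eps_b*[x**-12 - x**-6]`` with ``x = (r - delta)/sigma_m``
  and ``delta = (sigma_n - sigma_m)/2``.  Its well depth is exactly
  ``eps_b``, attained at ``r = delta + 2**(1/6)*sigma_m``.  The cutoff is
  ``r_cut_nm = 3*sigma_m`` and by default the tail is *not* energy-shifted
  there (the residual discontinuity is about ``0.0055*eps_b``); pass
  ``shift_nm=True`` to shift it to zero at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BondOverstretchError

#: WCA cutoff factor, the location of the Lennard-Jones minimum.
RC_WCA = 2.0 ** (1.0 / 6.0)

MONOMER = 0
NANOPARTICLE = 1

_SPECIES_CODES = {
    "monomer": MONOMER,
    "nanoparticle": NANOPARTICLE,
    MONOMER: MONOMER,
    NANOPARTICLE: NANOPARTICLE,
}


@dataclass(frozen=True)
class ForceField:
    """Complete parameter set for the pair and bonded interactions.

    Parameters
    ----------
    epsilon:
        Repulsive LJ energy scale (defines the reduced unit, 1 by convention).
    sigma_m:
        Monomer diameter (defines the reduced length unit).
    sigma_n:
        Nanoparticle diameter; 1 or 3 in the studied systems.
    eps_b:
        Monomer–nanoparticle well depth (binding strength), >= 0.
    fene_k:
        FENE spring constant, ``30*epsilon/sigma_m**2`` by convention.
    fene_r0:
        FENE maximum extension, ``1.5*sigma_m`` by convention.
    r_cut_nm:
        Monomer–nanoparticle cutoff distance, ``3*sigma_m``.
    shift_nm:
        If True, energy-shift ``u_nm`` to zero at ``r_cut_nm``.
    """

    epsilon: float = 1.0
    sigma_m: float = 1.0
    sigma_n: float = 1.0
    eps_b: float = 1.0
    fene_k: float = 30.0
    fene_r0: float = 1.5
    r_cut_nm: float = 3.0
    shift_nm: bool = False

    def __post_init__(self):
        for name in ("epsilon", "sigma_m", "sigma_n", "fene_k", "fene_r0", "r_cut_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.eps_b < 0:
            raise ValueError(f"eps_b must be non-negative, got {self.eps_b}")

    @property
    def delta(self) -> float:
        """Hard-core offset of the monomer–nanoparticle potential."""
        return 0.5 * (self.sigma_n - self.sigma_m)

    @property
    def rc_m(self) -> float:
        """Monomer–monomer cutoff ``2**(1/6)*sigma_m``."""
        return RC_WCA * self.sigma_m

    @property
    def rc_n(self) -> float:
        """Nanoparticle–nanoparticle cutoff ``2**(1/6)*sigma_n``."""
        return RC_WCA * self.sigma_n

    @property
    def r_min_nm(self) -> float:
        """Location of the monomer–nanoparticle well minimum."""
        return self.delta + RC_WCA * self.sigma_m

    @property
    def nm_shift_energy(self) -> float:
        """Energy subtracted from ``u_nm`` when ``shift_nm`` is enabled."""
        if not self.shift_nm:
            return 0.0
        x6 = (self.sigma_m / (self.r_cut_nm - self.delta)) ** 6
        return 4.0 * self.eps_b * (x6 * x6 - x6)

    def max_cutoff(self, has_nanoparticles: bool = True) -> float:
        """Largest interaction range present in the system."""
        if has_nanoparticles:
            return max(self.rc_m, self.rc_n, self.r_cut_nm)
        return self.rc_m


def _wca(r, sigma, epsilon):
    s6 = (sigma / r) ** 6
    return np.where(r < RC_WCA * sigma, 4.0 * epsilon * (s6 * s6 - s6) + epsilon, 0.0)


def u_mm(r, ff: ForceField):
    """Purely repulsive monomer–monomer energy; zero beyond ``rc_m``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("u_mm requires r > 0")
    out = _wca(r, ff.sigma_m, ff.epsilon)
    return out if out.ndim else float(out)


def u_nn(r, ff: ForceField):
    """Purely repulsive nanoparticle–nanoparticle energy (``sigma_m -> sigma_n``)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("u_nn requires r > 0")
    out = _wca(r, ff.sigma_n, ff.epsilon)
    return out if out.ndim else float(out)


def u_fene(r, ff: ForceField):
    """FENE bond energy; diverges logarithmically as ``r -> r0``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("u_fene requires r >= 0")
    if np.any(r >= ff.fene_r0):
        raise BondOverstretchError(
            f"bond length {float(np.max(r)):.6g} >= r0 = {ff.fene_r0}"
        )
    out = -0.5 * ff.fene_k * ff.fene_r0**2 * np.log(1.0 - (r / ff.fene_r0) ** 2)
    return out if out.ndim else float(out)


def u_nm(r, ff: ForceField):
    """Monomer–nanoparticle energy with hard-core offset ``delta``.

    Defined for ``r > delta``; zero beyond ``r_cut_nm``.  The well depth is
    ``-eps_b`` at ``r = delta + 2**(1/6)*sigma_m``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= ff.delta):
        raise ValueError(f"u_nm requires r > delta = {ff.delta}")
    x6 = (ff.sigma_m / (r - ff.delta)) ** 6
    out = np.where(
        r < ff.r_cut_nm,
        4.0 * ff.eps_b * (x6 * x6 - x6) - ff.nm_shift_energy,
        0.0,
    )
    return out if out.ndim else float(out)


def _dwca_dr(r, sigma, epsilon):
    s6 = (sigma / r) ** 6
    return np.where(
        r < RC_WCA * sigma, 4.0 * epsilon * (-12.0 * s6 * s6 + 6.0 * s6) / r, 0.0
    )


def du_dr(r, kind_i, kind_j, ff: ForceField):
    """Scalar derivative dU/dr of the non-bonded pair potential for a species pair."""
    r = np.asarray(r, dtype=float)
    ki, kj = _SPECIES_CODES[kind_i], _SPECIES_CODES[kind_j]
    if ki == MONOMER and kj == MONOMER:
        return _dwca_dr(r, ff.sigma_m, ff.epsilon)
    if ki == NANOPARTICLE and kj == NANOPARTICLE:
        return _dwca_dr(r, ff.sigma_n, ff.epsilon)
    rr = r - ff.delta
    if np.any(rr <= 0):
        raise ValueError("pair distance inside the hard-core region")
    x6 = (ff.sigma_m / rr) ** 6
    return np.where(
        r < ff.r_cut_nm, 4.0 * ff.eps_b * (-12.0 * x6 * x6 + 6.0 * x6) / rr, 0.0
    )


def dfene_dr(r, ff: ForceField):
    """Scalar derivative of the FENE bond energy, ``k*r/(1-(r/r0)**2)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= ff.fene_r0):
        raise BondOverstretchError("bond length >= r0")
    return ff.fene_k * r / (1.0 - (r / ff.fene_r0) ** 2)


def pair_energy(r, kind_i, kind_j, ff: ForceField):
    """Non-bonded pair energy dispatched on the two species."""
    ki, kj = _SPECIES_CODES[kind_i], _SPECIES_CODES[kind_j]
    if ki == MONOMER and kj == MONOMER:
        return u_mm(r, ff)
    if ki == NANOPARTICLE and kj == NANOPARTICLE:
        return u_nn(r, ff)
    return u_nm(r, ff)


def pair_force(r_vec, kind_i, kind_j, ff: ForceField, bonded: bool = False):
    """Force on particle *i* from particle *j*, ``r_vec = x_i - x_j``.

    Equals ``-grad_i U(|r_vec|)`` for the non-bonded potential of the species
    pair, plus the FENE contribution when ``bonded`` is set.  Antisymmetric
    under exchange of i and j by construction.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise ValueError("pair_force requires a non-zero separation")
    g = float(du_dr(r, kind_i, kind_j, ff))
    if bonded:
        g += float(dfene_dr(r, ff))
    return (-g / r) * r_vec
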