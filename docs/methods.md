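# Methods

## The model

`nanobrush` simulates an end-grafted polymer brush, optionally mixed with
mobile attractive nanoparticles, with coarse-grained Langevin dynamics in
reduced Lennard-Jones units (`sigma_m = epsilon = m = kB = 1`, time unit
`tau = sigma_m (m/epsilon)^(1/2)`).

**Interactions.**  All monomer pairs repel through the truncated-and-shifted
Lennard-Jones (WCA) potential

    U_mm(r) = 4 eps [ (sigma_m/r)^12 - (sigma_m/r)^6 ] + eps,   r < 2^(1/6) sigma_m,

zero beyond the cutoff, so the solvent is implicitly good (athermal): the
only monomer–monomer interaction is excluded volume.  Adjacent beads of a
chain are additionally bonded by the FENE spring

    U_FENE(r) = -(1/2) k r0^2 ln[1 - (r/r0)^2],   k = 30 eps/sigma_m^2,  r0 = 1.5 sigma_m,

the Kremer–Grest convention (the WCA term acts between bonded beads too).
Nanoparticle pairs repel through the same WCA form with `sigma_m -> sigma_n`.
Monomers and nanoparticles attract through a centre-shifted Lennard-Jones
potential

    U_nm(r) = 4 eps_b [ x^-12 - x^-6 ],   x = (r - Delta)/sigma_m,
    Delta = (sigma_n - sigma_m)/2,        cutoff r_cut = 3 sigma_m,

whose well depth is exactly `eps_b` at `r = Delta + 2^(1/6) sigma_m`.  The
tail is **not** energy-shifted at the cutoff by default: the potential is
implemented exactly as written, leaving a discontinuity of about
`0.0055 eps_b` that the thermostat absorbs; a `shift_nm` flag removes it.
Because `U_nm/eps_b` is a pure shape function, every monomer–nanoparticle
Boltzmann factor depends on `eps_b` and `T` only through `eps_b/T`, while
the WCA and FENE factors are nearly temperature-independent (they
approximate hard constraints).  This is the mechanism behind the `eps_b/T`
scaling of the equilibrium morphology that the analysis layer quantifies.

**Geometries.**  The planar slab is periodic in x, y with repulsive walls at
`z = 0` (grafting surface) and `z = Lz`; both species feel the wall through
the WCA form acting on the distance to the wall, with the species' own
diameter as length scale.  The cylinder geometry grafts chains to the inner
surface of a cylinder of radius `R` (axis along x) immersed in a fully
periodic box; the cylindrical surface repels monomers (WCA on
`R - distance-from-axis`) and exerts **no force on nanoparticles** — a
smooth, species-selective stand-in for a wall built of explicit atoms
permeable to nanoparticles.  This is a deliberate simplification: it keeps
the permeability contract (nanoparticles exchange freely between pore and
outer solution, monomers are confined) without modelling wall atoms.

## Initial configurations

Chains are grafted at random with a minimum anchor separation of one bead
diameter (random sequential insertion, 10^6 attempts before a packing
error).  Bead 1 of each chain is frozen at its anchor — it is never
integrated or thermostatted.  Chains start fully stretched perpendicular to
the grafting surface with bond length 0.97 sigma (near the minimum of the
combined FENE+WCA bond energy), which avoids both initial force spikes and
metastable entangled starts.

In the cylinder, stretched chains longer than the radius cannot all run
straight to the axis (the rays converge), so each chain is laid out as a
radial zigzag: an inward ray down to a per-chain turn radius, an axial
U-turn step, an outward ray, and so on, with per-chain randomized turn radii
so no annular band saturates.  A bead whose deterministic position would
fall within 0.85 sigma of an already placed bead falls back to a bonded
random-walk step (with bounded backtracking and whole-chain retries).  After
construction no non-bonded pair exceeds 50 eps — checked explicitly.
Nanoparticles are inserted uniformly at random in the solution region (above
the stretched chains in the slab, outside the cylinder surface in the pore)
without overlaps.  Initial velocities are Maxwell–Boltzmann at the target
temperature.

## Dynamics

Velocity Verlet with a BAOAB-split Langevin thermostat:

    B: v += dt/2 F/m     A: x += dt/2 v     O: v = c1 v + c2 xi
    A: x += dt/2 v       B: v += dt/2 F(x)/m

with `c1 = exp(-gamma dt)`, `c2 = sqrt((1 - c1^2) kB T/m)`.  Defaults are
`dt = 0.005 tau` and `gamma = 1/tau`.  With `gamma = 0` the O step is the
identity and the scheme is exactly NVE velocity Verlet, which the test suite
uses for energy-conservation checks.  The noise `xi` is uniform with unit
variance rather than Gaussian (the convention used by LAMMPS's Langevin
fix): the O-step's stationary second moment is exact for any unit-variance
noise, and with `c1 ~ 0.995` the stationary velocity distribution is a
weighted sum of hundreds of independent kicks and therefore Gaussian to
high accuracy — verified by the equipartition tests.  Uniform draws are
substantially cheaper, which matters because noise generation is a large
fraction of the step cost at these system sizes.

An optional coarser equilibration time step (`dt_equil`, 0.0075 tau where
used) can be set for the equilibration phase only: the equilibrium ensemble
does not depend on the path taken to reach it, the bead-spring model is
stable well beyond that step size at the temperatures studied, and the
production phase always runs at the protocol `dt`.

Frozen graft beads are skipped by every sub-step and by the thermostat;
their pair interactions still act on mobile particles (they behave as
external potential sources).  A FENE bond reaching `r0`, a hard-core breach,
or a non-finite coordinate aborts the run with the step index — the
simulation never silently clamps.

**Neighbor acceleration.**  A Verlet pair list with species-resolved list
cutoffs (each pair class uses its own interaction cutoff plus a 0.4 sigma
skin) is rebuilt whenever any particle has moved more than half the skin.
The list is built by cell binning when at least three cells fit along every
periodic direction, and by a direct pair scan otherwise (small desk boxes);
both builders are verified against an all-pairs reference with explicit
image enumeration.  The engine refuses to run when a periodic box dimension
is below twice the largest interaction cutoff (minimum image would silently
drop interactions).

**Randomness.**  Every run derives independent sub-seeds (builder,
equilibration phase, production phase) from its replicate seed through
`numpy.random.SeedSequence`; the compiled integrator seeds its own PRNG once
per phase.  Identical seeds reproduce trajectories bit-for-bit on the same
platform.

## Analysis

Density profiles are time-averaged histograms (default bin width
0.25 sigma) with explicit normalization contracts, all enforced to machine
precision by rescaling with the exact histogram integral `sum(v_i dz)` (the
same convention the quantile uses, so normalization and height are mutually
consistent):

* flat monomer profile: integral `sigma_g N` (psi(z) is then the local
  monomer concentration);
* flat nanoparticle profile: integral 1;
* radial cylinder profile in `r = R - rho` (distance from the grafting
  wall): `2 pi L sum (R - r_mid) psi_i dr = N n_ch`, bins at the axis
  excluded because the shell Jacobian vanishes there;
* projection profile: each monomer is projected onto the inward surface
  normal at its own chain's anchor; the coordinate can exceed `R`, which is
  what keeps the brush height measurable once chains reach past the axis.
  Normalized like the flat profile.

The brush height `h` is the smallest coordinate at which the cumulative
profile reaches 0.995 of its total, linearly interpolated inside the
straddling bin, ties broken toward smaller h.  The 0.995 value follows the
calibration of classic bead-spring brush studies.  The nanoparticle solution
concentration `c` is a time-averaged count over the solution volume: outside
the cylinder (`box volume - pi R^2 L`) in the pore geometry, and above the
brush (`z > h`, volume `Lx Ly (Lz - h)`) in the slab — the slab solution
region is defined self-consistently through the measured h, mirroring the
cylinder's "outside the brush region" rule.

State points carry replicate means and standard deviations of h and c over
independent seeds (five replicates in the standard protocol).  The
`eps_b/T` collapse score interpolates h(c) curves onto the overlap of their
c ranges and reports the mean and maximum spread across curves.

## Study conditions at reduced scale

Full-scale conditions (100 plane-grafted or 400 cylinder-grafted chains of
100 beads, 3,000–30,000 nanoparticles, 4x10^6 + 10^6 steps, five seeds) are
shipped as the `paper-flat` / `paper-cylinder` presets; they are
cluster-sized jobs.  The test suite and the acceptance script run `desk`
presets that keep every intensive parameter (grafting density 0.0625, dt,
damping, temperature range, five seeds) and shrink the extensive ones:

* flat: 16 chains x 40 beads (box 16 x 16 x 60), pure-brush scans with
  8x10^4 equilibration + 1x10^5 production steps; the equilibration
  length was confirmed by h(t) window traces (the stretched start relaxes
  within ~8x10^4 steps at all temperatures) and the production length by the
  fluctuation of the 0.995-quantile height (about +-0.65 sigma per 4x10^4
  step window for 16 chains), so the five-replicate mean has a standard
  error of ~0.15 sigma;
* nanoparticle runs: 384 nanoparticles (solution concentration
  ~0.02/sigma^3).  The reduced brush (N = 40) is less cooperative than the
  full-scale one and its compression window at `eps_b/T ~ 1.1` sits at
  higher concentration; 384 places the T = 0.9 system inside that window —
  determined from the package's own reduced-scale h–c diagram, exactly how
  the full-scale study locates its compression regime by sweeping c.
  Inside the collapse regime the transition is nucleation-limited: h(t)
  window traces at T = 0.9 show individual replicates dropping into the
  collapsed basin (h ~ 14.5) anywhere between ~500 and ~1200 tau, so that
  state point is equilibrated for ~1000 tau (run at the coarser
  equilibration step) before production; states outside the collapse
  regime equilibrate within ~400 tau.  Equilibration adequacy is always
  judged per state point from the trajectory, never assumed;
* cylinder: 24 chains x 16 beads inside R = 8 (box length 7.6, cross-section
  28), 120 nanoparticles.

What the reduced scale does and does not show: the desk systems reproduce
the *mechanisms* — pure-brush athermality, nanoparticle partitioning,
temperature-controlled compression, eps_b/T scaling, pore permeability —
but their absolute heights (h ~ 18 for N = 40 versus ~42 for N = 100) and
the sharpness of the collapse transition are not those of the full-scale
systems; short chains smooth the transition and shift its concentration
window.  Full-scale numbers require the paper presets on cluster resources.

## Numerical choices and edge cases

* Overlap threshold at build time: 50 eps on any non-bonded pair.
* `u_nm` is evaluated only for `r > Delta`; the integrator treats
  `r - Delta <= 0.05 sigma` as a hard-core breach and aborts.
* Empty trajectories, all-zero profiles, brush heights at the box top and
  non-overlapping collapse curves raise explicit analysis errors.
* Profiles warn and drop samples beyond the last radial bin; radial bins
  whose shell volume vanishes are excluded.
* The 0.995 quantile interpolates linearly inside the straddling bin; ties
  break toward smaller h, so the height is monotone under mass added above
  it and invariant under profile rescaling.

## Known limitations

* The smooth species-selective cylinder wall replaces an atomistic
  permeable wall; near-wall structure (layering against discrete wall atoms)
  is not reproduced.
* Nanoparticle–wall interaction in the slab uses the nanoparticle diameter
  as the WCA length scale; other conventions would shift the first
  nanoparticle layer by a fraction of sigma.
* The unshifted `U_nm` cutoff injects a ~0.005 eps_b discontinuity per
  crossing; NVE energy conservation tests therefore run nanoparticle-free.
* Desk-scale brush heights carry ~0.1 sigma standard errors; quantile-based
  heights of small brushes (16 chains) are intrinsically noisy because the
  outermost few chain ends dominate the 0.995 tail.
* One CPU, no domain decomposition: paper-scale presets run, but at cluster
  wall-times.
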