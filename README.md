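# nanobrush

Coarse-grained Langevin dynamics of end-grafted polymer brushes mixed with
attractive nanoparticles, in planar-slab and inside-cylinder (nanopore)
geometries — together with the analysis that turns trajectories into brush
heights, density profiles and h–c response diagrams.

Polymer brushes in good solvent are athermal: their equilibrium height is
set by excluded volume and grafting density alone, so temperature is not a
control knob.  Add nanoparticles that bind to the monomers, however, and
every nanoparticle–monomer contact contributes a Boltzmann factor
`exp(-U_nm/kB T)`; the brush then partitions nanoparticles, compresses or
re-swells depending on the solution concentration `c`, and becomes strongly
temperature-responsive.  Because the attraction scales linearly with the
binding strength `eps_b`, the equilibrium morphology depends on `eps_b` and
`T` essentially only through `eps_b/T`.  A brush grafted inside a cylinder
acts as a thermally gated nanovalve: the pore closes when the chains extend
to the axis and opens when bound nanoparticles pull them back to the wall.
This package is for polymer-physics and soft-matter researchers who want to
simulate and analyse that mechanism, at desk scale for method development
and at full published scale on a cluster.

## Model

* Kremer–Grest bead–spring chains: WCA repulsion
  `4 eps [(sigma/r)^12 - (sigma/r)^6] + eps` (cut at `2^(1/6) sigma`) plus
  FENE bonds `-(1/2) k r0^2 ln(1-(r/r0)^2)` with `k = 30`, `r0 = 1.5`.
* Monomer–nanoparticle attraction: centre-shifted Lennard-Jones
  `4 eps_b [x^-12 - x^-6]`, `x = (r - Delta)/sigma_m`,
  `Delta = (sigma_n - sigma_m)/2`, cut at `3 sigma_m`; well depth exactly
  `eps_b`.
* NVT Langevin dynamics (BAOAB), `dt = 0.005 tau`, damping `1/tau`;
  fully stretched starts; frozen graft beads.
* Brush height: 0.995 quantile of the normalized monomer density profile
  (`int psi dz = sigma_g N` flat; projection method in the cylinder so the
  height stays measurable when chains cross the axis).

See `docs/methods.md` for the complete model description, normalization
contracts and the reduced-scale study conditions.

## Worked example

Brush of 16 chains x 40 beads with and without 384 attractive
nanoparticles (`eps_b = 1`, `sigma_n = 1`) at two temperatures.  The
low-temperature point sits in the collapse regime, where the transition is
nucleation-limited, so it gets a longer equilibration:

```python
from nanobrush.config import get_preset
from nanobrush.experiments import run_state_point

cfg = get_preset("desk-flat")
pure, _ = run_state_point(cfg, T=0.9, n_np=0, seeds=[1, 2, 3])
cfg.integrator["n_steps_equil"] = 240_000   # collapse nucleation at T=0.9
sp_lo, _ = run_state_point(cfg, T=0.9, n_np=384, seeds=[1, 2, 3])
cfg.integrator["n_steps_equil"] = 80_000
sp_hi, _ = run_state_point(cfg, T=1.5, n_np=384, seeds=[1, 2, 3])
for T, sp in ((0.9, sp_lo), (1.5, sp_hi)):
    print(f"T={T}: h = {sp.h:5.2f} +- {sp.h_sd:.2f}   c = {sp.c:.4f}")
print(f"pure brush at T=0.9: h = {pure.h:5.2f} +- {pure.h_sd:.2f}")
```

prints (about seven minutes on one CPU):

```
T=0.9: h = 15.47 +- 1.29   c = 0.0168
T=1.5: h = 18.12 +- 0.95   c = 0.0246
pure brush at T=0.9: h = 18.34 +- 0.31
```

Read it as: at the low temperature the nanoparticle-loaded brush has
collapsed roughly three monomer diameters below its nanoparticle-free
height — bound nanoparticles are pulling the chains down, and the solution
concentration `c` drops because nanoparticles have partitioned into the
brush — while at `T = 1.5` the same loading leaves the brush at its pure
height with more nanoparticles left in solution.  That contrast is the
temperature response: the pure brush itself barely moves between these
temperatures, so the nanoparticles are what make the brush thermally
switchable.

The same experiments are available from the shell:

```bash
nanobrush build --preset desk-flat --outdir out      # initial configuration
nanobrush run   --config my_sweep.yaml --outdir runs # (T, n_np, seed) sweep
nanobrush analyze runs                               # profiles, hc.tsv, collapse report
nanobrush report  runs                               # h-c and profile plots
```

`--preset paper-flat` / `--preset paper-cylinder` select the full published
protocol (100/400 chains of 100 beads, 3,000/30,000 nanoparticles,
4x10^6 + 10^6 steps, five seeds) — cluster-sized jobs.

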