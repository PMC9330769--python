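# helixq

Inference of double-helix geometry and molecule–electrolyte interface
parameters from single-molecule escape-time electrometry.

A charged nucleic-acid fragment confined in a like-charged nanoslit escapes
from an electrostatic trap at a rate set exponentially by the trap depth,
which is the product of the molecule's *effective* (renormalized) charge and
the slit midplane potential. Measuring effective charges for three fragment
lengths and comparing them with nonlinear Poisson–Boltzmann (PB)
calculations for finite charged cylinders pins down the helix rise per
basepair `b` and radius `r`; plotting the inferred radius against the
hydrated cation radius characterizes the molecule–solvent interface.

## Components

| module | what it does |
|---|---|
| `helixq.electrolyte` | Debye length, Bjerrum length, slit midplane potential |
| `helixq.pb` | axisymmetric nonlinear PB solver for finite charged cylinders; effective charge via far-field matching against the linearized solution; tabulated `q_eff(b, r)` surfaces |
| `helixq.kinetics` | residence-event extraction from intensity traces, truncated-exponential escape-time MLE, Kramers conversion, Brownian-dynamics escape simulation with quadrature oracles |
| `helixq.inference` | pairwise charge ratios (cancelling the apparatus factor `f_M`), probability-weighted `(b, r)` manifold, refined-mode geometry estimate, self-consistent `f_M` |
| `helixq.interface` | weighted shared-slope fit `r_m = r_0(species) + k a_H` |
| `helixq.synthetic` | forward model: synthetic measurement tables, censored event tables, telegraph intensity traces |
| `helixq.cli` | `helixq` command-line pipeline |

## CLI

```bash
# tabulate PB effective-charge surfaces for 30/40/60 bp at 1.23 mM
helixq pbsurf --config config.yaml --out out/surf

# generate a complete synthetic experiment (measurements + event tables)
helixq simulate --config config.yaml --seed 7 --out out/sim

# fit escape times from event tables
helixq fit-events --events out/sim/events_*.csv --out out/fits

# three-length (b, r) inference from a measurement table
helixq infer-geometry --measurements out/sim/measurements.csv \
    --surface out/sim/surface_LiCl_30bp.csv \
    --surface out/sim/surface_LiCl_40bp.csv \
    --surface out/sim/surface_LiCl_60bp.csv --out out/geo

# shared-slope radius-vs-hydrated-cation-radius fit
helixq fit-interface --radii radii.csv --out out/interface

# everything in one pass
helixq run-all --config config.yaml --seed 7 --out out/all
```

Configuration is YAML (keys: `salt`, `c_mM`, `T_K`, `half_height_nm`,
`pocket_radius_nm`, `phi_s`, `f_A_e`, `b_grid`, `r_grid`, `lengths`,
`n_events`, ...); all tables are plain CSV with round-trippable floats, and
every JSON summary embeds the config hash and seed that produced it.

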