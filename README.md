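# icpulse

Coupled simulation of cardiac-induced intracranial pulsatility: three-field
Biot poroelasticity for the brain parenchyma (displacement, pore pressure,
total pressure) monolithically coupled to time-dependent Stokes flow in the
CSF spaces (velocity, fluid pressure) through Beavers–Joseph–Saffman-type
interface conditions. The system is driven by a prescribed pulsatile net
blood inflow distributed uniformly over the parenchyma and closed by an
exponential pressure–volume (PVI) compliance condition at the spinal
outlet.

The discretization is implicit Euler in time and continuous P2/P1 mixed
finite elements in space on tagged tetrahedral (or triangular) meshes, with
a conforming interface, a mortar-type interface multiplier enforcing
normal-flux continuity, and one sparse LU factorization reused over all
time steps (the nonlinear outlet condition is handled by a linearized
rank-one Sherman–Morrison update). The FEM core (quadrature, spaces,
assembly) is implemented in numpy/scipy and lives in `icpulse.fem`.

## Layout

| module | role |
| --- | --- |
| `icpulse.params` | material constants, unit conversions, Lamé derivation |
| `icpulse.geometry` | idealized tagged intracranial domain, fixtures, MSH I/O |
| `icpulse.waveform` | periodic net blood inflow and source density |
| `icpulse.system` | monolithic Stokes–Biot step operator |
| `icpulse.timeloop` | transient driver, outflow-volume accumulation |
| `icpulse.lumped` | two-compartment compliance oracle (independent check) |
| `icpulse.qoi` | probes, fluxes, stroke volumes, gradients, partitions |
| `icpulse.verification` | manufactured solutions and convergence studies |
| `icpulse.cli` | scenario runner (`icpulse` console script) |

The idealized geometry is a desk-scale concentric twin of the intracranial
space: rigid skull shell, thin cranial-SAS gap, thick poroelastic shell,
inner ventricular cavity, an aqueduct-analog channel at the north pole, and
a caudal outlet tube whose end face splits into a clamped spinal-cord disc
and an open spinal-SAS annulus. The three radii are calibrated so the
discrete parenchyma / cranial-SAS / ventricle volumes match their targets
(1369.54 / 292.08 / 30.3 ml).

## CLI

```sh
icpulse run --scenario standard --tier acceptance --out out_std
icpulse run --scenario A --tier test --out out_A     # PVI = 10 ml
icpulse waveform --out waveform.csv
```

Scenarios: `standard`, `A` (PVI = 10 ml), `B` (E = 3000 Pa), `C`
(ν = 0.4), `D` (c = 1e-5 1/Pa), `custom` (with `--set KEY=VALUE`).
Tiers: `test` (coarse, seconds per cycle), `acceptance` (default),
`fine` (3 cycles at 320 steps per cycle). Each run writes a QoI
table (CSV/JSON), probe/flux time series, the waveform echo and a
reproducibility manifest.

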