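# maxcalbench

Stochastic inference engines for small gene circuits, benchmarked
head-to-head on simulated single-cell protein-count trajectories.

Synthetic biologists characterize circuits by watching fluorescently
tagged proteins fluctuate in single cells.  Most of the network — mRNA,
dimers, protein–promoter complexes — stays invisible, so circuit
parameters must be *inferred* from the noisy count time series of the
one or two visible proteins.  This package implements, and lets you
compare, the three standard ways of doing that:

* **DM** — a *detailed model*: a reduced reaction scheme with explicit
  promoter states, solved as a chemical master equation (CME) with the
  Finite State Projection (FSP) truncation and matrix-exponential
  propagators;
* **CGM** — a *coarse-grain model*: a birth–death CME whose production
  propensity is a Hill function, g₂ + g₂\*Nⁿ/(Nⁿ+K) with n = 2,
  encoding feedback without auxiliary species;
* **MaxCal** — a *Maximum Caliber* model: per frame, the number of
  productions ℓ_α ≤ M and survivors ℓ_A ≤ N follow the max-path-entropy
  distribution P(ℓ_α,ℓ_A|N) ∝ C(N,ℓ_A)·e^{h_αℓ_α + h_Aℓ_A + K_Aℓ_αℓ_A};
  its m-frame propagator is a matrix *power*, not an exponential.

Benchmark data come from exact Gillespie simulations of two circuits: a
single-gene auto-activation switch (SGAA; the protein dimerizes and the
dimer activates its own promoter) and a two-gene toggle switch (TS;
either monomer represses the other gene).  Each engine is fitted by
maximizing the transition likelihood L = Π P(i→j over m frames)^ω(i→j),
and judged by its inferred *effective rates*: basal production p_eff,
activated/repressed production p_eff\*, and degradation r_eff.  For the
SGAA generator these are p_eff = p·g/d = 5×10⁻³ s⁻¹,
p_eff\* = p·g\*/d = 50×10⁻³ s⁻¹, r_eff = 10⁻³ s⁻¹.

## Worked example

Simulate a small SGAA ensemble, fit the MaxCal model, and read off the
effective rates:

```python
from maxcalbench import SimulationConfig, run_benchmark
from maxcalbench.inference import BenchmarkConfig, OptimizerConfig
from maxcalbench.io import render_report

sim = SimulationConfig(t_end=43200.0 + 48 * 3600.0, delta_t=300.0,
                       n_trajectories=20, n_replicates=2,
                       burn_in=43200.0, rng_seed=7)
report = run_benchmark(BenchmarkConfig(circuit="sgaa", sim=sim, m=16,
                                       optimizer=OptimizerConfig(seed=8)))
print(render_report(report))
```

```
Method  peff (s-1)           peff* (s-1)          reff (s-1)
True    5e-3                 50e-3                1e-3
DM      (5.2 +/- 2.4)e-3     (53 +/- 22)e-3       (1.1 +/- 0.47)e-3
CGM     (7 +/- 0.51)e-3      (1.6e+02 +/- 10)e-3  (2 +/- 0.088)e-3
MaxCal  (4.9 +/- 0.0094)e-3  (42 +/- 0.35)e-3     (1 +/- 0.034)e-3
```

Reading the table: MaxCal recovers all three effective rates close to
the generating truth; DM is accurate on average but its replicate-level
estimates scatter at this reduced data volume (see
`docs/methods.md`); the coarse-grain Hill model overshoots the
activated production rate severalfold — its saturated limit g₂+g₂\* is
an extrapolation beyond the observed counts.  MaxCal's likelihood step
is also the cheapest (matrix power vs. matrix exponential), which is
the practical argument for it on larger circuits.

The same pipeline is scriptable from the shell:

```bash
maxcalbench simulate --circuit sgaa --out data/ --seed 7
maxcalbench infer --model maxcal --circuit sgaa --data data/ --out fit.json
maxcalbench benchmark --config config.yaml --out report.json
```

## Layout

```
src/maxcalbench/
  circuits.py   reaction networks for the two generating schemes
  ssa.py        exact Gillespie simulator (numba), frame sampling
  fsp.py        truncated state spaces, generators, expm/power, stationary laws
  dm.py         detailed inference model (explicit promoter states)
  cgm.py        Hill coarse-grain inference model
  maxcal.py     Maximum Caliber path model and transition matrices
  inference.py  transition counting, likelihoods, optimization, benchmark
  io.py         TSV trajectories, manifests, fixtures, report rendering
  cli.py        simulate / infer / benchmark / report commands
```
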