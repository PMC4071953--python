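# mdximmune

A tested Python implementation of a six-variable ODE model of the immune
response to skeletal-muscle damage in the *mdx* mouse, the standard animal
model of early-onset Duchenne muscular dystrophy (DMD), together with its
calibration machinery, in-silico cell-depletion experiments, and the
ensemble/sweep analyses used to characterize its long-run regimes.

It is written for modelers and quantitative biologists who want to
reproduce, probe or extend the predator–prey-like coupling between
infiltrating immune cells and cycling muscle degeneration/regeneration,
without any external data downloads: a synthetic-data generator emulates the
sparse literature-style time courses the model is calibrated against.

## The model

State variables: immune-cell densities in cells/mm³ of muscle —
CD4⁺ helper T-cells *H*, CD8⁺ cytotoxic T-cells *C*, macrophages *M* — and
muscle-fiber state fractions in % of the tissue — normal *N*, damaged *D*,
regenerating *R*, with *N* + *D* + *R* = 100 conserved:

    dH/dt = bH + k1·D·M − dH·H
    dC/dt = bC + k2·D·H − dC·C
    dM/dt = bM + k3·M·D − dM·M
    dN/dt = k4·R − k5·C·N − α(t)·N
    dD/dt = k5·C·N + α(t)·N − k6·D·M − dD·D
    dR/dt = k6·D·M + dD·D − k4·R

with sources tied to homeostatic baselines, bX = dX·X0.  Mechanical damage
enters through a lognormal time-to-failure hazard

    α(t) = h / (t·σ·√(2π)) · exp(−(ln t − m)² / (2σ²)),

the hazard of a multiplicative damage-accumulation process; *t* is age in
weeks and *h* is the total hazard mass.  The wild-type configuration is
identical except *h* is one tenth of the dystrophic value.  Calibrated
parameter values ship as `mdx_parameters()` and are used as defaults
throughout.

## Worked example

```python
from mdximmune import (DepletionSchedule, SimulationSettings, integrate,
                       mdx_parameters, peak_value, run_depletion_experiment)

p = mdx_parameters()
tr = integrate(p, cfg=SimulationSettings(t_end=12.0))
print(peak_value(tr, "M"))            # (3.9, 104077.2...)
print(tr.final_state.N)               # 40.89...

sched = DepletionSchedule("macrophages", t_start=0.0, t_end=12.0,
                          mechanism="clamp_zero")
res = run_depletion_experiment(p, sched)
print(res.final_fibers)               # {'N': 84.77..., 'D': 1.357..., 'R': 13.87...}
```

The dystrophic run produces the hallmark inflammatory surge — macrophages
peak at ~104,000 cells/mm³ at week 3.9 — after which the tissue settles with
only ~41% normal fibers at week 12 and a large regenerating pool.  Clamping
macrophages to zero for the whole run removes both the clearing of damaged
fibers *and* the CD4⁺→CD8⁺ activation cascade; the net effect is protective,
leaving ~85% of fibers normal.

The numbered scripts under `analysis/` run the full study — reference and
wild-type dynamics, depletion, the 125-draw initial-condition ensemble, the
1024-corner two-level factorial census, k1/k4 sweeps, k1×k2 heat maps and
the synthetic-data parameter-recovery experiment — each printing what it
found and writing tables under `results/`.

A thin CLI mirrors the library (`mdximmune simulate|wildtype|deplete|fit|
recover|sweep|heatmap|ensemble|synth`).

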