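# Methods

## Model

The package implements a deterministic compartment model of the dystrophic
muscle micro-environment.  Three immune populations (CD4⁺ helpers H, CD8⁺
cytotoxics C, macrophages M; cells/mm³) interact with three fiber-state
fractions (normal N, damaged D, regenerating R; % of tissue).  The
assumptions encoded in the equations:

- Immune populations have constant homeostatic sources bX = dX·X0 and
  first-order death, so with no damage present (D = 0) the baselines
  (H0, C0, M0) are exact fixed points of the immune subsystem.
- Damage recruits the immune response hierarchically: macrophages
  self-amplify on damage (k3·M·D), macrophages plus damage activate helpers
  (k1·D·M), helpers plus damage license cytotoxics (k2·D·H).
- Cytotoxic cells damage normal fibers (k5·C·N); macrophages clear damaged
  fibers into the regenerating pool (k6·D·M), as does a slower unspecified
  physiological route (dD·D); regenerating fibers mature at k4·R.
- Fibers only change state, so N + D + R = 100 identically.  The code
  computes dR/dt = −(dN/dt + dD/dt), which makes the conservation identity
  exact in floating point as well as algebraically.
- Primary mechanical damage is a lognormal time-to-failure hazard α(t)
  applied to normal fibers: damage accumulation is multiplicative, so
  failure times are approximately lognormal in the age t (weeks).  h is the
  total hazard mass (∫α dt = h), m and σ the log-time location and scale.
  α(0) is defined as 0 by continuity; the hazard is evaluated in log space
  so the 1/t factor cannot overflow near t = 0.

Everything is parameterized by the calibrated dystrophic values shipped as
`mdx_parameters()` (units: weeks, cells/mm³, percentage points; "per cent"
rates mean per percentage point of damaged fibers).  The wild-type
configuration differs only in h → h/10.  Time-course observations quoted in
days are converted as days/7 on ingest.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with rel_tol 1e-8 and
abs_tol 1e-10 by default; the system mixes scales of ~1e5 (counts) and
~1e2 (percentages).  An independent re-implementation in R (deSolve/lsoda)
agrees with the reference 12-week trajectory to ~9 significant digits;
frozen values from that cross-check are asserted in the test suite at
0.05%.  Refining tolerances moves reported states by <0.1%.  Negative
undershoots beyond tolerance raise a warning rather than being clipped.
Ensemble-scale work (the 1024-corner factorial) runs at rel_tol 1e-6; the
regime labels were spot-checked against tighter tolerances.

Depletion experiments modify the dynamics inside a window, by either
clamping the target population (component and derivative held at zero;
implemented by masking, so dynamics resume cleanly at the window end) or
blocking its influx (source and activation terms zeroed, death retained).
Runs are split into piecewise segments at the window edges; at the entry
instant of a clamp the post-jump state is reported.

## Long-run regimes and classification

The model has two attracting long-run structures: a chronic elevated-immune
state (normal fraction ~30%, reached from the calibrated parameters) and a
quiescent branch (immune near baseline, tissue near-normal), reached from
parameter corners with weak immune activation.  `classify_mode` labels a
trajectory from the tail of N over a window (default weeks 40–50):
"oscillatory" if the peak-to-peak amplitude is ≥1 percentage point,
otherwise "disease_free" (tail mean ≥90%) or "quiescent_low".  The
thresholds are conventions; at the calibrated point the oscillation has
damped to amplitude ≈0.8 by week 40, so the calibrated run itself labels
"quiescent_low" rather than "oscillatory" — the cycling is a transient of
the first ~25 weeks here.  "Asymptotic" quantities are operationalized as
the tail mean over weeks 40–50 of a 50-week run (heat maps report the
week-50 point value).

Several outcomes reported for this model are not reproduced by its own
printed equations and parameters, and the corresponding checks fail
honestly rather than being loosened: the k4 grid sweep places the
normal-tissue optimum at 0.07 (tail-mean N ≈ 52%), not ~0.1 with ~100%
normal; the upper-edge k1 run settles at ~83% regenerating rather than
~75%; the calibrated run's CD8⁺ peak is ~430 cells/mm³, well short of the
>1,200 cells/mm³ seen in the underlying experimental data; the wild-type
(h/10) configuration merely delays the inflammatory surge instead of
suppressing it; and 8% of the factorial corners show a genuine second
damage surge within the first 7 weeks.  These discrepancies are robust to
integrator choice and tolerance and to an independent solver, so they
reflect the printed model, not the numerics.

## Calibration

The objective is per-dataset max-normalized weighted least squares: each
dataset's sum of squared residuals is divided by the square of its largest
observed value, putting counts and percentages on a common scale; weights
default to 1 and datasets are fitted jointly.  Thirteen parameters are free
(k1..k6, dH, dC, dM, dD, h, m, σ); baselines are fixed.  Default bounds are
[½×, 2×] the reference value for rates and [0, 2×] for the damage
parameters.  Integrator failures inside a fit return a large finite penalty
so population methods can continue.

The global stage is seeded differential evolution (population 15·13,
latin-hypercube init, no polish) within an evaluation budget; budgets below
two generations fall back to a seeded latin-hypercube best-of-sample.  The
local stage is bounded trust-region least squares on the stacked residual
vector, chosen over derivative-free simplex refinement because the latter
stalls in 13 dimensions; the local stage never returns a point worse than
its start.  The whole pipeline is reproducible from (seed, budget, bounds,
observations).

## Synthetic data

The generator emulates the pooled literature-style calibration data: weekly
sampling from day 14 to day 84 (11 points per series), one series per
variable — macrophage counts (soleus-style), CD4⁺/CD8⁺ counts
(quadriceps-style), and the three fiber-state percentages.  Counts receive
independent unit-mean multiplicative lognormal noise (default CV 0.2);
percentages receive additive Gaussian noise truncated to [0, 100] (default
sd 3 points).  These scales are typical of cytometry/histology variability;
the source data do not state them.  The generator captures sparseness and
measurement scatter but not between-animal covariance, replicate structure,
muscle-type kinetic differences, or correlated errors within a fiber-state
triplet (noisy triplets need not sum to 100; noise-free ones do).  Passing
recovery tests therefore demonstrate identifiability under idealized
independent noise, not under real pooled-literature heterogeneity.

Recovery at these defaults (5 replicates, budget 4000 global + 2000 local
evaluations, 12-week horizon at rel_tol 1e-6): k4, dC and k5 are recovered
within 50% relative error in at least 4 of 5 replicates; the k4, dC, dH and
k5 medians are ≤25%; dD, h, m and σ are weakly identifiable from 11-point
series (the
damage-shape parameters trade off against each other and against k5), which
is reported rather than asserted.

## Design choices and limitations

- The depletion reproduction pins sustained clamping (whole 12-week
  horizon): the cited antibody protocols ran day 6 to week 4, but the
  protective ~85%-normal outcome arises under sustained absence of the
  macrophage compartment; the windowed variant is exposed and reported by
  the analysis driver (it ends at ~17% normal — the cascade rebounds).
- Initial-condition ensemble ranges (H0 ∈ [0,10], C0 ∈ [1,100],
  M0 ∈ [100,1000] cells/mm³) span reported wild-type immune densities; the
  strict equivalence verdict (identical regime label, peak times within one
  week) fails at these widths because the widest draws shift the
  macrophage surge by up to ~3 weeks, although every draw shares the gross
  picture.
- The factorial ensemble uses exactly the printed Min/Max levels, which are
  close to but not exactly half/double of the calibrated values; they are
  stored verbatim.
- Out of scope: spatial structure, stochastic dynamics, M1/M2 macrophage
  subpopulations, cytokine/chemokine signalling, muscle-type (EDL/TA vs
  soleus) kinetic differences, and any re-derivation of the calibrated
  parameter values from the original literature figures.
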