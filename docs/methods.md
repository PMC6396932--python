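# Methods

## The culture system being modelled

The package models a well-mixed in-vitro liquid culture of murine
hematopoietic progenitors: 5000 LSK cells seeded in a 96-well plate well
with 300 µL of media containing 100 ng/mL stem cell factor (SCF), cultured
for 9 days with periodic full media exchange, and phenotyped by flow
cytometry at days 0.5, 1, 2, 4, 7 and 9.  Cell counts in such cultures span
four orders of magnitude — hundreds of LSK and CMP cells against several
hundred thousand mature ("Terminal") cells — which shapes several numerical
choices below.

Two deterministic, first-order ODE hierarchies are implemented:

- **three-state**: LSK → CMP → Terminal, with a "jump" route LSK → Terminal;
- **five-state**: LT-HSC → ST-HSC → MPP → CMP → Terminal, with jumps from
  ST-HSC and MPP to Terminal, constant proliferation and secretion rates,
  and quiescent fractions on LT-HSC, ST-HSC and MPP.

## State variables and units

Populations are continuous cell numbers per state.  The environment carries
SCF (ng/mL), glucose GC (mM), a constant media volume (µL, default 300),
and four secreted biomolecule pools tracked as amounts (ng): DiffS, DiffI,
ProS, ProI.  Pool concentrations used by the kernels are amount/volume;
SCF consumption (`K_SCF_consumption`, ng/cell/day) is converted to a
concentration derivative through the volume, while glucose consumption
(`K_GC_consumption`, mM/cell/day) folds the volume in.

## Flow wiring

The rate laws supply *fractions* (self-renewal `f`, quiescence `q`, jump
`j`) and *rates* (proliferation `PR`, stepwise differentiation constants
`DR_itoj`, apoptosis `death_i`).  They are combined as:

- the quiescent fraction gates proliferation and differentiation but not
  apoptosis (quiescent cells are biologically inactive; death here is
  environmental, driven by nutrient depletion — a switch
  `quiescence_gates_death` inverts this choice);
- the self-renewal fraction `f` multiplies the proliferative inflow
  `a·f·PR·N` and its complement multiplies the differentiation outflow
  `a·(1−f)·DR·N`, with `a = 1−q` the active fraction;
- the jump fraction splits the differentiation outflow between the direct
  route to Terminal (`j`, at rate `DR_toTerm`) and the stepwise route
  (`1−j`, at rate `DR_tonext`).

With proliferation, apoptosis and quiescence switched off this wiring
transfers cells between states exactly, conserving the total — a property
the test suite checks both algebraically (on the RHS) and on integrated
trajectories.

## Feedback nondimensionalisation

The exponential feedback terms `e^(−[biomolecule])`, `e^(−[SCF]·R_p)` and
`e^(−T_d)` take dimensional arguments; each is divided by a reference scale
(`c_hat` = 1 ng/mL for pool concentrations, `s_hat` = 1 for the SCF×R_p
signal, `t_hat` = 1 for the Terminal feedback signal).  The scales default
to 1 in the stated units and are absorbed into the calibrated feedback
constants, so they are configuration constants, not free parameters.

`T_d`, the Terminal-derived differentiation-stimulator signal that feeds
back on the jump fraction, is by default the instantaneous product
`c3 · #Terminal` (with `c3` the Terminal cells' DiffS secretion rate); a
parameter switch (`td_mode = "diffs_pool"`) reinterprets it as the DiffS
pool concentration instead, since the two readings are both defensible.

## Media exchange

Exchange events are instantaneous resets between integration segments:
SCF and glucose return to their input concentrations and the four secreted
pools are emptied (full media replacement; `reset_pools=False` keeps the
pools, for partial-bookkeeping comparisons).  Populations and volume are
untouched.  This is exact and avoids the stiffness of modelling the pulse
as a forcing term.  A frequency of `f` days produces events at
`f, 2f, … ≤` horizon; a frequency at or beyond the horizon means no
exchange ever occurs.

## Integration

Segments between events are integrated with `scipy.integrate.solve_ivp`
using the implicit BDF method at `rtol = atol = 1e-8` by default.  BDF was
chosen over LSODA because the consumption clamps (SCF and glucose stop
being consumed once exhausted) create derivative kinks at which LSODA's
step-size control can collapse; BDF crosses them robustly.  Populations
and environment stocks are floored at zero — counts below one cell have no
physical meaning and the rate laws would otherwise drive small negatives.
Halving the tolerances moves day-9 counts by far less than 0.1%
(checked in the suite).  Off-grid queries use shape-preserving monotone
cubic (PCHIP) interpolation on the dense output grid (0.05-day spacing
plus all event and requested sample times).

## Calibration

No raw count tables are available for this culture system, only
population-scale anchors, so the packaged default parameter sets are
calibration artifacts: they were fitted to reproduce the anchor scales
(Terminal peak near 6×10⁵ cells; LSK between ~10² and 2×10³ after the
seeding transient; CMP below 300 cells with a spike before day 1) and the
qualitative profiles (biphasic LSK with a day-4 minimum, exponential
Terminal growth, stronger expansion under more frequent exchange, the jump
ablation signatures, and a sensitivity structure in which the Terminal row
carries the fewest high-impact parameters).  They are shipped as versioned
YAML files under `hsckinetics/data/`, not hard-coded.

The fitting objective is the sum of squared log residuals
`log(model + 1) − log(observed + 1)` over all states and times: with counts
spanning 10² to 6×10⁵, linear residuals would be entirely dominated by the
Terminal compartment, while log residuals weight each state comparably; the
1-cell offset keeps empty states finite.  Optional SEM weighting divides
each residual by the relative precision of its summary point.  Optimisation
is bounded least squares (`scipy.optimize.least_squares`, trf), optionally
multi-started from seeded Latin-hypercube draws placed log-uniformly within
the bounds.  Only a declared subset of parameters is fitted; with six time
points per state a full 30+-parameter fit is unidentifiable, so requests
for more than 12 simultaneous free parameters are refused unless forced.
Default bounds are a decade around the initial value, capped at 1 for the
fraction maxima.  If no start improves on the initial loss the initial
parameters are returned with `converged=False` — the final loss therefore
never exceeds the loss at the starting point.

## Sensitivity analysis

For parameter `P` and state output `O(t)`, the per-time sensitivity is
`S_t = [(O′(t) − O(t))/O(t)] / δ` for a one-sided forward perturbation
`P → P(1+δ)` with `δ = 0.01` (central differences available).  The summary
`S` is the signed mean of `S_t` over the sampling days (an absolute-mean
option exists, since either time-average convention is defensible); the
denominator average is trivially `δ` because the perturbation is constant.
Entries with `|S| > 1` are flagged high-impact.  Evaluation times at which
the baseline count is zero are excluded from the average with a warning
rather than treated as infinite.  The matrix costs one extra simulation per
parameter; parameters with a zero current value are not perturbable.

## Synthetic data

The generator emulates the FACS count summaries of the modelled study
design: it simulates a scenario, samples the states at the FACS days, draws
`n` replicate counts per state/time as `count · exp(σZ)` with
`σ = sqrt(ln(1+cv²))` (so the multiplier's CV equals `cv`), and reports the
replicate mean and SEM.  Defaults are `cv = 0.15` and 3 replicates — an
engineering choice, since the study reports only SEM error bars; counts are
positive and span four decades, which motivates multiplicative lognormal
over additive noise.  Four reference scenarios with fixed documented seeds
package the experimental arms (three-state at 2-, 5- and 10-day exchange;
five-state at 2-day).  The five-state seed split of the 5000 LSK cells is
LT/ST/MPP = 10/60/30% by default (configurable); ST-HSC dominance within
the LSK gate is expected, but no exact split is published.

What the generator does *not* emulate: FACS gating error and spillover,
per-cell stochasticity (births/deaths are deterministic rates), replicate
correlation across time points (wells are resampled independently), and
day-to-day animal variability.  Passing recovery tests on these synthetic
data therefore demonstrates correctness of the estimation machinery under
the model's own assumptions, not robustness to real-world measurement
structure.

## Known limitations

- Only the myeloid-oriented compartments are modelled; no lymphoid branch,
  no spatial transport, no stochastic or structured-population (PDE)
  variants.
- The calibrated defaults reproduce anchor scales and orderings, not any
  specific raw dataset; per-parameter values should not be over-read.
- The sensitivity statistic is local and one-at-a-time; it does not probe
  parameter interactions (no Sobol/Morris analysis).
- The identifiability guard is a heuristic cap, not a formal analysis.
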