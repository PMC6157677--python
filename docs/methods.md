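# Methods

## Model

One breeder, one season of `T` discrete steps, no mortality, aging, or
carry-over between seasons: a season is a single fitness draw for a fixed
strategy `c` (clutch size).  The state is the energy reserve `E`, started
at the basic reserve `E_i`, which is also a hard floor (see invariants).

**Decision rule.**  Outside an attempt the breeder forages (`E += f_f`).
An attempt starts as soon as `E ≥ E_i + c·x·t_r` — the full cost of a
successful attempt must be banked up front; ties start the attempt.  The
decision and the first breeding step share a time step, so for the
capital-breeding variant attempt starts fall exactly on the lattice
`t_n = c·x·t_r/f_f + n(1 + c·x/f_f)` used by the closed forms.

**Breeding step.**  Each of the up-to-`t_r` breeding steps first applies
the hazard test (fresh `h` from the hazard model, fresh `u ~ U(0,1)`,
failure iff `h > u`) and, if the nest survives the test, pays the step's
energy flow `E += f_b − c·x` with `f_b = f_f(1 − c/c_max)` (or 0 in the
capital-breeding variant).  This ordering — destruction happens before
the day's provisioning — was a genuinely open design point; we chose
test-first for two reasons:

1. Only a nest that survives all `t_r` tests pays the full `c·x·t_r` and
   drives the reserve to its lowest point; a nest failing on its last
   step does not.  That matches the intended energy dynamics (successful
   nests, and only they, bottom out the reserve).
2. It is the ordering under which the model actually produces the
   season-length reversal.  With pay-then-test, the long-season
   standardized fitness rate is `c·q / (E[min(K, t_r)]·(1 + (c·x−f_b)/f_f))`
   with `K` the geometric failure time — for the default parameters the
   denominator is proportional to `c`, the rate is asymptotically
   independent of `c`, and finite-`T` end effects make large clutches
   strictly worse at *every* season length.  With test-then-pay the rate
   is increasing in `c`, so large clutches genuinely catch up and
   slightly overtake in long seasons, which is the phenomenon the model
   exists to exhibit.

A failing step consumes the time step; the parent neither forages nor
pays care that step.  An attempt still open at step `T` is truncated:
no fledglings, but its paid energy and its steps count.

**Hazard.**  `h ~ Beta(α, β)` with `α = h_m/h_v`, `β = (1−h_m)/h_v`,
redrawn independently every breeding step.  Validation requires the
distribution to be convex and positively skewed (`1 < α < β`, which with
`h_m < 0.5` reduces to `h_v < h_m`).  An optional clutch-size-dependent
mode inflates each draw by `1 + γ·(c−1)/(c_max−1)`, clamped at 1 —
a single interpretable knob that is monotone in `c` and nests the
independent model exactly at `γ = 0`.  A degenerate constant hazard is
provided for deterministic traces and limits.

An important structural fact: because `h` is redrawn i.i.d. every step
and compared against an independent uniform, the per-step failure
indicator is marginally Bernoulli(`h_m`) *regardless of `h_v`*.  Hazard
variance is therefore exactly inert in the simulation law, which is why
fitness curves are insensitive to it (the matching test asserts equality
within Monte-Carlo noise).  The beta correction in the analytic module
answers a different question — it treats `h` as constant within an
attempt — and is kept as the closed-form counterpart, not as a statement
about the simulator.

**Excessive reserve.**  The season's terminal waste is measured from the
end of the last *completed* attempt (success or failure) to step `T`; a
truncated final attempt's steps count as wasted, and a season with no
completed attempt is wasted in full.  The wasted energy is `E_T − E_i`.
A stricter variant, time since the last *successful* attempt, is kept as
the additional statistic `time_since_last_success`; it is systematically
larger (it adds the failed tail of the season) and does not correspond
to the closed forms below.

## Closed forms

With constant `h` and `f_b = 0`, a failure after `k` steps has
probability `p_k = (1−h)^{k−1} h` and success `q = (1−h)^{t_r}`.  Starts
live on the lattice above; the boundary indices are

    n1 = ⌊(T − c·x·t_r/f_f)/(1 + c·x/f_f)⌋            (last possible start)
    n2 = ⌊(T − c·x·t_r/f_f − t_r)/(1 + c·x/f_f)⌋      (last completable start)
    n3 = ⌊(T − c·x·t_r/f_f − t_r)/(1 + c·x/f_f) − t_r⌋ (last fail-and-restart)

Counts are taken as magnitudes (`n1−n2`, `n2−n3`), for which the ratio
identity `(n2−n3)/(n1−n2) ≈ 1 + c·x/f_f` holds (exactly when the spacing
divides `t_r`).  The zeroth-order waste is uniform over the last-success
window: mean `(t_r/2)(1 + c·x/f_f)`, SD `(t_r/√12)(1 + c·x/f_f)`,
independent of `h`; the season fraction is `t_r/(2T)·(1 + c·x/f_f)` and
the fitness loss `ρ_max` times that.  `ρ_max` (maximum breeding success)
has no canonical value; it defaults to 1 so the loss is reported as a
fraction of maximal success.  The weighted refinement mixes the
never-completing tail (waste `t_r/2`, weight `w = 1/(1 + Aq)`,
`A = 1 + c·x/f_f`) with the window (waste `(t_r/2)A`); the beta-hazard
variant replaces `q` by the exact product `E[(1−h)^{t_r}] =
Π_{j<t_r}(β+j)/(α+β+j)`, always above `(1−h_m)^{t_r}` by convexity.
The statement `⟨h²⟩ = h_m² + h_v²` (treating `h_v` as an SD) conflicts
with the beta parameterization, under which `Var(h) =
h_m(1−h_m)/(1/h_v+1)`; the exact product form is canonical here and the
truncated series is exposed only as the diagnostic
`expected_survival_series`.

Foraging-while-breeding is folded back in as a net-flow substitution
`x → x − f_b/c`, so the analytic per-step outflow `c·x − f_b` matches
the simulator exactly and `c = c_max` is a fixed point.  Substitutions
that would make breeding profitable (`c·x ≤ f_b`) are rejected.

## Parameters and defaults

| symbol | default | meaning (units) |
|---|---|---|
| `T` | 500 | season length (steps) |
| `E_i` | 250 | basic/initial reserve (energy) |
| `c`, `c_max` | 1, 10 | clutch size and its cap (offspring) |
| `f_f` | 1 | foraging income (energy/step) |
| `x` | 1 | care cost per offspring (energy/step) |
| `t_r` | 24 | steps to fledge |
| `h_m`, `h_v` | 0.03, 0.01 | hazard mean and beta scale |
| `n` | 10,000 | replicate seasons |
| `predation_gamma` | 0 | hazard inflation at `c = c_max` |
| `forage_while_breeding` | true | `f_b = f_f(1−c/c_max)` vs 0 |

A step is a relative unit, not a calendar day.  Study presets override
only their swept axes.  Levels not fixed by the study designs and chosen
here once: "high predation" `h_m = 0.10`, hazard-variance levels
`h_v ∈ {0.01, 0.02}`, clutch-dependence strength `γ = 1` (hazard doubles
at `c = c_max`).  Each preset records these in its `assumptions`
metadata.

## Randomness and reproducibility

A master seed spawns one child stream per replicate via
`SeedSequence([seed, replicate])`, so any replicate is reproducible in
isolation; sweep cells get seeds from `SeedSequence([master, cell_index])`
with cells enumerated in alphabetical-axis order, making results
independent of axis declaration order and of execution order.  The
hazard and uniform draws for a season are pre-drawn as arrays and
consumed identically by the pure-Python reference loop and the
numba-compiled kernel; the two paths agree bit for bit (asserted in the
tests).  Same seed ⇒ byte-identical CSVs.

## Numerical choices

* Threshold comparison uses a `1e-9` slack so that reserves assembled
  from fractional `f_b` increments still trigger the documented
  tie-breaks ("ties breed"); energy increments are many orders of
  magnitude coarser.
* Energy conservation `E_T − E_i = acquired − invested` holds to 1e−9
  on every replicate; the reserve never drops below `E_i` because the
  threshold pre-banks the worst-case drawdown.
* `E[(1−h)^t]` is computed as a log-sum of the exact product, robust for
  large `t_r`.
* With a single replicate, SDs and SEs are reported as 0.

## What the tests show (and what they do not)

All inputs are generated internally; there is no empirical data.  The
replicate engine *is* the study-condition generator: Full-scale runs
use `n = 10,000` replicates per condition; the shipped tests scale stochastic checks to
`n = 1,000–2,000` replicates (and `n = 50,000` only for the cheap
small-season enumeration check), sizes at which the asserted orderings
are separated by several standard errors.  Passing tests show the model
reproduces its own qualitative structure — the season-length reversal,
hazard-variance inertness, predation- and food-driven optimum shifts,
and simulation/closed-form agreement on wasted time — under the stated
i.i.d.-hazard, single-strategy, single-season assumptions.  They say
nothing about real birds: no density dependence, no within-season
strategy adjustment, no heterogeneity among individuals, no temporal
autocorrelation in the environment, and no evolutionary dynamics (means
of fixed strategies are compared; there is no mutation or invasion
analysis).

## Known limitations

* The closed forms assume constant-within-attempt hazard and the
  capital-breeding lattice; with `f_b > 0` the net-flow substitution
  makes the lattice exact but the hazard-weighted mixture remains an
  approximation.
* The clutch-dependent hazard's linear-inflation form is a modeling
  choice; only its monotonicity is principled.
* `n3`'s trailing `− t_r` is applied inside the floor; the count-ratio
  identity cross-checks this reading.
* Statistical tests use fixed seeds; they are deterministic regressions
  of stochastic claims, not significance tests on fresh randomness.
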