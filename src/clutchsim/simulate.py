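"""Individual-based season simulator and replicate engine.

One season is a loop over ``T`` discrete steps.  Outside an attempt the
breeder forages (``E += f_f``) until the reserve reaches the breeding
threshold ``E_i + c*x*t_r``, at which point an attempt starts and its first
breeding step is taken in the same time step.  Each breeding step first
applies the hazard test -- a fresh hazard draw ``h`` is compared against a
fresh uniform draw ``u`` and the nest fails iff ``h > u`` -- and, if the
nest survives the test, the step's energy flow ``E += f_b - c*x`` is paid.
A failing step therefore consumes the time step but not that step's care
cost: the nest is destroyed by the environment before the day's provisioning
happens.  (Only a nest surviving all ``t_r`` tests pays the full ``c*x*t_r``
and drives the reserve to its lowest point.)  Surviving ``t_r`` steps
fledges ``c`` offspring; failure at any step ends the attempt with none.
Either way, control returns to the forage/breed decision on the next step.
An attempt still open when the season ends is truncated (no fledglings,
but its invested energy and its steps count).

The "excessive reserve" is the season's terminal waste: the time after
the end of the last completed attempt -- the period in which the breeder
can only accumulate reserve (or start a doomed, truncated attempt) that no
completed breeding can ever use -- and the energy held above ``E_i`` at the
final step.  A season in which no attempt completes is wasted in full.
The stricter "time since the last successful attempt" is kept as an
additional per-replicate statistic.

Two equivalent execution paths exist: :func:`run_season` (pure Python,
optionally records a full :class:`SeasonTrace`) and a numba-compiled kernel
used by :func:`run_replicates`.  Both consume the identical pre-drawn
hazard/uniform arrays in the identical order, so their results agree
bit-for-bit; the test suite asserts this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .hazard import HazardModel
from .params import ENERGY_EPS, ModelParams

__all__ = [
    "SeasonTrace",
    "SeasonResult",
    "ReplicateSummary",
    "decide_action",
    "run_season",
    "measure_excessive_reserve",
    "run_replicates",
    "replicate_rng",
    "RESULT_COLUMNS",
]

#: per-replicate output columns, in CSV order
RESULT_COLUMNS = [
    "replicate",
    "fledglings",
    "n_attempts",
    "n_successes",
    "acquired_energy",
    "invested_energy",
    "excessive_reserve_time",
    "excessive_reserve_energy",
    "time_since_last_success",
    "seed",
]

#: statistics summarized over replicates
STATISTICS = [
    "fledglings",
    "n_attempts",
    "n_successes",
    "acquired_energy",
    "invested_energy",
    "excessive_reserve_time",
    "excessive_reserve_energy",
    "time_since_last_success",
]


@dataclass
class SeasonTrace:
    """Full per-step record of one simulated season (1-indexed steps)."""

    energy_series: np.ndarray          # length T+1; energy_series[0] = E_i
    phase_series: list[str]            # length T, "forage" or "breed"
    attempt_log: list[tuple[int, int, str]]  # (start, end, outcome)


@dataclass(frozen=True)
class SeasonResult:
    fledglings: int
    n_attempts: int
    n_successes: int
    acquired_energy: float
    invested_energy: float
    excessive_reserve_time: int          # T - end of last completed attempt
    excessive_reserve_energy: float      # reserve above E_i at season end
    time_since_last_success: int         # stricter variant: from last success
    final_energy: float
    min_energy: float


@dataclass
class ReplicateSummary:
    """Distribution of season statistics over n independent replicates.

    ``stats`` is indexed by statistic name with columns ``mean``, ``sd``,
    ``se`` (= sd/sqrt(n)) and the season-length-standardized ``mean_std``
    (= mean/T) and ``sd_std`` (= sd/sqrt(T)).
    """

    n: int
    T: int
    stats: pd.DataFrame
    table: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame, T: int,
                   keep_table: bool = True) -> "ReplicateSummary":
        n = len(table)
        mean = table[STATISTICS].mean()
        sd = table[STATISTICS].std(ddof=1) if n > 1 else mean * 0.0
        stats = pd.DataFrame(
            {
                "mean": mean,
                "sd": sd,
                "se": sd / np.sqrt(n),
                "mean_std": mean / T,
                "sd_std": sd / np.sqrt(T),
            }
        )
        return cls(n=n, T=T, stats=stats, table=table if keep_table else None)


def decide_action(E: float, params: ModelParams) -> str:
    """Forage/breed decision: breed iff E >= E_i + c*x*t_r (ties breed)."""
    if E >= params.breeding_threshold - ENERGY_EPS:
        return "breed"
    return "forage"


@njit(cache=False)
def _season_kernel(T, E_i, f_f, f_b, cx, t_r, threshold, c, h_arr, u_arr):
    """Simulate one season; consumes one (h, u) pair per breeding step."""
    E = E_i
    draw_idx = 0
    breeding = False
    steps_in = 0
    fledglings = 0
    n_attempts = 0
    n_successes = 0
    acquired = 0.0
    invested = 0.0
    last_success_end = 0
    last_completed_end = 0
    min_E = E
    for t in range(1, T + 1):
        if not breeding:
            if E >= threshold - ENERGY_EPS:
                breeding = True
                steps_in = 0
                n_attempts += 1
            else:
                E += f_f
                acquired += f_f
                if E < min_E:
                    min_E = E
                continue
        # breeding step: hazard test first; survivors pay the care cost
        steps_in += 1
        h = h_arr[draw_idx]
        u = u_arr[draw_idx]
        draw_idx += 1
        if h > u:
            breeding = False          # nest destroyed; offspring lost
            last_completed_end = t
        else:
            E += f_b - cx
            acquired += f_b
            invested += cx
            if steps_in == t_r:
                breeding = False      # fledged
                n_successes += 1
                fledglings += c
                last_success_end = t
                last_completed_end = t
        if E < min_E:
            min_E = E
    return (
        fledglings,
        n_attempts,
        n_successes,
        acquired,
        invested,
        last_completed_end,
        last_success_end,
        E,
        min_E,
        1 if breeding else 0,
        draw_idx,
    )


def _predraw(params: ModelParams, hazard: HazardModel,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Pre-draw hazard and uniform arrays (one pair per potential step)."""
    h_arr = hazard.draw_array(params.c, params.T, rng)
    u_arr = rng.random(params.T)
    return h_arr, u_arr


def run_season(params: ModelParams, hazard: HazardModel | None = None,
               rng: np.random.Generator | None = None,
               keep_trace: bool = False):
    """Simulate one season in pure Python (reference path).

    Returns a :class:`SeasonResult`, or ``(SeasonResult, SeasonTrace)``
    when ``keep_trace`` is true.  Mirrors the compiled kernel operation
    for operation, so results are bit-identical given the same stream.
    """
    if hazard is None:
        hazard = HazardModel.from_params(params)
    if rng is None:
        rng = replicate_rng(params.seed, 0)
    T = params.T
    f_f, f_b = params.f_f, params.f_b
    cx = params.c * params.x
    t_r = params.t_r
    threshold = params.breeding_threshold
    h_arr, u_arr = _predraw(params, hazard, rng)

    E = params.E_i
    draw_idx = 0
    breeding = False
    steps_in = 0
    attempt_start = 0
    fledglings = n_attempts = n_successes = 0
    acquired = invested = 0.0
    last_success_end = 0
    last_completed_end = 0
    min_E = E
    energy = np.empty(T + 1)
    energy[0] = E
    phases: list[str] = []
    attempts: list[tuple[int, int, str]] = []

    for t in range(1, T + 1):
        if not breeding:
            if E >= threshold - ENERGY_EPS:
                breeding = True
                steps_in = 0
                n_attempts += 1
                attempt_start = t
            else:
                E += f_f
                acquired += f_f
                if E < min_E:
                    min_E = E
                energy[t] = E
                phases.append("forage")
                continue
        steps_in += 1
        h = h_arr[draw_idx]
        u = u_arr[draw_idx]
        draw_idx += 1
        if h > u:
            breeding = False
            last_completed_end = t
            attempts.append((attempt_start, t, "failure"))
        else:
            E += f_b - cx
            acquired += f_b
            invested += cx
            if steps_in == t_r:
                breeding = False
                n_successes += 1
                fledglings += params.c
                last_success_end = t
                last_completed_end = t
                attempts.append((attempt_start, t, "success"))
        if E < min_E:
            min_E = E
        energy[t] = E
        phases.append("breed")

    if breeding:
        attempts.append((attempt_start, T, "truncated"))

    result = SeasonResult(
        fledglings=fledglings,
        n_attempts=n_attempts,
        n_successes=n_successes,
        acquired_energy=acquired,
        invested_energy=invested,
        excessive_reserve_time=(
            T - last_completed_end if last_completed_end else T
        ),
        excessive_reserve_energy=E - params.E_i,
        time_since_last_success=T - last_success_end if n_successes else T,
        final_energy=E,
        min_energy=min_E,
    )
    if keep_trace:
        return result, SeasonTrace(energy, phases, attempts)
    return result


def measure_excessive_reserve(trace: SeasonTrace,
                              params: ModelParams) -> tuple[int, float]:
    """Terminal waste of a season: (time steps, energy above E_i).

    Time counts from the end of the last completed attempt (success or
    failure) to the end of the season; a truncated final attempt's steps
    count as wasted.  A season in which no attempt completes is wasted in
    full (time = T).
    """
    ends = [e for (_, e, o) in trace.attempt_log if o in ("success", "failure")]
    wasted_time = params.T - max(ends) if ends else params.T
    wasted_energy = float(trace.energy_series[-1]) - params.E_i
    return wasted_time, wasted_energy


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent stream for one replicate of one run.

    Built from ``SeedSequence([seed, replicate])`` so any replicate is
    reproducible in isolation and runs are order-independent.
    """
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, replicate]))
    )


def run_replicates(params: ModelParams, hazard: HazardModel | None = None,
                   n: int | None = None, seed: int | None = None,
                   keep_table: bool = True) -> ReplicateSummary:
    """Simulate ``n`` independent seasons and summarize their statistics.

    Uses the compiled kernel; each replicate draws from its own child
    stream of the master ``seed`` (default ``params.seed``).
    """
    if hazard is None:
        hazard = HazardModel.from_params(params)
    if n is None:
        n = params.n
    if seed is None:
        seed = params.seed
    T = params.T
    f_f, f_b = params.f_f, params.f_b
    cx = params.c * params.x
    t_r = params.t_r
    threshold = params.breeding_threshold
    E_i = params.E_i
    c = params.c

    rows = np.empty((n, 10))
    for r in range(n):
        rng = replicate_rng(seed, r)
        h_arr, u_arr = _predraw(params, hazard, rng)
        (fled, n_att, n_succ, acq, inv, last_comp, last_succ, E_T, min_E,
         _truncated, _used) = _season_kernel(
            T, E_i, f_f, f_b, cx, t_r, threshold, c, h_arr, u_arr
        )
        wasted = T - last_comp if last_comp else T
        since_succ = T - last_succ if n_succ else T
        rows[r] = (fled, n_att, n_succ, acq, inv, wasted, E_T - E_i,
                   since_succ, E_T, min_E)

    table = pd.DataFrame(
        rows,
        columns=STATISTICS + ["final_energy", "min_energy"],
    )
    table.insert(0, "replicate", np.arange(n))
    table["seed"] = seed
    for col in ("fledglings", "n_attempts", "n_successes",
                "excessive_reserve_time", "time_since_last_success"):
        table[col] = table[col].astype(int)
    return ReplicateSummary.from_table(table, T=T, keep_table=keep_table)
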