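"""Closed-form approximation of end-of-season wasted time.

In the simplified capital-breeding picture (no foraging while breeding),
attempt start times fall on a discrete lattice

    t_n = c*x*t_r/f_f + n * (1 + c*x/f_f),   n = 0, 1, 2, ...

because an attempt failing after k steps loses k*(c*x) energy, which takes
k*(c*x)/f_f foraging steps to recover -- the same delay as k one-step
failures.  Three boundary indices matter at the end of a season of length
T:

* n1 -- last index at which an attempt can start at all;
* n2 -- last index at which an attempt can start *and* run its full t_r
  steps before the season ends;
* n3 -- last index at which an attempt can start and, should it fail at
  the last moment, still restart at or before t_{n2}.

At the zeroth order in season length, the wasted time after the last
completed attempt is uniform over the lattice spanned by (n3, n2], giving
mean (t_r/2)(1 + c*x/f_f) and SD (t_r/sqrt(12))(1 + c*x/f_f) -- linear in
clutch size and independent of the hazard.  A refinement weights the
never-completing tail starts (n2, n1] (waste T - t_n with certainty)
against the last-success window (n3, n2] (waste T - t_n - t_r with
probability q = (1-h)^t_r), yielding a mixture with weight
w = 1 / (1 + A*q) where A = 1 + c*x/f_f.  A stochastic-hazard variant
replaces q by the exact beta expectation E[(1-h)^t_r].

Foraging during breeding is folded back in by a net-flow substitution:
x -> x - f_b/c, so the total per-step outflow c*x - f_b matches the
simulator exactly and the lattice spacing becomes 1 + (c*x - f_b)/f_f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazard import HazardModel, expected_survival_beta, success_probability
from .params import ModelParams

__all__ = [
    "AnalyticWaste",
    "SeasonTooShortError",
    "start_time",
    "boundary_indices",
    "zeroth_order_waste",
    "weighted_waste",
    "stochastic_h_waste",
    "apply_fb_substitution",
    "analytic_waste",
    "analytic_table",
]


class SeasonTooShortError(ValueError):
    """Season too short for even one complete breeding attempt."""


def _origin(params: ModelParams) -> float:
    return params.c * params.x * params.t_r / params.f_f


def _spacing(params: ModelParams) -> float:
    return 1.0 + params.c * params.x / params.f_f


def start_time(n: int, params: ModelParams) -> float:
    """Lattice start time t_n = c*x*t_r/f_f + n*(1 + c*x/f_f)."""
    if n < 0:
        raise ValueError("lattice index must be non-negative")
    return _origin(params) + n * _spacing(params)


def boundary_indices(params: ModelParams,
                     T: int | None = None) -> tuple[int, int, int]:
    """Boundary lattice indices (n1, n2, n3) for a season of length T."""
    if T is None:
        T = params.T
    o = _origin(params)
    A = _spacing(params)
    t_r = params.t_r
    if T <= o + t_r:
        raise SeasonTooShortError(
            f"season_too_short: T={T} <= c*x*t_r/f_f + t_r = {o + t_r}"
        )
    n1 = math.floor((T - o) / A)
    z = (T - o - t_r) / A
    n2 = math.floor(z)
    n3 = math.floor(z - t_r)
    return n1, n2, n3


def zeroth_order_waste(params: ModelParams, T: int | None = None,
                       rho_max: float = 1.0
                       ) -> tuple[float, float, float, float]:
    """Zeroth-order wasted time: (mean, sd, fraction of season, fitness loss).

    mean = (t_r/2)(1 + c*x/f_f); sd = (t_r/sqrt(12))(1 + c*x/f_f);
    fraction = mean/T; loss = rho_max * fraction.  Both mean and sd are
    independent of the hazard, deterministic or stochastic.
    """
    if T is None:
        T = params.T
    A = _spacing(params)
    t_r = params.t_r
    mean = t_r / 2.0 * A
    sd = t_r / math.sqrt(12.0) * A
    fraction = t_r / (2.0 * T) * A
    return mean, sd, fraction, rho_max * fraction


def weighted_waste(params: ModelParams, T: int | None = None,
                   h: float = 0.0) -> tuple[float, float, float]:
    """Wasted time for constant hazard h: (mean, sd, mixture weight w).

    Mixture of the never-completing tail (waste t_r/2 on average, weight
    w) and the last-success window (waste (t_r/2)(1 + c*x/f_f), weight
    1-w), with w = 1 / (1 + (1 + c*x/f_f)(1-h)^t_r) from the lattice count
    ratio (n2-n3)/(n1-n2) = 1 + c*x/f_f.  h -> 1 gives w -> 1 and the
    mean collapses to t_r/2.
    """
    if T is not None:
        boundary_indices(params, T)  # precondition: season long enough
    A = _spacing(params)
    t_r = params.t_r
    q = success_probability(h, t_r)
    w = 1.0 / (1.0 + A * q)
    mean = w * (t_r / 2.0) + (1.0 - w) * (t_r / 2.0) * A
    sd = t_r / math.sqrt(12.0) * A * (A * q / (1.0 + A * q))
    return mean, sd, w


def stochastic_h_waste(params: ModelParams, T: int | None = None,
                       hazard: HazardModel | None = None
                       ) -> tuple[float, float]:
    """Wasted time with beta-distributed hazard: (mean, sd).

    Same mixture as :func:`weighted_waste` with the per-attempt success
    probability replaced by the exact beta expectation E[(1-h)^t_r],
    which exceeds (1 - h_m)^t_r whenever the hazard is genuinely random.
    """
    if T is not None:
        boundary_indices(params, T)
    if hazard is None:
        hazard = HazardModel.from_params(params)
    A = _spacing(params)
    t_r = params.t_r
    q = expected_survival_beta(hazard, t_r)
    w = 1.0 / (1.0 + A * q)
    mean = w * (t_r / 2.0) + (1.0 - w) * (t_r / 2.0) * A
    sd = t_r / math.sqrt(12.0) * A * (A * q / (1.0 + A * q))
    return mean, sd


def apply_fb_substitution(params: ModelParams) -> ModelParams:
    """Fold foraging-while-breeding into the care cost: x -> x - f_b/c.

    The returned copy has ``forage_while_breeding=False`` and an adjusted
    ``x`` such that the net per-step outflow during breeding, c*x - f_b,
    is unchanged; the analytic lattice then uses the same energy flow as
    the simulator.  ``c = c_max`` (where f_b = 0) is a fixed point.
    Degenerate substitutions where breeding would gain energy are
    rejected.
    """
    if not params.forage_while_breeding:
        return params
    net = params.c * params.x - params.f_b
    if net <= 0:
        raise ValueError(
            "non_positive_breeding_outflow: c*x - f_b = "
            f"{net} <= 0; breeding would gain energy"
        )
    return params.replace(x=net / params.c, forage_while_breeding=False)


@dataclass(frozen=True)
class AnalyticWaste:
    """All closed-form wasted-time quantities for one parameter set."""

    lattice_origin: float
    lattice_spacing: float
    n1: int
    n2: int
    n3: int
    q: float
    waste_mean_zeroth: float
    waste_sd_zeroth: float
    waste_mean_weighted: float
    waste_sd_weighted: float
    w: float
    waste_mean_beta: float
    waste_sd_beta: float
    loss_fraction: float


def analytic_waste(params: ModelParams, T: int | None = None,
                   hazard: HazardModel | None = None,
                   rho_max: float = 1.0) -> AnalyticWaste:
    """Assemble every closed-form quantity for one clutch-size strategy.

    Applies the f_b net-flow substitution automatically when the
    parameter set forages while breeding.
    """
    p = apply_fb_substitution(params)
    if T is None:
        T = p.T
    if hazard is None:
        hazard = HazardModel.from_params(p)
    n1, n2, n3 = boundary_indices(p, T)
    mz, sz, _frac, loss = zeroth_order_waste(p, T, rho_max=rho_max)
    mw, sw, w = weighted_waste(p, T, h=p.h_m)
    mb, sb = stochastic_h_waste(p, T, hazard=hazard)
    return AnalyticWaste(
        lattice_origin=_origin(p),
        lattice_spacing=_spacing(p),
        n1=n1,
        n2=n2,
        n3=n3,
        q=success_probability(p.h_m, p.t_r),
        waste_mean_zeroth=mz,
        waste_sd_zeroth=sz,
        waste_mean_weighted=mw,
        waste_sd_weighted=sw,
        w=w,
        waste_mean_beta=mb,
        waste_sd_beta=sb,
        loss_fraction=loss,
    )


def analytic_table(params: ModelParams, c_grid=None, T: int | None = None,
                   rho_max: float = 1.0) -> pd.DataFrame:
    """Closed-form quantities over a clutch-size grid, one row per c."""
    if c_grid is None:
        c_grid = range(1, params.c_max + 1)
    rows = []
    for c in c_grid:
        p_c = params.replace(c=int(c))
        aw = analytic_waste(p_c, T=T, rho_max=rho_max)
        rows.append(
            {
                "c": int(c),
                "n1": aw.n1,
                "n2": aw.n2,
                "n3": aw.n3,
                "q": aw.q,
                "waste_mean_zeroth": aw.waste_mean_zeroth,
                "waste_sd_zeroth": aw.waste_sd_zeroth,
                "waste_mean_weighted": aw.waste_mean_weighted,
                "waste_sd_weighted": aw.waste_sd_weighted,
                "waste_mean_beta": aw.waste_mean_beta,
                "loss_fraction": aw.loss_fraction,
            }
        )
    return pd.DataFrame(rows)
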