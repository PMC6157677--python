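"""Per-step nest-failure hazard: beta-distributed draws and closed forms.

Each breeding time step draws a fresh hazard ``h`` (the current
environmental condition) and the nest fails iff ``h`` exceeds an
independent uniform draw.  Two hazard laws are supported:

* ``independent`` -- h ~ Beta(alpha, beta), identical for every clutch size;
* ``clutch_dependent`` -- the same beta draw inflated by a linear factor
  ``1 + gamma * (c - 1) / (c_ref - 1)`` and clamped to 1, so that larger
  clutches attract proportionally more predation; ``gamma = 0`` recovers
  the independent law exactly.

A degenerate constant hazard (``HazardModel.constant``) is provided for
deterministic traces and for the point-mass limit of the analytic results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HazardModel",
    "draw_hazard",
    "step_failure",
    "failure_time_pmf",
    "success_probability",
    "expected_survival_beta",
    "expected_survival_series",
]


@dataclass(frozen=True)
class HazardModel:
    alpha: float | None          # beta shape 1 = h_m / h_v
    beta: float | None           # beta shape 2 = (1 - h_m) / h_v
    mode: str = "independent"
    gamma: float = 0.0           # clutch-dependence strength
    c_ref: int = 10              # clutch size at which inflation is 1 + gamma
    fixed_h: float | None = None  # degenerate point mass, overrides (alpha, beta)

    def __post_init__(self):
        if self.fixed_h is None:
            if self.alpha is None or self.beta is None:
                raise ValueError("beta hazard requires alpha and beta")
            if not (1.0 < self.alpha < self.beta):
                raise ValueError(
                    "hazard distribution must be convex and positively "
                    f"skewed (1 < alpha < beta); got alpha={self.alpha}, "
                    f"beta={self.beta}"
                )
        elif not (0.0 <= self.fixed_h <= 1.0):
            raise ValueError("fixed hazard must lie in [0, 1]")

    @classmethod
    def from_params(cls, params) -> "HazardModel":
        return cls(
            alpha=params.alpha,
            beta=params.beta,
            mode=params.predation_mode,
            gamma=params.predation_gamma,
            c_ref=params.c_max,
        )

    @classmethod
    def constant(cls, h: float, **kwargs) -> "HazardModel":
        """Point-mass hazard h with probability one (no environmental noise)."""
        return cls(alpha=None, beta=None, fixed_h=float(h), **kwargs)

    @property
    def mean(self) -> float:
        if self.fixed_h is not None:
            return self.fixed_h
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        if self.fixed_h is not None:
            return 0.0
        a, b = self.alpha, self.beta
        return a * b / ((a + b) ** 2 * (a + b + 1.0))

    def clutch_factor(self, c: int) -> float:
        """Multiplicative hazard inflation for clutch size ``c``."""
        if self.mode != "clutch_dependent" or self.c_ref <= 1:
            return 1.0
        if not (1 <= c <= self.c_ref):
            raise ValueError(f"clutch size {c} outside [1, {self.c_ref}]")
        return 1.0 + self.gamma * (c - 1) / (self.c_ref - 1)

    def draw_array(self, c: int, size: int, rng: np.random.Generator) -> np.ndarray:
        """``size`` independent hazard draws for clutch size ``c``."""
        if self.fixed_h is not None:
            base = np.full(size, self.fixed_h)
        else:
            base = rng.beta(self.alpha, self.beta, size)
        factor = self.clutch_factor(c)
        if factor != 1.0:
            base = np.minimum(1.0, base * factor)
        return base


def draw_hazard(model: HazardModel, c: int, rng: np.random.Generator) -> float:
    """One hazard draw (clutch-dependent inflation applied, clamped to 1)."""
    return float(model.draw_array(c, 1, rng)[0])


def step_failure(h: float, rng: np.random.Generator) -> bool:
    """Nest fails this step iff h exceeds a fresh Uniform(0,1) draw."""
    if not (0.0 <= h <= 1.0):
        raise ValueError("hazard must lie in [0, 1]")
    return h > rng.random()


def failure_time_pmf(h: float, k: int, t_r: int) -> float:
    """P(attempt fails on step k): geometric, (1-h)^(k-1) * h, 1 <= k <= t_r."""
    if not (1 <= k <= t_r):
        raise ValueError(f"k={k} outside [1, t_r={t_r}]")
    if not (0.0 <= h <= 1.0):
        raise ValueError("hazard must lie in [0, 1]")
    return (1.0 - h) ** (k - 1) * h


def success_probability(h: float, t_r: int) -> float:
    """P(nest survives all t_r steps): q = (1-h)^t_r."""
    if not (0.0 <= h <= 1.0):
        raise ValueError("hazard must lie in [0, 1]")
    return (1.0 - h) ** t_r


def expected_survival_beta(model: HazardModel, t_r: int) -> float:
    """E[(1-h)^t_r] for h ~ Beta(alpha, beta), by the exact product form.

    Uses E[(1-h)^t] = prod_{j=0}^{t-1} (beta + j) / (alpha + beta + j),
    which follows from the beta-function ratio B(alpha, beta + t)/B(alpha,
    beta).  For a constant hazard this reduces to (1-h)^t_r.  The result
    always exceeds (1 - E[h])^t_r for a non-degenerate beta hazard, by
    convexity of (1-h)^t.
    """
    if t_r < 1:
        raise ValueError("t_r must be a positive integer")
    if model.fixed_h is not None:
        return success_probability(model.fixed_h, t_r)
    a, b = model.alpha, model.beta
    # log-sum for numerical robustness at large t_r
    log_p = 0.0
    for j in range(t_r):
        log_p += math.log(b + j) - math.log(a + b + j)
    return math.exp(log_p)


def expected_survival_series(h_m: float, h_v: float, t_r: int) -> float:
    """Second-order series for E[(1-h)^t_r] treating h_v as an SD.

    Diagnostic only: expands E[(1-h)^t] = 1 - C(t,1)<h> + C(t,2)<h^2> - ...
    and truncates after the quadratic term with <h^2> = h_m^2 + h_v^2.
    This treats h_v as a standard deviation, which is *not* consistent with
    the beta parameterization used everywhere else (there
    Var(h) = h_m(1-h_m)/(1/h_v + 1)); :func:`expected_survival_beta` is the
    canonical expectation.
    """
    return (
        1.0
        - t_r * h_m
        + t_r * (t_r - 1) / 2.0 * (h_m * h_m + h_v * h_v)
    )
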