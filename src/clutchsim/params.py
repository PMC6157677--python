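"""Model parameterization: validation, defaults, and config file round-trip.

The model follows a single breeder through a breeding season of ``T``
discrete time steps.  The breeder alternates between foraging (gaining
``f_f`` energy per step) and breeding attempts of up to ``t_r`` steps, each
step of which costs ``c * x`` energy (clutch size times per-offspring care
cost) while optionally returning a reduced foraging income
``f_b = f_f * (1 - c / c_max)``.  An attempt may only start once the reserve
``E`` exceeds the cost of a full successful attempt,
``E >= E_i + c * x * t_r``.  Per-step nest failure is governed by a hazard
``h`` drawn from a Beta(alpha, beta) distribution with
``alpha = h_m / h_v`` and ``beta = (1 - h_m) / h_v``.

All parameters live in the frozen :class:`ModelParams` dataclass; the
derived quantities ``alpha``, ``beta`` and ``f_b`` are computed properties.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParams",
    "ParamValidationError",
    "validate_params",
    "effective_fb",
    "load_config",
    "write_config",
    "run_metadata",
]

PREDATION_MODES = ("independent", "clutch_dependent")

#: float comparison slack for the breeding threshold; energy is accumulated
#: in increments that are far coarser than this.
ENERGY_EPS = 1e-9


class ParamValidationError(ValueError):
    """Raised when a parameter set violates a model invariant.

    ``violations`` holds one short machine-readable code per failed
    invariant (e.g. ``alpha_not_gt_1``, ``clutch_out_of_range``).
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid model parameters: " + ", ".join(self.violations)
        )


@dataclass(frozen=True)
class ModelParams:
    """One validated model configuration (construct via :func:`validate_params`)."""

    T: int = 500                 # breeding-season length (time steps)
    E_i: float = 250.0           # basic (lowest) reserve; also the initial reserve
    c: int = 1                   # clutch size -- the strategy under evaluation
    c_max: int = 10              # maximum clutch size
    f_f: float = 1.0             # foraging income per foraging step
    x: float = 1.0               # per-offspring care cost per breeding step
    t_r: int = 24                # steps a nest must survive to fledge
    h_m: float = 0.03            # mean per-step nest-failure rate
    h_v: float = 0.01            # beta scale: alpha = h_m/h_v, beta = (1-h_m)/h_v
    n: int = 10_000              # replicate seasons per evaluation
    predation_mode: str = "independent"
    predation_gamma: float = 0.0     # strength of clutch-size dependence of hazard
    forage_while_breeding: bool = True   # f_b = f_f*(1-c/c_max) if True else 0
    seed: int = 0                # master RNG seed

    # -- derived quantities -------------------------------------------------

    @property
    def alpha(self) -> float:
        return self.h_m / self.h_v

    @property
    def beta(self) -> float:
        return (1.0 - self.h_m) / self.h_v

    @property
    def f_b(self) -> float:
        return effective_fb(self)

    @property
    def breeding_threshold(self) -> float:
        """Reserve required to start an attempt: E_i + c*x*t_r."""
        return self.E_i + self.c * self.x * self.t_r

    def as_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def replace(self, **overrides) -> "ModelParams":
        """Return a revalidated copy with ``overrides`` applied."""
        return validate_params({**self.as_dict(), **overrides})


_INT_FIELDS = {"T", "c", "c_max", "t_r", "n", "seed"}
_FLOAT_FIELDS = {"E_i", "f_f", "x", "h_m", "h_v", "predation_gamma"}
_BOOL_FIELDS = {"forage_while_breeding"}
_KNOWN_KEYS = (
    _INT_FIELDS | _FLOAT_FIELDS | _BOOL_FIELDS | {"predation_mode"}
)


def validate_params(raw: Mapping[str, Any]) -> ModelParams:
    """Validate a flat key-value mapping and return a :class:`ModelParams`.

    Missing keys take the documented defaults.  Unknown keys are an error
    (they are almost always typos).  All violated invariants are collected
    and reported together in :class:`ParamValidationError`.
    """
    violations: list[str] = []
    values: dict[str, Any] = {
        f.name: f.default for f in dataclasses.fields(ModelParams)
    }

    for key in raw:
        if key not in _KNOWN_KEYS:
            violations.append(f"unknown_key:{key}")
    if violations:
        raise ParamValidationError(violations)

    for key, val in raw.items():
        try:
            if key in _INT_FIELDS:
                if isinstance(val, bool) or float(val) != int(float(val)):
                    raise ValueError
                values[key] = int(float(val))
            elif key in _FLOAT_FIELDS:
                values[key] = float(val)
            elif key in _BOOL_FIELDS:
                if isinstance(val, bool):
                    values[key] = val
                elif isinstance(val, str) and val.lower() in ("true", "false"):
                    values[key] = val.lower() == "true"
                else:
                    raise ValueError
            else:  # predation_mode
                values[key] = str(val)
        except (TypeError, ValueError):
            violations.append(f"not_parseable:{key}")
    if violations:
        raise ParamValidationError(violations)

    v = values
    if v["T"] < 1:
        violations.append("T_not_positive")
    if v["E_i"] < 0:
        violations.append("E_i_negative")
    if v["c_max"] < 1:
        violations.append("c_max_not_positive")
    if not (1 <= v["c"] <= v["c_max"]):
        violations.append("clutch_out_of_range")
    if v["f_f"] <= 0:
        violations.append("f_f_not_positive")
    if v["x"] <= 0:
        violations.append("x_not_positive")
    if v["t_r"] < 1:
        violations.append("t_r_not_positive")
    if v["n"] < 1:
        violations.append("n_not_positive")
    if v["predation_gamma"] < 0:
        violations.append("gamma_negative")
    if v["predation_mode"] not in PREDATION_MODES:
        violations.append("predation_mode_invalid")

    if v["h_v"] <= 0:
        violations.append("h_v_not_positive")
    if v["h_m"] <= 0:
        violations.append("mean_not_positive")
    elif v["h_m"] >= 0.5:
        violations.append("mean_too_high")
    if v["h_v"] > 0 and v["h_m"] > 0:
        alpha = v["h_m"] / v["h_v"]
        beta = (1.0 - v["h_m"]) / v["h_v"]
        # the hazard distribution must be convex and positively skewed
        if alpha <= 1:
            violations.append("alpha_not_gt_1")
        if alpha >= beta:
            violations.append("alpha_not_lt_beta")

    if violations:
        raise ParamValidationError(violations)
    return ModelParams(**values)


def effective_fb(params: ModelParams) -> float:
    """Foraging income per breeding step: f_f*(1 - c/c_max), or 0 if disabled.

    Declines linearly in clutch size -- the breeding/foraging trade-off --
    and vanishes at the maximum clutch size.
    """
    if not params.forage_while_breeding:
        return 0.0
    return params.f_f * (1.0 - params.c / params.c_max)


def load_config(path) -> ModelParams:
    """Read a flat YAML config and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ParamValidationError(["config_not_a_mapping"])
    return validate_params(raw)


def write_config(params: ModelParams, path) -> None:
    """Write a config that :func:`load_config` reads back identically."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)


def run_metadata(params: ModelParams, seed: int | None = None,
                 assumptions: Mapping[str, Any] | None = None) -> dict:
    """JSON-serializable run metadata emitted alongside every output."""
    from . import __version__

    meta = {
        "package": "clutchsim",
        "version": __version__,
        "params": params.as_dict(),
        "seed": params.seed if seed is None else seed,
    }
    if assumptions:
        meta["assumptions"] = dict(assumptions)
    # round-trip check: everything must be JSON-clean
    json.dumps(meta)
    return meta
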