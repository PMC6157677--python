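"""Parameter sweeps, study presets, and the simulation-vs-analytic comparison.

A sweep is a full factorial over named parameter axes (e.g. clutch size x
season length), each cell evaluated by ``n`` replicate seasons.  Cells get
independent child seeds derived from the master seed and the cell's
position in a canonical (alphabetical-axis) ordering, so results do not
depend on axis declaration order and cells are safe to evaluate in any
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .analytic import analytic_waste, apply_fb_substitution
from .hazard import HazardModel
from .params import ModelParams, ParamValidationError, validate_params
from .simulate import STATISTICS, run_replicates

__all__ = [
    "SweepSpec",
    "run_sweep",
    "preset",
    "PRESET_NAMES",
    "compare_sim_analytic",
    "load_sweep_spec",
    "write_sweep_spec",
]

#: parameters that may be swept
SWEEPABLE = {
    "c", "T", "h_m", "h_v", "f_f", "x", "t_r",
    "predation_gamma", "forage_while_breeding",
}


@dataclass
class SweepSpec:
    """Full-factorial experiment: base parameters plus named axes."""

    base: ModelParams
    axes: dict[str, list]
    n: int = 10_000
    seed: int = 0
    assumptions: dict[str, Any] = field(default_factory=dict)

    def cells(self) -> list[tuple[int, dict[str, Any], ModelParams]]:
        """Enumerate (index, axis-values, params) in canonical order.

        Every cell is validated before any simulation starts, so an
        invalid corner aborts the whole sweep up front with the offending
        cell named.
        """
        names = sorted(self.axes)
        for name in names:
            if name not in SWEEPABLE:
                raise ValueError(f"axis not sweepable: {name}")
        out = []
        index = 0

        def rec(i: int, acc: dict):
            nonlocal index
            if i == len(names):
                try:
                    cell_params = self.base.replace(**acc)
                except ParamValidationError as err:
                    raise ParamValidationError(
                        [f"cell {acc}: {v}" for v in err.violations]
                    ) from err
                out.append((index, dict(acc), cell_params))
                index += 1
                return
            for value in self.axes[names[i]]:
                acc[names[i]] = value
                rec(i + 1, acc)
            del acc[names[i]]

        rec(0, {})
        return out


def _cell_seed(master_seed: int, cell_index: int) -> int:
    """Stable independent seed for one sweep cell (kept below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), int(cell_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Evaluate a sweep; one output row per (cell x statistic).

    Columns: the swept axis values, ``cell``, ``cell_seed``, ``n``,
    ``statistic`` and its raw ``mean``/``sd``/``se`` plus the
    season-length-standardized ``mean_std`` (/T) and ``sd_std``
    (/sqrt(T)).  Deterministic given the master seed.
    """
    cells = spec.cells()
    rows = []
    for index, axis_values, cell_params in cells:
        seed = _cell_seed(spec.seed, index)
        summary = run_replicates(
            cell_params, n=spec.n, seed=seed, keep_table=False
        )
        for stat in STATISTICS:
            row = dict(axis_values)
            row.update(
                cell=index,
                cell_seed=seed,
                n=spec.n,
                T=cell_params.T,
                statistic=stat,
                mean=summary.stats.loc[stat, "mean"],
                sd=summary.stats.loc[stat, "sd"],
                se=summary.stats.loc[stat, "se"],
                mean_std=summary.stats.loc[stat, "mean_std"],
                sd_std=summary.stats.loc[stat, "sd_std"],
            )
            rows.append(row)
    return pd.DataFrame(rows)


# -- study presets ----------------------------------------------------------

PRESET_NAMES = (
    "energy_budget",     # acquired/invested energy across c and T
    "season_length",     # fitness vs c for short/medium/long seasons,
                         # crossed with hazard mean/variance levels
    "predation",         # clutch-size-independent vs -dependent hazard
    "food",              # three food-availability levels x two seasons
    "waste_comparison",  # simulated vs analytic end-of-season waste
)

# Undocumented study levels adopted here (recorded in each spec's
# assumptions): the "high predation" hazard mean, the hazard-variance
# levels, and the clutch-dependence strength.
_HIGH_HM = 0.10
_HV_LEVELS = [0.01, 0.02]
_GAMMA = 1.0


def preset(name: str, n: int | None = None, seed: int = 0) -> SweepSpec:
    """Return the sweep spec for one canned study design.

    ``n`` overrides the replicate count (default: the full-scale 10,000)
    for reduced-scale runs.
    """
    base = validate_params({})
    c_axis = list(range(1, base.c_max + 1))
    if name == "energy_budget":
        spec = SweepSpec(
            base=base,
            axes={"c": c_axis, "T": [500, 10_000]},
            assumptions={},
        )
    elif name == "season_length":
        spec = SweepSpec(
            base=base,
            axes={
                "c": c_axis,
                "T": [500, 1_500, 10_000],
                "h_m": [0.03, _HIGH_HM],
                "h_v": list(_HV_LEVELS),
            },
            assumptions={
                "h_m_levels": [0.03, _HIGH_HM],
                "h_v_levels": list(_HV_LEVELS),
            },
        )
    elif name == "predation":
        spec = SweepSpec(
            base=base.replace(predation_mode="clutch_dependent"),
            axes={
                "c": c_axis,
                "T": [500, 10_000],
                "h_m": [0.03, _HIGH_HM],
                "predation_gamma": [0.0, _GAMMA],
            },
            assumptions={"high_predation_h_m": _HIGH_HM, "gamma": _GAMMA},
        )
    elif name == "food":
        spec = SweepSpec(
            base=base,
            axes={"c": c_axis, "T": [500, 10_000], "f_f": [1.0, 2.0, 3.0]},
            assumptions={},
        )
    elif name == "waste_comparison":
        spec = SweepSpec(
            base=base.replace(T=10_000),
            axes={"c": c_axis, "forage_while_breeding": [True, False]},
            assumptions={},
        )
    else:
        raise ValueError(f"unknown preset: {name!r} (choose from {PRESET_NAMES})")
    if n is not None:
        spec.n = n
    spec.seed = seed
    return spec


def compare_sim_analytic(spec: SweepSpec, rho_max: float = 1.0,
                         band: str = "zeroth") -> pd.DataFrame:
    """Simulated vs closed-form end-of-season waste, per clutch size.

    The spec must sweep ``c`` (optionally crossed with
    ``forage_while_breeding``).  For each cell the simulated mean +/- SD
    of the excessive reserve of time is set against the zeroth-order,
    constant-h weighted, and beta-corrected analytic values;
    ``within_band`` flags |sim_mean - analytic_mean| <= analytic_sd for
    the chosen ``band`` ("zeroth" or "weighted").
    """
    if "c" not in spec.axes:
        raise ValueError("comparison sweep must include a 'c' axis")
    extra = set(spec.axes) - {"c", "forage_while_breeding", "T"}
    if extra:
        raise ValueError(f"comparison sweep cannot include axes: {extra}")
    table = run_sweep(spec)
    waste = table[table.statistic == "excessive_reserve_time"]
    rows = []
    for _, r in waste.iterrows():
        overrides = {
            k: (r[k].item() if hasattr(r[k], "item") else r[k])
            for k in spec.axes
        }
        cell_params = spec.base.replace(**overrides)
        aw = analytic_waste(cell_params, rho_max=rho_max)
        band_mean, band_sd = {
            "zeroth": (aw.waste_mean_zeroth, aw.waste_sd_zeroth),
            "weighted": (aw.waste_mean_weighted, aw.waste_sd_weighted),
        }[band]
        rows.append(
            {
                "c": int(r["c"]),
                "forage_while_breeding": bool(
                    r.get("forage_while_breeding",
                          spec.base.forage_while_breeding)
                ),
                "T": int(r["T"]),
                "n": int(r["n"]),
                "sim_mean": r["mean"],
                "sim_sd": r["sd"],
                "zeroth_mean": aw.waste_mean_zeroth,
                "zeroth_sd": aw.waste_sd_zeroth,
                "weighted_mean": aw.waste_mean_weighted,
                "weighted_sd": aw.waste_sd_weighted,
                "beta_mean": aw.waste_mean_beta,
                "beta_sd": aw.waste_sd_beta,
                "within_band": bool(abs(r["mean"] - band_mean) <= band_sd),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["forage_while_breeding", "c"], ignore_index=True
    )


# -- sweep spec (de)serialization -------------------------------------------

def load_sweep_spec(path) -> SweepSpec:
    """Read a sweep spec from YAML: {params: {...}, axes: {...}, n, seed}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = validate_params(raw.get("params", {}))
    return SweepSpec(
        base=base,
        axes={k: list(v) for k, v in (raw.get("axes") or {}).items()},
        n=int(raw.get("n", base.n)),
        seed=int(raw.get("seed", base.seed)),
        assumptions=dict(raw.get("assumptions", {})),
    )


def write_sweep_spec(spec: SweepSpec, path) -> None:
    doc = {
        "params": spec.base.as_dict(),
        "axes": spec.axes,
        "n": spec.n,
        "seed": spec.seed,
        "assumptions": spec.assumptions,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
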