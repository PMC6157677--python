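"""Season loop semantics: deterministic traces, conservation, oracle checks."""

import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clutchsim import (
    HazardModel,
    decide_action,
    measure_excessive_reserve,
    replicate_rng,
    run_replicates,
    run_season,
    validate_params,
)
from clutchsim.simulate import _predraw, _season_kernel


class TestDecideAction:
    @pytest.mark.parametrize(
        ("E", "c", "expected"),
        [
            (250.0, 2, "forage"),    # threshold 298
            (298.0, 2, "breed"),     # boundary: ties breed
            (489.9, 10, "forage"),   # threshold 490
            (490.0, 10, "breed"),
        ],
    )
    def test_threshold(self, defaults, E, c, expected):
        assert decide_action(E, defaults.replace(c=c)) == expected


class TestDeterministicSeason:
    """h = 0, c = 10, f_b = 0: the season schedule is fully hand-traceable.

    Forage 240 steps (E: 250 -> 490), breed steps 241-264 (success, E back
    to 250), forage 241-500 without reaching the threshold again.
    """

    @pytest.fixture()
    def outcome(self, no_hazard):
        p = validate_params({"c": 10, "forage_while_breeding": False})
        result, trace = run_season(p, hazard=no_hazard, keep_trace=True)
        return p, result, trace

    def test_single_successful_attempt(self, outcome):
        _, result, trace = outcome
        assert result.fledglings == 10
        assert result.n_attempts == 1
        assert result.n_successes == 1
        assert trace.attempt_log == [(241, 264, "success")]

    def test_energy_schedule(self, outcome):
        _, result, trace = outcome
        E = trace.energy_series
        assert E[0] == 250.0
        assert E[240] == 490.0          # threshold reached
        assert E[264] == 250.0          # reserve at its lowest after success
        assert E[500] == 486.0
        assert result.acquired_energy == 476.0
        assert result.invested_energy == 240.0
        assert trace.phase_series.count("breed") == 24

    def test_excessive_reserve(self, outcome):
        p, result, trace = outcome
        assert result.excessive_reserve_time == 236
        assert result.time_since_last_success == 236
        assert result.excessive_reserve_energy == 236.0
        assert measure_excessive_reserve(trace, p) == (236, 236.0)

    def test_truncated_attempt_wastes_whole_season(self, no_hazard):
        """Season ending mid-attempt: no fledglings, everything wasted."""
        p = validate_params({"c": 10, "T": 250, "forage_while_breeding": False})
        result, trace = run_season(p, hazard=no_hazard, keep_trace=True)
        assert trace.attempt_log == [(241, 250, "truncated")]
        assert result.fledglings == 0
        assert result.invested_energy == 100.0   # 10 surviving steps paid
        assert result.excessive_reserve_time == 250
        assert measure_excessive_reserve(trace, p)[0] == 250

    def test_certain_failure_never_fledges(self):
        p = validate_params({"c": 10, "forage_while_breeding": False})
        result = run_season(p, hazard=HazardModel.constant(1.0))
        assert result.fledglings == 0
        assert result.n_successes == 0
        # attempts keep completing (failing) right up to the season's end
        assert result.excessive_reserve_time == 0
        assert result.time_since_last_success == p.T


class TestKernelEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize(
        "overrides",
        [
            {"c": 3},
            {"c": 10, "forage_while_breeding": False},
            {"c": 2, "h_m": 0.2, "h_v": 0.05, "T": 300},
            {"c": 5, "predation_mode": "clutch_dependent",
             "predation_gamma": 1.5},
        ],
    )
    def test_python_and_compiled_paths_agree(self, overrides, seed):
        """Reference loop and compiled kernel agree bit-for-bit."""
        p = validate_params(overrides)
        hz = HazardModel.from_params(p)
        result = run_season(p, hz, replicate_rng(seed, 0))
        h_arr, u_arr = _predraw(p, hz, replicate_rng(seed, 0))
        (fled, n_att, n_succ, acq, inv, last_comp, last_succ, E_T, min_E,
         _trunc, _used) = _season_kernel(
            p.T, p.E_i, p.f_f, p.f_b, p.c * p.x, p.t_r,
            p.breeding_threshold, p.c, h_arr, u_arr,
        )
        assert result.fledglings == fled
        assert result.n_attempts == n_att
        assert result.n_successes == n_succ
        assert result.acquired_energy == acq
        assert result.invested_energy == inv
        assert result.final_energy == E_T
        assert result.min_energy == min_E
        assert result.excessive_reserve_time == (
            p.T - last_comp if last_comp else p.T
        )


season_cases = st.builds(
    dict,
    T=st.integers(20, 200),
    E_i=st.floats(0, 50, allow_nan=False),
    c=st.integers(1, 6),
    f_f=st.sampled_from([0.5, 1.0, 2.0]),
    x=st.sampled_from([0.5, 1.0, 2.0]),
    t_r=st.integers(1, 8),
    h_m=st.floats(0.02, 0.4, allow_nan=False),
    h_v=st.floats(0.002, 0.015, allow_nan=False),
    forage_while_breeding=st.booleans(),
    seed=st.integers(0, 10_000),
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(raw=season_cases)
def test_energy_conservation_and_floor(raw):
    """E_T - E_i = acquired - invested exactly; the reserve never dips
    below the basic level E_i (worst drawdown <= c*x*t_r by the threshold
    rule)."""
    raw = dict(raw, c_max=6, n=1)
    params = validate_params(raw)
    result = run_season(params)
    assert result.final_energy - params.E_i == pytest.approx(
        result.acquired_energy - result.invested_energy, abs=1e-9
    )
    assert result.min_energy >= params.E_i - 1e-9


# -- independent enumeration oracle ----------------------------------------
#
# For a constant hazard and integer energy flows, the season is a renewal
# process over attempt start times.  The full distribution of the number of
# successes can be enumerated exactly: an attempt starting at step s either
# fails on step k (probability (1-h)^(k-1) h, paying k-1 care steps, hence
# restarting after ceil((k-1)*net/f_f) foraging steps), succeeds after t_r
# steps (probability (1-h)^t_r), or survives to the end of the season
# without completing.

def enumerate_success_distribution(T, t_r, h, net, f_f, first_start):
    @lru_cache(maxsize=None)
    def dist(start):
        if start > T:
            return ((0, 1.0),)
        rem = T - start + 1
        out = {}
        for k in range(1, min(t_r, rem) + 1):
            p_k = (1 - h) ** (k - 1) * h
            nxt = start + k + math.ceil((k - 1) * net / f_f)
            for s, p in dist(nxt):
                out[s] = out.get(s, 0.0) + p_k * p
        if rem >= t_r:
            q = (1 - h) ** t_r
            nxt = start + t_r + math.ceil(t_r * net / f_f)
            for s, p in dist(nxt):
                out[s + 1] = out.get(s + 1, 0.0) + q * p
        else:
            out[0] = out.get(0, 0.0) + (1 - h) ** rem
        return tuple(sorted(out.items()))

    return dict(dist(first_start))


class TestEnumerationOracle:
    def test_success_distribution_matches_enumeration(self):
        """Simulated n_successes distribution matches exact enumeration
        (total variation < 0.01 at n = 50,000 seasons)."""
        p = validate_params(
            {"c": 2, "T": 60, "t_r": 5, "forage_while_breeding": False,
             "n": 1}
        )
        h = 0.2
        net = p.c * p.x  # f_b = 0
        first_start = math.ceil(p.c * p.x * p.t_r / p.f_f) + 1
        exact = enumerate_success_distribution(
            p.T, p.t_r, h, net, p.f_f, first_start
        )
        assert sum(exact.values()) == pytest.approx(1.0, abs=1e-12)

        summary = run_replicates(
            p, hazard=HazardModel.constant(h), n=50_000, seed=9
        )
        counts = summary.table["n_successes"].value_counts(normalize=True)
        support = set(exact) | set(counts.index)
        tv = 0.5 * sum(
            abs(exact.get(s, 0.0) - counts.get(s, 0.0)) for s in support
        )
        assert tv < 0.01

        mean_exact = sum(s * pr for s, pr in exact.items())
        se = summary.stats.loc["n_successes", "se"]
        assert abs(summary.stats.loc["n_successes", "mean"] - mean_exact) < 3 * se


class TestReplicates:
    def test_same_seed_is_bit_identical(self, defaults):
        p = defaults.replace(c=3, T=200)
        a = run_replicates(p, n=50, seed=123)
        b = run_replicates(p, n=50, seed=123)
        assert a.table.equals(b.table)
        assert a.stats.equals(b.stats)

    def test_single_replicate_convention(self, defaults):
        summary = run_replicates(defaults.replace(c=2, T=200), n=1, seed=5)
        assert (summary.stats["sd"] == 0.0).all()
        assert (summary.stats["se"] == 0.0).all()

    def test_degenerate_hazard_has_zero_spread(self, defaults, no_hazard):
        summary = run_replicates(
            defaults.replace(c=4), hazard=no_hazard, n=20, seed=0
        )
        assert summary.stats.loc["fledglings", "sd"] == 0.0

    def test_standardization_identities(self, defaults):
        summary = run_replicates(defaults.replace(c=2), n=40, seed=8)
        stats = summary.stats
        np.testing.assert_allclose(stats["mean_std"], stats["mean"] / 500)
        np.testing.assert_allclose(stats["sd_std"], stats["sd"] / np.sqrt(500))
        np.testing.assert_allclose(stats["se"], stats["sd"] / np.sqrt(40))

    def test_attempts_fall_and_income_rises_with_clutch_size(self, defaults):
        """Larger clutches need longer preparation (fewer attempts) but
        forage at full efficiency for more of the season (higher income)."""
        attempts, acquired = [], []
        for c in range(1, 11):
            s = run_replicates(defaults.replace(c=c), n=2_000, seed=17,
                               keep_table=False)
            attempts.append(s.stats.loc["n_attempts"])
            acquired.append(s.stats.loc["acquired_energy"])
        for lo, hi in zip(attempts, attempts[1:]):
            se_diff = math.hypot(lo["se"], hi["se"])
            assert hi["mean"] <= lo["mean"] + 3 * se_diff
        assert attempts[-1]["mean"] < attempts[0]["mean"]
        for lo, hi in zip(acquired, acquired[1:]):
            se_diff = math.hypot(lo["se"], hi["se"])
            assert hi["mean"] >= lo["mean"] - 3 * se_diff
        assert acquired[-1]["mean"] > acquired[0]["mean"]
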