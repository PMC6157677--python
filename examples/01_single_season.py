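"""One simulated breeding season, step by step.

Runs a single season for a mid-sized clutch under the default stochastic
hazard, prints the attempt log and the season summary, and shows where
the terminal "excessive reserve" comes from.
"""

from clutchsim import HazardModel, run_season, validate_params

params = validate_params({"c": 6, "seed": 42})
result, trace = run_season(
    params, hazard=HazardModel.from_params(params), keep_trace=True
)

print(f"clutch size c={params.c}, season T={params.T}, hazard mean {params.h_m}")
print("\nattempt log (start, end, outcome):")
for start, end, outcome in trace.attempt_log:
    print(f"  steps {start:3d}-{end:3d}: {outcome}")

print(f"\nfledglings            : {result.fledglings}")
print(f"attempts / successes  : {result.n_attempts} / {result.n_successes}")
print(f"acquired energy       : {result.acquired_energy:.1f}")
print(f"invested energy       : {result.invested_energy:.1f}")
print(f"excessive reserve     : {result.excessive_reserve_time} steps, "
      f"{result.excessive_reserve_energy:.1f} energy")

# The excessive reserve is the tail of the season after the last completed
# attempt: time and energy that no completed breeding could use.
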