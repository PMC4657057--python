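"""What parallel execution costs the method: the batch replay.

Learning from previous resamples is inherently serial: resamples solved
simultaneously cannot learn from each other.  The replay freezes the
training pool at batch boundaries of size C (the core count) and re-runs
the schedule, showing how the total function-evaluation cost grows as
parallelism increases — up to C = B, where nothing is ever learned and
the fingerprints are pure overhead.
"""

import fpboot as fb

data = fb.simulate_exponential(theta=2.0, n=100, seed=7)
model = fb.get_model("exponential")
plan = fb.VariantPlan(option="warm_start", g=1, B=200, seed=1)

baseline = fb.run(fb.VariantPlan(option="original_optimum", B=200, seed=1), model, data)
base_cost = fb.total_cost(baseline.records)
print(f"original-optimum baseline: {base_cost} evaluations\n")

for cores in (1, 5, 20, 100, 200):
    replay = fb.parallel_replay(plan, model, data, cores=cores)
    cost = fb.total_cost(replay.records)
    print(f"C={cores:3d} cores: total cost {cost:5d}  "
          f"(speed-up vs baseline x{base_cost / cost:.2f})")

print("\nWith every resample in one batch (C=B) the warm-start variant is "
      "slower than the baseline: fingerprints are paid for, predictions "
      "never materialize.")
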