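"""Generate the volatility-modulated conflict task and one synthetic subject.

Builds the counterbalanced 8-run design (16-trial 50% burn-in plus four
20-trial blocks per run; stable runs fixed at 20% or 80% incongruent,
volatile runs alternating every block), simulates reaction speeds and
accuracy, and writes the trial table as CSV.
"""

import numpy as np

import flexcontrol as fc

trials = fc.make_experiment(seed=0, subject_id="demo")
post = trials[trials["block_index"] > 1]
print(f"trials: {len(trials)} (8 runs x 96)")
print("incongruent proportion by run type (post burn-in):")
print(post.groupby("run_type")["congruency"].mean().to_string())
print("block proportions of run 1:")
print(trials[trials.run_index == 1].groupby("block_index")["congruency"].mean().round(2).to_string())

sim = fc.simulate_subject(trials, fc.GeneratorParams(), np.random.default_rng(0))
sim = fc.apply_exclusions(sim)
print(f"\nsimulated accuracy: {sim['correct'].mean():.3f} (error rate 5.8% injected)")
print("exclusion breakdown:")
print(sim["exclusion_reason"].value_counts().to_string())
ret = sim[~sim["excluded"]]
by_c = ret.groupby("congruency")["rt_ms"].mean()
print(f"\nmean RT congruent {by_c[0]:.0f} ms, incongruent {by_c[1]:.0f} ms "
      "(conflict slows responding)")

fc.write_trials(sim, "demo_trials.csv")
print("\nwrote demo_trials.csv")
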