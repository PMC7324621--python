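"""Fitting the hierarchical DDM with an inverted-U drift regression.

Simulates 5 subjects x 240 trials whose drift is a quadratic function of
centred SC (true beta1 = 0.3, beta2 = -1.0) with instruction-dependent
boundaries, fits the matching model, and prints convergence diagnostics and
the posterior of the regression coefficients.  Takes about half a minute.
"""

import numpy as np

from sceneddm import (
    BehaviourGenSpec,
    ModelSpec,
    Regression,
    assign_conditions,
    build_model,
    build_trial_schedule,
    fit,
    gelman_rubin,
    generate_behaviour,
    generate_stat_pool,
    posterior_p,
)

pool = generate_stat_pool(2000, seed=0)
stim = assign_conditions(pool, n_per_condition=40, mode="joint", seed=1)
schedule = build_trial_schedule(stim, seed=2)
gen = BehaviourGenSpec(beta1=0.3, beta2=-1.0, n_subjects=5, seed=3)
data = generate_behaviour(gen, schedule)
data = data[data["response"] >= 0]
print(f"simulated {len(data)} trials, accuracy {data.response.mean():.3f}")

spec = ModelSpec(regressions={"v": Regression("SC", "linear+quadratic")})
model = build_model(data, spec)
trace = fit(model, chains=4, iterations=1500, burn=200, seed=4, tune=500)
print(f"retained {trace.n_retained} samples "
      f"({trace.chains} chains x {trace.iterations - trace.burn})")

rhat = gelman_rubin(trace)
print(f"max group-level Rhat: {max(rhat.values()):.4f} (convergence band 0.98-1.02)")

print("\nposterior of the group-level regression coefficients:")
for name, truth in (("beta_v_lin", gen.beta1), ("beta_v_quad", gen.beta2)):
    x = trace.get(name)
    P, direction, _, _ = posterior_p(trace, name)
    lo, hi = np.percentile(x, [2.5, 97.5])
    print(f"  {name}: mean {x.mean():+.3f} [95% CI {lo:+.3f}, {hi:+.3f}], "
          f"true {truth:+.1f}, P({'>' if direction == 'negative' else '<'}0) = {P:.4f}")

print("\nA negative quadratic coefficient with P < 0.01 recovers the inverted-U: "
      "drift is highest\nat intermediate scene complexity and drops for sparse and "
      "cluttered scenes alike.")
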