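"""Posterior predictive checks and the decay-swap counterfactual.

After fitting, full sessions are re-simulated from posterior draws to check
that the model reproduces the observed learning curves, and the older group
is re-simulated with the young group's decay rate to show how much of the
group difference the single decay parameter accounts for.
"""

import numpy as np

from rlwm import McmcConfig, counterfactual_swap, fit, posterior_predictive_curves
from rlwm.behavior import empirical_learning_curves
from rlwm.cohort import CohortSpec, generate_cohort

spec = CohortSpec(n_young=14, n_older=14,
                  n_missing_brain_young=0, n_missing_brain_older=0)
cohort = generate_cohort(spec, seed=13)
posterior = fit(
    cohort.behavior,
    variant="two_group",
    mcmc=McmcConfig(n_chains=2, n_warmup=250, n_kept=500, seed=2),
)

curves = posterior_predictive_curves(posterior, cohort.plans, n_draws=80, seed=1)
observed = empirical_learning_curves(cohort.behavior)
print("posterior predictive check (iterations of the observed curve inside"
      " the 95% band):")
for key in sorted(curves):
    pc, oc = curves[key], observed[key]
    inside = int(((oc.mean >= pc.lo) & (oc.mean <= pc.hi)).sum())
    print(f"  {key[0]} set size {key[1]}: {inside}/9")

phi_means = posterior.group_level_mean("phi").mean(axis=(0, 1))
print("\nfitted group-level decay means:",
      {g: round(float(m), 3) for g, m in zip(posterior.group_names, phi_means)})

own = counterfactual_swap(posterior, "older", "older", "phi", cohort.plans,
                          seed=3, n_reps=10)
swap = counterfactual_swap(posterior, "young", "older", "phi", cohort.plans,
                           seed=3, n_reps=10)


def ss6_curve(records):
    learn = records[(records.phase == "learn") & (records.set_size == 6)]
    return learn.groupby("iteration").reward.mean().to_numpy()


print("\nolder-group set-size-6 learning curve, own vs young decay rate:")
print("  own decay:  ", np.round(ss6_curve(own), 2))
print("  young decay:", np.round(ss6_curve(swap), 2))
print("slower forgetting alone lifts the older curve toward the young one")
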