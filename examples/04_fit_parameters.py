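"""Recover growth-model parameters from noisy leaf-area trajectories.

Generates a daily observation table with 2% multiplicative noise from a
known parameter set, perturbs the starting values by +-30% and runs the
generalized least squares estimator; prints the recovered values next to
the truth with relative standard errors and fit diagnostics.
"""

import numpy as np

from rosettrack import (Environment, GrowthParams, fit_parameters,
                        generate_area_dataset)

env = Environment.constant_photoperiod(504)
truth = GrowthParams()
obs, _ = generate_area_dataset(truth, env, noise_cv=0.02, seed=7)
print(f"{obs.n} observations across "
      f"{len(set(obs.ranks.tolist()))} leaves")

init = truth.theta() * np.array([1.3, 1 / 1.3] * 4)
result = fit_parameters(obs, env, template=truth, init=init, n_starts=1)

print(f"{'parameter':>20} {'truth':>10} {'estimate':>10} {'rel. SE':>8}")
for name in GrowthParams.ESTIMABLE:
    print(f"{name:>20} {getattr(truth, name):10.4g} "
          f"{result.estimates[name]:10.4g} "
          f"{result.relative_errors[name]:8.1%}")
print(f"efficiency {result.efficiency:.4f}, accuracy {result.accuracy:.4f}, "
      f"NRMSE {result.nrmse:.4f}")
# Efficiency near 1 means the fitted trajectories explain almost all the
# variance; accuracy near 1 means predictions are unbiased on average.
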