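"""Estimate a haemodynamic response function from trial-averaged epochs.

Simulates 18 noisy responses to a brief full-field flash (the HRF
localiser design), averages them and fits the double-gamma model, as done
per participant before pRF fitting.
"""

import numpy as np

from stereoprf import HRFParams, Timeseries, double_gamma, estimate_hrf

true = HRFParams(peak_delay=5.4, undershoot_delay=15.0, undershoot_ratio=0.3)
dt, n_samples = 0.5, 64
t = np.arange(n_samples) * dt
rng = np.random.default_rng(11)
peak = double_gamma(t, true).max()
epochs = [
    Timeseries(double_gamma(t, true) + rng.normal(0, 0.2 * peak, n_samples), dt)
    for _ in range(18)
]

fit, resid, converged = estimate_hrf(epochs)
print(f"converged: {converged} (residual norm {resid:.3f})")
print(f"peak delay        true {true.peak_delay:.2f} s   fitted {fit.peak_delay:.2f} s")
print(f"undershoot delay  true {true.undershoot_delay:.2f} s  fitted {fit.undershoot_delay:.2f} s")
print(f"undershoot ratio  true {true.undershoot_ratio:.2f}    fitted {fit.undershoot_ratio:.2f}")
# the fitted parameters define the participant-specific kernel that
# convolves every pRF model prediction
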