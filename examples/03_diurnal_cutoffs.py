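"""Dynamically tailored classification cutoffs from a diurnal rhythm.

Fits the cosinor model theta = b0 + b1 sin(2*pi*h/24) + b2 cos(2*pi*h/24)
to a person's accumulated momentary scores, then derives a person- and
time-specific cutoff: expected level + 0.5 residual SDs.
"""

import numpy as np

from jitaema import CutoffSpec, dynamic_cutoff, fit_cosinor, is_classifiable, predict_cosinor

rng = np.random.default_rng(3)

# two weeks of observed momentary fatigue scores with an afternoon peak
hours = rng.uniform(6, 22, size=70)
scores = 0.2 + 0.5 * np.sin(2 * np.pi * (hours - 9) / 24) + rng.normal(0, 0.4, size=70)

fit = fit_cosinor(hours, scores)
print(f"cosinor fit: b0={fit.beta0:.3f}, b1={fit.beta1:.3f}, b2={fit.beta2:.3f}, "
      f"residual SD={fit.resid_sd:.3f} (n={fit.n_obs})")

spec = CutoffSpec(kind="dynamic", delta_sd=0.5, daytime=(6, 18), run_in_days=2)
history = list(zip(hours, scores))
for hour in (8, 12, 16):
    expected = predict_cosinor(fit, hour)
    cut = dynamic_cutoff(history, hour, spec)
    print(f"  hour {hour:2d}: expected level {expected:+.3f} -> cutoff {cut:+.3f}")

print("\nA momentary score is 'elevated' when it exceeds the person's own")
print("expected level at that time of day by half a within-person SD.")
print("classifiable(day=2, hour=10):", is_classifiable(2, 10, spec), "(run-in)")
print("classifiable(day=5, hour=20):", is_classifiable(5, 20, spec), "(night)")
print("classifiable(day=5, hour=10):", is_classifiable(5, 10, spec))
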