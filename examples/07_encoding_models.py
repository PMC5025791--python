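"""Fit the four encoding models and probe time-reversal symmetry.

Linear and adaptation models provably produce equal full-support response
integrals for a ramp and its reversal; the multilayer model with a positive
rectifier threshold breaks that symmetry, as the data do.
"""

import numpy as np

from rampasym import models, stimuli, synth
from rampasym.models import (
    fit_ln, fit_multilayer, reversal_integral_oracle, train_test_split,
    unexplained_variance,
)

RATE = 31.5
specs = stimuli.build_stimulus_set("white_noise")
envs = stimuli.render_battery(specs, RATE)
train, test = train_test_split(specs)

# archetype responses as fitting targets (5% noise)
gen = synth.archetype_model(rate=RATE)
targets = np.stack([gen.predict(e) for e in envs], axis=1)[:6]
rng = np.random.default_rng(0)
noisy = targets + rng.normal(0, 0.05 * targets.std(), targets.shape)

ml, _ = fit_multilayer([envs[i] for i in train], noisy[:, train], RATE)
ln = fit_ln([envs[i] for i in train], noisy[:, train], RATE)
for name, model in [("multilayer", ml), ("LN", ln)]:
    pred = np.stack([model.predict(envs[i]) for i in test], axis=1)
    print(f"{name:10s} test unexplained variance: "
          f"{100*unexplained_variance(pred, noisy[:, test]):5.1f}%")
print(f"fitted rectifier threshold theta = {ml.theta:.2f}")

# reversal oracle on a random linear model: integrals must match exactly
ramps = [stimuli.render_envelope(s, RATE, 0.5, 3.5) for s in specs
         if s.kind == stimuli.RampKind.UP_RAMP and s.duration == 2.0]
lin = models.LinearKernelModel(kernel=rng.standard_normal(32), rate=RATE)
print(f"linear model reversal integral mismatch: "
      f"{reversal_integral_oracle(lin, ramps):.1e}")
print(f"multilayer (theta>0) reversal integral mismatch: "
      f"{reversal_integral_oracle(ml, ramps):.3f}")
# The linear mismatch is at machine precision; the thresholded multilayer
# model's is order 0.1 — only the latter architecture can encode ramp
# direction in its response integrals.
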