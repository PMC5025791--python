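"""Up- vs down-ramp response-integral asymmetry across synthetic sessions.

For each session, integrate the population mean deconvolved rate from sound
onset to offset + 500 ms for the 2 s up- and down-ramp and form the
normalized index 2 (I_up - I_down) / (I_up + I_down); test the sign across
sessions with a one-sided Wilcoxon signed-rank test.
"""

import numpy as np
from scipy import stats

from rampasym import population, preprocess, stimuli, synth

specs = [s for s in stimuli.build_stimulus_set("white_noise")
         if s.duration == 2.0 and min(s.level_start, s.level_end) == 60.0]
iu = next(i for i, s in enumerate(specs) if s.kind == stimuli.RampKind.UP_RAMP)

indices = []
for session in range(10):
    ds = synth.generate_dataset(seed=200 + session, n_neurons=120,
                                n_trials=20, specs=specs)
    r = preprocess.preprocess_tensor(ds.F, ds.Fnp)
    mean = r.trial_mean().mean(axis=0)
    ints = [population.response_integral(mean[j], r.onsets[j], r.offsets[j],
                                         r.rate) for j in range(2)]
    indices.append(population.asymmetry_index(ints[iu], ints[1 - iu]))

indices = np.array(indices)
p = stats.wilcoxon(indices, alternative="greater").pvalue
print("per-session asymmetry indices:", np.round(indices, 3))
print(f"median index {np.median(indices):+.2f}, one-sided signed-rank p = {p:.2e}")
# A positive index means up-ramps drive a larger integrated population
# response than their time-reversed down-ramps — a signature of nonlinear
# (threshold-type) encoding, since no linear model can produce it.
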