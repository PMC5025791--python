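"""Trial-structured array containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialTensor:
    """Neurons x stimuli x trials x frames array on a common frame grid.

    ``values`` may hold raw fluorescence, dF/F or deconvolved rate;
    ``onsets``/``offsets`` give the stimulus window (frame indices,
    half-open) per stimulus.  Stimuli of different durations share the grid
    by construction (equal pre-pad, post-pad absorbing the difference).
    """

    values: np.ndarray
    rate: float
    onsets: np.ndarray
    offsets: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (neurons, stimuli, trials, frames)")
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if len(self.onsets) != self.n_stimuli or len(self.offsets) != self.n_stimuli:
            raise ValueError("one onset/offset per stimulus required")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def trial_mean(self) -> np.ndarray:
        """(neurons, stimuli, frames) average across trials."""
        return self.values.mean(axis=2)

    def with_values(self, values: np.ndarray) -> "TrialTensor":
        return TrialTensor(values, self.rate, self.onsets, self.offsets, self.labels)
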