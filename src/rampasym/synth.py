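"""Ground-truthed synthetic calcium-imaging datasets.

The generator emulates the statistical structure of two-photon GCaMP6s
recordings of mouse auditory cortex during intensity-modulated sounds:

* a population of archetype neurons (quiet-ON, loud-OFF, quiet-OFF, tonic,
  ON+OFF, loud-OFF+tonic, plus a non-responsive majority) whose noise-free
  firing rates are produced by a generative multilayer encoding model;
* GCaMP6s-like calcium kinetics (decay time constant 2 s), a 0.7-weighted
  shared neuropil contamination, and i.i.d. Gaussian trial noise;
* spatially clumped cluster layouts in a 550 x 540 um field of view;
* logistic behavioural learning curves.

Everything is seeded and bit-reproducible; the ground-truth labels let
every downstream analysis be validated against what was generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import TrialTensor
from .models import IntensityChannels, ChannelParams, MultilayerModel
from .stimuli import Quality, StimulusEnvelope, build_stimulus_set, render_battery

__all__ = [
    "ARCHETYPE_FAMILIES",
    "RESPONSIVE_PROPORTIONS",
    "PopulationConfig",
    "KineticsConfig",
    "SyntheticPopulation",
    "archetype_model",
    "sample_population",
    "generate_rates",
    "rates_to_fluorescence",
    "spatial_layout",
    "generate_learning_curves",
    "LearningCurve",
    "SyntheticDataset",
    "generate_dataset",
]

#: Responsive archetype families, in canonical order.
ARCHETYPE_FAMILIES = (
    "quiet_on",
    "loud_off",
    "quiet_off",
    "tonic",
    "on_off",
    "loud_off_tonic",
)
NONRESPONSIVE = "nonresponsive"

#: Default split of the responsive population across families.
RESPONSIVE_PROPORTIONS = {
    "loud_off": 0.30,
    "quiet_on": 0.18,
    "quiet_off": 0.04,
    "tonic": 0.18,
    "on_off": 0.15,
    "loud_off_tonic": 0.15,
}

# Readout weights of the generative multilayer model, per family:
# (tonic_Q, tonic_L, on_Q, on_L, off_Q, off_L).  Negative weights on the
# opposite-channel transient cancel responses outside the preferred range
# (e.g. quiet-ON cells stay silent at loud onsets); the readout is clipped
# at zero when rates are generated.  Amplitudes are scaled so each family's
# noise-free profile energy (std over the standard battery) is comparable,
# matching the comparable response amplitudes observed across cluster
# types in vivo.
ARCHETYPE_WEIGHTS = {
    "quiet_on": (0.0, 0.0, 1.3, -1.55, 0.0, 0.0),
    "loud_off": (0.0, 0.0, 0.0, 0.0, 0.0, 0.8),
    "quiet_off": (0.0, 0.0, 0.0, 0.0, 1.2, -1.4),
    "tonic": (0.0, 8.0, 0.0, 0.0, 0.0, 0.0),
    "on_off": (0.0, 0.0, 0.33, 0.33, 0.33, 0.0),
    "loud_off_tonic": (0.0, 3.6, 0.0, 0.0, 0.0, 0.7),
    NONRESPONSIVE: (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

#: Rectifier threshold of the generative model (units of smoothed channel
#: derivative, 1/s).  Large enough to suppress the slow within-ramp
#: derivative of 1 and 2 s ramps while passing abrupt onset/offset
#: transients — the mechanism that makes response integrals asymmetric.
GENERATIVE_THETA = 2.0
#: Decay of the generative readout kernels, seconds (transient responses).
GENERATIVE_KERNEL_TAU = 0.15


@dataclass
class PopulationConfig:
    n_neurons: int = 1000
    responsive_fraction: float = 0.37
    proportions: dict = field(default_factory=lambda: dict(RESPONSIVE_PROPORTIONS))
    gain_sd: float = 0.5  # lognormal sd of per-neuron gain (long-tailed SNR)
    clumping: float = 0.0
    clump_sigma: float = 40.0  # um
    field_size: tuple = (550.0, 540.0)  # um


@dataclass
class KineticsConfig:
    """Calcium-indicator and noise parameters for fluorescence synthesis."""

    tau_decay: float = 2.0  # s, GCaMP6s transient decay
    tau_rise: float = 0.1  # s
    noise_sd: float = 0.10  # dF/F units, per-frame
    neuropil_weight: float = 0.7
    baseline_F0: float = 100.0  # a.u.
    calcium_gain: float = 0.02  # dF/F per unit rate-kernel convolution
    neuropil_lowpass_sigma: float = 0.2  # s

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if not 0.0 <= self.neuropil_weight <= 1.0:
            raise ValueError("neuropil_weight must lie in [0, 1]")


@dataclass
class SyntheticPopulation:
    labels: np.ndarray  # archetype family name per neuron
    gains: np.ndarray  # per-neuron response gain, >= 0
    positions: np.ndarray  # (n, 2) um
    config: PopulationConfig
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.labels)

    @property
    def responsive(self) -> np.ndarray:
        return self.labels != NONRESPONSIVE


def archetype_model(
    channels: IntensityChannels | None = None,
    theta: float = GENERATIVE_THETA,
    rate: float = 31.5,
    kernel_tau: float = GENERATIVE_KERNEL_TAU,
    kernel_duration: float = 1.0,
) -> MultilayerModel:
    """The generative multilayer model with one readout row per family.

    Row order is ``ARCHETYPE_FAMILIES`` followed by the all-zero
    non-responsive row.
    """
    if channels is None:
        channels = IntensityChannels()
    n_lags = int(round(kernel_duration * rate))
    base = np.exp(-np.arange(n_lags) / (kernel_tau * rate))
    families = ARCHETYPE_FAMILIES + (NONRESPONSIVE,)
    tonic = np.array([ARCHETYPE_WEIGHTS[f][:2] for f in families])
    kernels = np.stack(
        [np.outer(ARCHETYPE_WEIGHTS[f][2:], base) for f in families]
    )
    return MultilayerModel(
        channels=channels, theta=theta, tonic_weights=tonic, kernels=kernels,
        rate=rate,
    )


def _allocate_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n cells to the families."""
    fams = list(proportions)
    raw = np.array([proportions[f] * n for f in fams])
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(fams, counts))


def sample_population(
    config: PopulationConfig | None = None, seed: int = 0
) -> SyntheticPopulation:
    """Draw archetype labels, gains and spatial positions for a population."""
    config = config or PopulationConfig()
    total = sum(config.proportions.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"responsive proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    n = config.n_neurons
    n_resp = int(round(config.responsive_fraction * n))
    counts = _allocate_counts(n_resp, config.proportions)
    labels = [NONRESPONSIVE] * (n - n_resp)
    for fam, c in counts.items():
        labels.extend([fam] * c)
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    gains = np.exp(rng.normal(0.0, config.gain_sd, size=n))
    gains[labels == NONRESPONSIVE] = 0.0
    positions = spatial_layout(
        labels, config.clumping, seed=rng.integers(2**31),
        sigma=config.clump_sigma, field_size=config.field_size,
    )
    return SyntheticPopulation(labels=labels, gains=gains, positions=positions,
                               config=config, seed=seed)


def generate_rates(
    pop: SyntheticPopulation,
    envelopes: list[StimulusEnvelope],
    rate: float = 31.5,
    channels: IntensityChannels | None = None,
    theta: float = GENERATIVE_THETA,
) -> np.ndarray:
    """Noise-free firing rates, (n_neurons, n_stimuli, n_frames).

    Each neuron's rate is its archetype's multilayer-model output scaled by
    its gain and rectified at zero (the readout cancellation weights can
    transiently go negative).
    """
    model = archetype_model(channels=channels, theta=theta, rate=rate)
    families = ARCHETYPE_FAMILIES + (NONRESPONSIVE,)
    fam_rates = np.stack(
        [np.clip(model.predict(env), 0.0, None) for env in envelopes], axis=1
    )  # (n_families, n_stimuli, n_frames)
    idx = np.array([families.index(l) for l in pop.labels])
    return pop.gains[:, None, None] * fam_rates[idx]


def _calcium_kernel(kin: KineticsConfig, rate: float) -> np.ndarray:
    """(1 - exp(-t/tau_rise)) exp(-t/tau_decay), unit peak, 5 tau_decay span."""
    t = np.arange(int(round(5.0 * kin.tau_decay * rate))) / rate
    k = (1.0 - np.exp(-t / kin.tau_rise)) * np.exp(-t / kin.tau_decay)
    return k / k.max()


def rates_to_fluorescence(
    rates: np.ndarray,
    kinetics: KineticsConfig | None = None,
    n_trials: int = 20,
    seed: int = 0,
    rate: float = 31.5,
    dtype=np.float32,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert rates to trial-resolved raw fluorescence plus neuropil.

    ``F = F0 (1 + g * (rate x calcium kernel)) + w * Fnp + noise`` with the
    neuropil trace ``Fnp`` a shared, slow, stimulus-locked signal (the
    population-average calcium signal low-pass filtered with a 200 ms
    Gaussian) identical across trials and neurons.  Noise is i.i.d.
    Gaussian per frame and trial with sd ``noise_sd * F0``.

    Returns ``(F, Fnp)``; ``F`` has shape (neurons, stimuli, trials,
    frames), ``Fnp`` is a read-only broadcast view of the same shape.
    """
    from scipy.ndimage import gaussian_filter1d

    kin = kinetics or KineticsConfig()
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, float)
    n_neurons, n_stimuli, n_frames = rates.shape
    ck = _calcium_kernel(kin, rate)
    # calcium-convolved dF/F-scale signal per neuron and stimulus
    from scipy.signal import fftconvolve

    cal = fftconvolve(rates, ck[None, None, :], axes=2)[..., :n_frames]
    cal *= kin.calcium_gain
    pop_mean = cal.mean(axis=0)  # (stimuli, frames)
    np_sig = gaussian_filter1d(pop_mean, kin.neuropil_lowpass_sigma * rate, axis=-1)
    fnp = kin.baseline_F0 * (1.0 + np_sig)  # neuropil trace, a.u.
    F = np.empty((n_neurons, n_stimuli, n_trials, n_frames), dtype=dtype)
    base = kin.baseline_F0 * (1.0 + cal) + kin.neuropil_weight * fnp[None]
    F[:] = base[:, :, None, :]
    noise = rng.standard_normal(F.shape).astype(dtype)
    F += (kin.noise_sd * kin.baseline_F0) * noise
    fnp_full = np.broadcast_to(
        fnp.astype(dtype)[None, :, None, :], F.shape
    )
    return F, fnp_full


def spatial_layout(
    labels: np.ndarray,
    clumping: float,
    seed: int = 0,
    sigma: float = 40.0,
    field_size: tuple = (550.0, 540.0),
) -> np.ndarray:
    """Cell positions in the imaging field, optionally clumped by label.

    With probability ``clumping`` a cell is placed around its label's
    Gaussian center (sd ``sigma`` um, clipped to the field); otherwise it is
    placed uniformly.  ``clumping=0`` gives a uniform layout.
    """
    if not 0.0 <= clumping <= 1.0:
        raise ValueError("clumping must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    fx, fy = field_size
    n = len(labels)
    pos = rng.uniform((0, 0), (fx, fy), size=(n, 2))
    if clumping > 0:
        centers = {
            lab: rng.uniform((0.15 * fx, 0.15 * fy), (0.85 * fx, 0.85 * fy))
            for lab in dict.fromkeys(labels)  # insertion-ordered unique
        }
        clumped = rng.random(n) < clumping
        for i in np.flatnonzero(clumped):
            p = rng.normal(centers[labels[i]], sigma)
            pos[i] = np.clip(p, (0, 0), (fx, fy))
    return pos


# ---------------------------------------------------------------------------
# behavioural learning curves

@dataclass
class LearningCurve:
    """Binned fraction-correct performance over training for one mouse."""

    performance: np.ndarray  # per trial bin, in [0, 1]
    group: str  # e.g. "up_cue" / "down_cue"
    trials_per_bin: int = 20
    chance: float = 0.5

    @property
    def trial_index(self) -> np.ndarray:
        return (np.arange(len(self.performance)) + 0.5) * self.trials_per_bin


def generate_learning_curves(
    group_params: dict,
    n_mice: int,
    seed: int = 0,
) -> list[LearningCurve]:
    """Logistic learning curves with per-mouse rate and onset.

    ``group_params`` keys: ``group`` (name), ``k`` (learning rate, 1/trial),
    ``k_sd`` (lognormal spread factor), ``t0`` (inflection trial),
    ``t0_sd``, ``plateau`` (asymptotic fraction correct, in (0.5, 1]),
    ``noise_sd`` (per-bin Gaussian noise), ``n_trials``, ``trials_per_bin``.
    """
    p = dict(group_params)
    plateau = p.get("plateau", 0.9)
    if not 0.5 < plateau <= 1.0 and plateau != 0.5:
        raise ValueError("plateau must lie in (0.5, 1] (or exactly 0.5 for chance)")
    rng = np.random.default_rng(seed)
    n_trials = p.get("n_trials", 600)
    tpb = p.get("trials_per_bin", 20)
    t = (np.arange(n_trials // tpb) + 0.5) * tpb
    curves = []
    for _ in range(n_mice):
        k = p["k"] * np.exp(rng.normal(0.0, p.get("k_sd", 0.0)))
        t0 = p["t0"] + rng.normal(0.0, p.get("t0_sd", 0.0))
        perf = 0.5 + (plateau - 0.5) / (1.0 + np.exp(-k * (t - t0)))
        perf = perf + rng.normal(0.0, p.get("noise_sd", 0.0), size=len(t))
        curves.append(
            LearningCurve(np.clip(perf, 0.0, 1.0), p.get("group", "group"), tpb)
        )
    return curves


# ---------------------------------------------------------------------------
# full dataset assembly and HDF5 I/O

@dataclass
class SyntheticDataset:
    """One synthetic imaging session: raw fluorescence plus ground truth."""

    F: TrialTensor
    Fnp: np.ndarray
    rates: np.ndarray
    population: SyntheticPopulation
    envelopes: list[StimulusEnvelope]
    kinetics: KineticsConfig
    seed: int

    def save(self, path: str | Path) -> None:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as h5:
            h5.create_dataset("F", data=self.F.values, compression="gzip")
            h5.create_dataset("Fnp", data=np.ascontiguousarray(self.Fnp[:, :, 0, :]),
                              compression="gzip")
            h5.create_dataset("rates", data=self.rates, compression="gzip")
            h5.create_dataset("positions", data=self.population.positions)
            h5.create_dataset(
                "labels",
                data=np.array([str(l) for l in self.population.labels], dtype="S"),
            )
            h5.create_dataset("stimuli/onsets", data=self.F.onsets)
            h5.create_dataset("stimuli/offsets", data=self.F.offsets)
            h5.create_dataset(
                "stimuli/envelopes", data=np.stack([e.values for e in self.envelopes])
            )
            h5.attrs["rate"] = self.F.rate
            h5.attrs["seed"] = self.seed
        sidecar = {
            "seed": self.seed,
            "kinetics": asdict(self.kinetics),
            "population": {
                **{k: v for k, v in asdict(self.population.config).items()},
            },
            "stimuli": [e.spec.label for e in self.envelopes if e.spec],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def generate_dataset(
    seed: int = 0,
    n_neurons: int = 1000,
    n_trials: int = 20,
    rate: float = 31.5,
    quality: Quality | str = Quality.WHITE_NOISE,
    population_config: PopulationConfig | None = None,
    kinetics: KineticsConfig | None = None,
    specs=None,
) -> SyntheticDataset:
    """Generate one complete synthetic session for the standard battery."""
    rng = np.random.default_rng(seed)
    cfg = population_config or PopulationConfig(n_neurons=n_neurons)
    kin = kinetics or KineticsConfig()
    if specs is None:
        specs = build_stimulus_set(quality)
    envelopes = render_battery(specs, rate)
    pop = sample_population(cfg, seed=int(rng.integers(2**31)))
    rates = generate_rates(pop, envelopes, rate=rate)
    F, Fnp = rates_to_fluorescence(
        rates, kin, n_trials=n_trials, seed=int(rng.integers(2**31)), rate=rate
    )
    onsets = np.array([e.onset_index for e in envelopes])
    offsets = np.array([e.offset_index for e in envelopes])
    tensor = TrialTensor(F, rate, onsets, offsets,
                         labels=[e.spec.label for e in envelopes])
    return SyntheticDataset(
        F=tensor, Fnp=Fnp, rates=rates, population=pop, envelopes=envelopes,
        kinetics=kin, seed=seed,
    )
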