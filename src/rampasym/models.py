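"""Stimulus->response encoding models and the time-reversal integral test.

Four model families map a dB-SPL envelope ``s(t)`` onto a (deconvolved)
cortical response:

* **linear** — a monotone pointwise scaling of ``s`` convolved with a causal
  kernel ``h`` supported on [0, 1] s.
* **adaptation** — the scaled input passes through synaptic depression,
  ``s_d(t) = s(t) (1 - d(t))`` with ``d' = -d/tau_a + u s (1 - d)``, before
  the linear kernel.
* **LN** — two intensity channels (a "quiet" and a "loud" sigmoid of the dB
  level) each convolved with a kernel on [0, 2] s, summed, then passed
  through a monotone piecewise-linear output nonlinearity.
* **multilayer** — the two channels feed six feature detectors (tonic,
  rectified-ON and rectified-OFF per channel, thresholded by a shared
  rectifier ``G(x) = x - theta`` for ``x > theta``); the response is a
  weighted sum of the tonic features plus kernels applied to the four
  transient features.

The first three families cannot produce unequal full-support response
integrals for a ramp and its time reversal (for the linear stage this is a
permutation argument; for adaptation it follows from an exact invariance of
the depression ODE).  The multilayer model with ``theta > 0`` breaks that
symmetry, which is the property the analyses in this package quantify.
All linear stages are fitted by the Moore-Penrose pseudo-inverse
(minimum-norm least squares); ``u``, ``tau_a``, ``theta`` and the channel
parameters are fitted by brute-force grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import (
    RAMP_RANGES,
    RampKind,
    StimulusEnvelope,
    StimulusSpec,
    time_reverse,
)

__all__ = [
    "ChannelParams",
    "IntensityChannels",
    "DEFAULT_CHANNELS",
    "make_channels",
    "feature_detectors",
    "FEATURE_NAMES",
    "LinearKernelModel",
    "fit_linear",
    "adaptation_dynamics",
    "AdaptationModel",
    "fit_adaptation",
    "LNModel",
    "fit_ln",
    "MultilayerModel",
    "fit_multilayer",
    "unexplained_variance",
    "train_test_split",
    "reversal_integral_oracle",
    "trajectory_divergence",
]


# ---------------------------------------------------------------------------
# intensity channels

@dataclass(frozen=True)
class ChannelParams:
    """Sigmoid intensity channel: amplitude / (1 + exp(-slope (s - midpoint)))."""

    amplitude: float = 1.0
    midpoint: float = 60.0  # dB SPL
    slope: float = 0.25  # 1 / dB

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return self.amplitude / (1.0 + np.exp(-self.slope * (np.asarray(s, float) - self.midpoint)))


@dataclass(frozen=True)
class IntensityChannels:
    """'Quiet' and 'loud' sigmoid channels applied to the dB envelope.

    The quiet channel saturates at low sound levels (low midpoint), the loud
    channel only rises at high levels.  Both map the silence floor (0 dB)
    to approximately zero.
    """

    quiet: ChannelParams = field(default_factory=lambda: ChannelParams(1.0, 50.0, 0.25))
    loud: ChannelParams = field(default_factory=lambda: ChannelParams(1.0, 72.0, 0.25))


DEFAULT_CHANNELS = IntensityChannels()


def make_channels(
    env: StimulusEnvelope | np.ndarray, channels: IntensityChannels = DEFAULT_CHANNELS
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the quiet/loud sigmoids to a dB-SPL envelope -> (sQ, sL)."""
    s = env.values if isinstance(env, StimulusEnvelope) else np.asarray(env, float)
    return channels.quiet(s), channels.loud(s)


# ---------------------------------------------------------------------------
# feature detectors (middle layer of the multilayer model)

FEATURE_NAMES = ("tonic_Q", "tonic_L", "on_Q", "on_L", "off_Q", "off_L")


def _causal_smoother(tau_f: float, rate: float) -> np.ndarray:
    """Causal exponential smoother, truncated at 5 tau, unit discrete sum.

    Unit sum makes the smoother transparent to constants and exactly
    preserve the discrete integral of its input.
    """
    n = max(int(round(5.0 * tau_f * rate)), 1)
    k = np.exp(-np.arange(n) / (tau_f * rate))
    return k / k.sum()


def rectifier(x: np.ndarray, theta: float) -> np.ndarray:
    """Shared rectifying nonlinearity G: x - theta above theta, else 0."""
    return np.where(x > theta, x - theta, 0.0)


def _forward_diff(x: np.ndarray, rate: float) -> np.ndarray:
    """Forward difference times frame rate; last sample zero-padded."""
    d = np.empty_like(x, dtype=float)
    d[..., :-1] = np.diff(x, axis=-1) * rate
    d[..., -1] = 0.0
    return d


def feature_detectors(
    sQ: np.ndarray,
    sL: np.ndarray,
    theta: float,
    rate: float,
    tau_f: float = 0.05,
) -> np.ndarray:
    """Six nonlinear feature traces from the two intensity channels.

    Per channel c in {Q, L}: the tonic feature transmits ``s_c``; the ON
    (OFF) feature rectifies the positive (negative) part of ``ds_c/dt``,
    smooths it with a causal exponential of time constant ``tau_f`` and
    applies the shared rectifier ``G`` with threshold ``theta``.

    Returns an array ``(6, n_frames)`` ordered as ``FEATURE_NAMES``.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    kern = _causal_smoother(tau_f, rate)
    out = np.empty((6, len(sQ)))
    out[0] = sQ
    out[1] = sL
    for i, s in enumerate((sQ, sL)):
        d = _forward_diff(s, rate)
        on = np.convolve(np.clip(d, 0.0, None), kern)[: len(s)]
        off = np.convolve(np.clip(-d, 0.0, None), kern)[: len(s)]
        out[2 + i] = rectifier(on, theta)
        out[4 + i] = rectifier(off, theta)
    return out


# ---------------------------------------------------------------------------
# design-matrix helpers

def lagged_design(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Causal lagged copies of ``x``: column j is x delayed by j frames."""
    n = len(x)
    X = np.zeros((n, n_lags))
    for j in range(n_lags):
        X[j:, j] = x[: n - j]
    return X


def _pinv_fit(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares (Moore-Penrose pseudo-inverse)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef


def _apply_kernel(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    return np.convolve(x, h)[: len(x)]


# ---------------------------------------------------------------------------
# linear model

@dataclass
class LinearKernelModel:
    """Causal temporal kernel applied to a scaled envelope."""

    kernel: np.ndarray  # (n_lags,) or (n_targets, n_lags)
    rate: float
    scaling: "callable | None" = None  # monotone pointwise input scaling

    def scale(self, env: StimulusEnvelope) -> np.ndarray:
        x = env.values
        return self.scaling(x) if self.scaling is not None else np.asarray(x, float)

    def predict(self, env: StimulusEnvelope) -> np.ndarray:
        x = self.scale(env)
        h = np.atleast_2d(self.kernel)
        out = np.stack([_apply_kernel(x, hk) for hk in h])
        return out[0] if self.kernel.ndim == 1 else out


def fit_linear(
    envelopes: list[StimulusEnvelope],
    targets: np.ndarray,
    rate: float,
    kernel_duration: float = 1.0,
    scaling=None,
) -> LinearKernelModel:
    """Fit the causal kernel by pseudo-inverse on lagged scaled inputs.

    ``targets``: (n_stimuli, n_frames) or (n_targets, n_stimuli, n_frames).
    """
    n_lags = int(round(kernel_duration * rate))
    sc = scaling if scaling is not None else (lambda v: np.asarray(v, float))
    X = np.vstack([lagged_design(sc(e.values), n_lags) for e in envelopes])
    tgt = np.asarray(targets, float)
    single = tgt.ndim == 2
    if single:
        tgt = tgt[None]
    Y = np.hstack([t.reshape(-1) for t in tgt]).reshape(len(tgt), -1).T
    coef = _pinv_fit(X, Y)  # (n_lags, n_targets)
    kernel = coef.T[0] if single else coef.T
    return LinearKernelModel(kernel=kernel, rate=rate, scaling=scaling)


# ---------------------------------------------------------------------------
# adaptation model

def adaptation_dynamics(
    s: np.ndarray,
    u: float | np.ndarray,
    tau_a: float | np.ndarray,
    rate: float,
    n_substeps: int = 4,
    return_integral: bool = False,
):
    """Synaptic-depression dynamics ``d' = -d/tau_a + u s (1 - d)``, d(0)=0.

    The input ``s`` is held piecewise constant over frames and the ODE is
    integrated with a fixed-step 4th-order Runge-Kutta scheme using
    ``n_substeps`` sub-steps per frame (steps aligned with frame boundaries,
    where the input jumps).  Returns the depressed input
    ``s_d = s (1 - d)`` sampled at frame times; with ``return_integral``
    also the full-support integral of ``s_d`` accumulated by the same
    scheme (so quadrature error shrinks with the step as well).

    ``u`` (1/(a.u. s)) and ``tau_a`` (s) may be broadcastable arrays, in
    which case all parameter combinations are integrated in parallel and
    ``s_d`` has shape ``broadcast(u, tau_a).shape + (n_frames,)``.

    The input is expected on the order of unity (e.g. a sigmoid channel
    output); the explicit scheme is stable for step sizes with
    ``h * (1/tau_a + u * max(s)) << 1`` and raises if the state diverges.
    """
    u = np.asarray(u, float)
    tau_a = np.asarray(tau_a, float)
    if np.any(u < 0) or np.any(tau_a <= 0):
        raise ValueError("u must be >= 0 and tau_a > 0")
    s = np.asarray(s, float)
    shape = np.broadcast(u, tau_a).shape
    d = np.zeros(shape)
    integral = np.zeros(shape)
    h = 1.0 / (rate * n_substeps)
    s_d = np.empty(shape + (len(s),))

    def rhs(dv, sv):
        return -dv / tau_a + u * sv * (1.0 - dv)

    for k, sk in enumerate(s):
        s_d[..., k] = sk * (1.0 - d)
        for _ in range(n_substeps):
            k1 = rhs(d, sk)
            k2 = rhs(d + 0.5 * h * k1, sk)
            k3 = rhs(d + 0.5 * h * k2, sk)
            k4 = rhs(d + h * k3, sk)
            if return_integral:
                # Simpson-consistent quadrature of s_d over the sub-step
                i1 = sk * (1.0 - d)
                i2 = sk * (1.0 - (d + 0.5 * h * k1))
                i3 = sk * (1.0 - (d + 0.5 * h * k2))
                i4 = sk * (1.0 - (d + h * k3))
                integral += h * (i1 + 2.0 * i2 + 2.0 * i3 + i4) / 6.0
            d = d + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        # analytically 0 <= d <= 1; a gross violation means the explicit
        # scheme is unstable for this (u, tau_a, step) combination
        if not np.all(np.isfinite(d)) or np.any(np.abs(d) > 2.0):
            raise FloatingPointError(
                "adaptation integration diverged; reduce the step "
                "(increase n_substeps) or rescale the input"
            )
    if return_integral:
        return s_d, integral
    return s_d


@dataclass
class AdaptationModel:
    """Depression stage followed by a fitted linear kernel."""

    u: float
    tau_a: float
    kernel: np.ndarray
    rate: float
    scaling: "callable | None" = None
    n_substeps: int = 4

    def depressed_input(self, env: StimulusEnvelope) -> np.ndarray:
        x = env.values if self.scaling is None else self.scaling(env.values)
        return adaptation_dynamics(x, self.u, self.tau_a, self.rate, self.n_substeps)

    def predict(self, env: StimulusEnvelope) -> np.ndarray:
        return _apply_kernel(self.depressed_input(env), self.kernel)


def fit_adaptation(
    envelopes: list[StimulusEnvelope],
    targets: np.ndarray,
    rate: float,
    u_grid: np.ndarray,
    tau_grid: np.ndarray,
    kernel_duration: float = 1.0,
    scaling=None,
    n_substeps: int = 4,
) -> tuple[AdaptationModel, float]:
    """Brute-force search over (u, tau_a); kernel by pseudo-inverse per cell.

    Returns the best model and its training residual sum of squares.
    """
    u_grid = np.atleast_1d(np.asarray(u_grid, float))
    tau_grid = np.atleast_1d(np.asarray(tau_grid, float))
    if u_grid.size == 0 or tau_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    n_lags = int(round(kernel_duration * rate))
    sc = scaling if scaling is not None else (lambda v: np.asarray(v, float))
    y = np.asarray(targets, float).reshape(-1)
    best = None
    for u in u_grid:
        for tau_a in tau_grid:
            X = np.vstack(
                [
                    lagged_design(
                        adaptation_dynamics(sc(e.values), u, tau_a, rate, n_substeps),
                        n_lags,
                    )
                    for e in envelopes
                ]
            )
            coef = _pinv_fit(X, y)
            ss = float(np.sum((X @ coef - y) ** 2))
            if best is None or ss < best[0]:
                best = (ss, u, tau_a, coef)
    ss, u, tau_a, coef = best
    model = AdaptationModel(
        u=float(u), tau_a=float(tau_a), kernel=coef, rate=rate, scaling=scaling,
        n_substeps=n_substeps,
    )
    return model, ss


# ---------------------------------------------------------------------------
# LN model

@dataclass
class PiecewiseLinear:
    """Monotone piecewise-linear output nonlinearity with a kink at x0.

    F(x) = a (x - x0) + c for x <= x0, b (x - x0) + c for x > x0,
    with a, b >= 0 (monotone nondecreasing), continuous at x0.
    """

    a: float = 1.0
    b: float = 1.0
    c: float = 0.0
    x0: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return (
            self.c
            + self.a * np.minimum(x - self.x0, 0.0)
            + self.b * np.maximum(x - self.x0, 0.0)
        )


@dataclass
class LNModel:
    """Two-channel linear stage plus per-target static nonlinearity."""

    channels: IntensityChannels
    kernels_q: np.ndarray  # (n_targets, n_lags)
    kernels_l: np.ndarray
    nonlinearities: list[PiecewiseLinear]
    rate: float

    def linear_output(self, env: StimulusEnvelope) -> np.ndarray:
        sQ, sL = make_channels(env, self.channels)
        return np.stack(
            [
                _apply_kernel(sQ, hq) + _apply_kernel(sL, hl)
                for hq, hl in zip(self.kernels_q, self.kernels_l)
            ]
        )

    def predict(self, env: StimulusEnvelope) -> np.ndarray:
        lin = self.linear_output(env)
        return np.stack([F(z) for F, z in zip(self.nonlinearities, lin)])


def _fit_piecewise(z: np.ndarray, y: np.ndarray, n_kinks: int = 25) -> PiecewiseLinear:
    """Fit (a, b, c, x0) by a kink grid over quantiles of the linear output.

    For each candidate x0 the remaining parameters are linear and solved in
    closed form; negative slopes are clipped to zero (monotonicity) and the
    candidate re-scored.
    """
    qs = np.quantile(z, np.linspace(0.02, 0.98, n_kinks))
    best = None
    for x0 in np.unique(qs):
        lo = np.minimum(z - x0, 0.0)
        hi = np.maximum(z - x0, 0.0)
        X = np.column_stack([lo, hi, np.ones_like(z)])
        coef = _pinv_fit(X, y)
        a, b, c = coef
        a, b = max(a, 0.0), max(b, 0.0)
        resid = y - (c + a * lo + b * hi)
        ss = float(resid @ resid)
        if best is None or ss < best[0]:
            best = (ss, PiecewiseLinear(float(a), float(b), float(c), float(x0)))
    return best[1]


def fit_ln(
    envelopes: list[StimulusEnvelope],
    targets: np.ndarray,
    rate: float,
    channels: IntensityChannels = DEFAULT_CHANNELS,
    kernel_duration: float = 2.0,
) -> LNModel:
    """Fit kernels first (pseudo-inverse), then the output nonlinearity."""
    n_lags = int(round(kernel_duration * rate))
    tgt = np.asarray(targets, float)
    if tgt.ndim == 2:
        tgt = tgt[None]
    blocks = []
    for e in envelopes:
        sQ, sL = make_channels(e, channels)
        blocks.append(np.hstack([lagged_design(sQ, n_lags), lagged_design(sL, n_lags)]))
    X = np.vstack(blocks)
    Y = tgt.reshape(tgt.shape[0], -1).T
    coef = _pinv_fit(X, Y)  # (2 n_lags, n_targets)
    kq = coef[:n_lags].T
    kl = coef[n_lags:].T
    lin = X @ coef  # (frames_total, n_targets)
    nls = [_fit_piecewise(lin[:, i], Y[:, i]) for i in range(Y.shape[1])]
    return LNModel(channels=channels, kernels_q=kq, kernels_l=kl,
                   nonlinearities=nls, rate=rate)


# ---------------------------------------------------------------------------
# multilayer model

@dataclass
class MultilayerModel:
    """Channels -> six feature detectors -> linear readout per target.

    ``tonic_weights`` has shape (n_targets, 2) for (tonic_Q, tonic_L);
    ``kernels`` has shape (n_targets, 4, n_lags) for the transient features
    (on_Q, on_L, off_Q, off_L).
    """

    channels: IntensityChannels
    theta: float
    tonic_weights: np.ndarray
    kernels: np.ndarray
    rate: float
    tau_f: float = 0.05

    @property
    def n_targets(self) -> int:
        return self.tonic_weights.shape[0]

    def features(self, env: StimulusEnvelope) -> np.ndarray:
        sQ, sL = make_channels(env, self.channels)
        return feature_detectors(sQ, sL, self.theta, self.rate, self.tau_f)

    def predict(self, env: StimulusEnvelope) -> np.ndarray:
        feats = self.features(env)
        out = np.zeros((self.n_targets, feats.shape[1]))
        for i in range(self.n_targets):
            out[i] = (
                self.tonic_weights[i, 0] * feats[0]
                + self.tonic_weights[i, 1] * feats[1]
            )
            for j in range(4):
                out[i] += _apply_kernel(feats[2 + j], self.kernels[i, j])
        return out


def _multilayer_design(
    envelopes: list[StimulusEnvelope],
    channels: IntensityChannels,
    theta: float,
    rate: float,
    n_lags: int,
    tau_f: float,
) -> np.ndarray:
    blocks = []
    for e in envelopes:
        sQ, sL = make_channels(e, channels)
        feats = feature_detectors(sQ, sL, theta, rate, tau_f)
        cols = [feats[0][:, None], feats[1][:, None]]
        cols += [lagged_design(feats[2 + j], n_lags) for j in range(4)]
        blocks.append(np.hstack(cols))
    return np.vstack(blocks)


def fit_multilayer(
    envelopes: list[StimulusEnvelope],
    targets: np.ndarray,
    rate: float,
    theta_mode: str = "fit",
    theta_grid: np.ndarray | None = None,
    channels: IntensityChannels = DEFAULT_CHANNELS,
    channel_grid: "list[IntensityChannels] | None" = None,
    kernel_duration: float = 1.0,
    tau_f: float = 0.05,
) -> tuple[MultilayerModel, float]:
    """Fit the multilayer model: linear readout exactly, theta by grid.

    ``theta_mode`` is ``"zero"`` (rectifier threshold fixed at 0) or
    ``"fit"`` (brute-force over ``theta_grid``, default 0..8 in 17 steps).
    An optional ``channel_grid`` brute-forces the channel sigmoids as well.
    Returns the best model and its training residual sum of squares.
    """
    tgt = np.asarray(targets, float)
    if tgt.ndim == 2:
        tgt = tgt[None]
    Y = tgt.reshape(tgt.shape[0], -1).T
    n_lags = int(round(kernel_duration * rate))
    if theta_mode == "zero":
        thetas = np.array([0.0])
    elif theta_mode == "fit":
        thetas = (
            np.asarray(theta_grid, float)
            if theta_grid is not None
            else np.linspace(0.0, 8.0, 17)
        )
    else:
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    chan_candidates = channel_grid if channel_grid is not None else [channels]
    best = None
    for chans in chan_candidates:
        for theta in thetas:
            X = _multilayer_design(envelopes, chans, float(theta), rate, n_lags, tau_f)
            coef = _pinv_fit(X, Y)
            ss = float(np.sum((X @ coef - Y) ** 2))
            if best is None or ss < best[0]:
                best = (ss, float(theta), chans, coef)
    ss, theta, chans, coef = best
    tonic = coef[:2].T.copy()
    kernels = coef[2:].T.reshape(Y.shape[1], 4, n_lags).copy()
    model = MultilayerModel(
        channels=chans, theta=theta, tonic_weights=tonic, kernels=kernels,
        rate=rate, tau_f=tau_f,
    )
    return model, ss


# ---------------------------------------------------------------------------
# evaluation utilities

def unexplained_variance(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Residual sum of squares over total (mean-centred) sum of squares."""
    p = np.asarray(predictions, float).reshape(-1)
    t = np.asarray(targets, float).reshape(-1)
    tot = float(np.sum((t - t.mean()) ** 2))
    if tot == 0:
        raise ValueError("targets have zero variance; unexplained variance undefined")
    return float(np.sum((p - t) ** 2)) / tot


def train_test_split(specs: list[StimulusSpec]) -> tuple[list[int], list[int]]:
    """Partition the 23-stimulus battery into the train/test index sets.

    Train: 0.25 s constants at 50, 60, 70 and 85 dB plus all ramps between
    50 and 85 dB.  Test: constants at 55, 65 and 80 dB plus all ramps
    between 60 and 85 dB.
    """
    train, test = [], []
    for i, s in enumerate(specs):
        if s.kind == RampKind.CONSTANT:
            if s.level_start in (50.0, 60.0, 70.0, 85.0):
                train.append(i)
            elif s.level_start in (55.0, 65.0, 80.0):
                test.append(i)
            else:
                raise ValueError(f"unexpected constant level {s.level_start}")
        else:
            lo, hi = sorted((s.level_start, s.level_end))
            if (lo, hi) == RAMP_RANGES[0]:
                train.append(i)
            elif (lo, hi) == RAMP_RANGES[1]:
                test.append(i)
            else:
                raise ValueError(f"unexpected ramp range {(lo, hi)}")
    if len(train) + len(test) != len(specs):
        raise ValueError("battery does not partition into the stated sets")
    return train, test


def reversal_integral_oracle(model, envelopes: list[StimulusEnvelope]) -> float:
    """Worst-case relative difference of full-support response integrals
    between each envelope and its time reversal.

    Envelopes should carry enough post-stimulus padding for the model
    response to relax back to baseline (kernel support plus adaptation
    recovery); the integral is the discrete sum times the frame interval
    over the whole trace.  Returns ``max |I_fwd - I_rev| / (|I_fwd| + |I_rev|)``.
    """
    worst = 0.0
    for env in envelopes:
        rev = time_reverse(env)
        for resp_f, resp_r in _paired_responses(model, env, rev):
            i_f = float(np.sum(resp_f)) / env.rate
            i_r = float(np.sum(resp_r)) / env.rate
            denom = abs(i_f) + abs(i_r)
            if denom == 0:
                continue
            worst = max(worst, abs(i_f - i_r) / denom)
    return worst


def _paired_responses(model, env, rev):
    rf = np.atleast_2d(model.predict(env))
    rr = np.atleast_2d(model.predict(rev))
    return zip(rf, rr)


def trajectory_divergence(
    data_up: np.ndarray,
    data_down: np.ndarray,
    model_up: np.ndarray,
    model_down: np.ndarray,
    n_components: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame distance between up- and down-ramp population trajectories.

    Principal components are fitted on the data trajectories (frames as
    samples, response channels as features); data and model trajectories are
    projected onto the leading ``n_components`` and the Euclidean distance
    between the up and down trajectory is returned per frame, for the data
    and for the model predictions.
    """
    from sklearn.decomposition import PCA

    data_up = np.asarray(data_up, float)
    data_down = np.asarray(data_down, float)
    pts = np.vstack([data_up.T, data_down.T])  # frames x channels
    pca = PCA(n_components=n_components)
    pca.fit(pts)
    du = pca.transform(data_up.T)
    dd = pca.transform(data_down.T)
    mu = pca.transform(np.asarray(model_up, float).T)
    md = pca.transform(np.asarray(model_down, float).T)
    return (
        np.linalg.norm(du - dd, axis=1),
        np.linalg.norm(mu - md, axis=1),
    )
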