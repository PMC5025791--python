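"""Fluorescence preprocessing: neuropil correction, baseline, dF/F,
temporal deconvolution.

The raw somatic signal F(t) is contaminated by out-of-focus neuropil
fluorescence.  A "filled-in" neuropil frame stack is built by Gaussian
smoothing the movie outside all ROIs, the per-neuron neuropil trace is
subtracted with a fixed 0.7 weight, a per-block baseline F0 is taken as the
minimum of a Gaussian-filtered trace, and firing-rate time courses are
estimated by the linear deconvolution r(t) = f'(t) + f(t)/tau with
tau = 2 s (GCaMP6s transient decay).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .containers import TrialTensor

__all__ = [
    "neuropil_fill_in",
    "neuropil_correct",
    "baseline_f0",
    "dff",
    "deconvolve",
    "preprocess_tensor",
]

#: Gaussian truncation (in sigmas) used by every filter in this module.
FILTER_TRUNCATE = 4.0


def neuropil_fill_in(
    frames: np.ndarray,
    mask: np.ndarray,
    sigma_um: float = 170.0,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Fill ROI holes with smoothed surround fluorescence.

    ``Y(t) = (X(t) . M) (x) g / (M (x) g)`` with ``M`` a binary image equal
    to 1 outside all ROIs and ``g`` a spatial Gaussian (sigma 170 um,
    truncated at 4 sigma, reflective boundaries).  ``frames`` is (t, y, x)
    or a single (y, x) frame.
    """
    mask = np.asarray(mask, float)
    if mask.max() == 0:
        raise ZeroDivisionError("mask has no neuropil pixels (all zero)")
    if not np.isin(mask, (0.0, 1.0)).all():
        raise ValueError("mask must be binary")
    sigma_px = sigma_um / pixel_size_um
    denom = gaussian_filter(mask, sigma_px, mode="reflect", truncate=FILTER_TRUNCATE)
    frames = np.asarray(frames, float)
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    out = np.empty_like(stack)
    for t, frame in enumerate(stack):
        num = gaussian_filter(frame * mask, sigma_px, mode="reflect",
                              truncate=FILTER_TRUNCATE)
        out[t] = num / denom
    return out[0] if single else out


def neuropil_correct(F: np.ndarray, Fnp: np.ndarray, weight: float = 0.7) -> np.ndarray:
    """Subtract the weighted neuropil trace: Fc = F - weight * Fnp."""
    F = np.asarray(F, float)
    Fnp = np.asarray(Fnp, float)
    if F.shape[-1] != Fnp.shape[-1]:
        raise ValueError("F and Fnp must share the time axis length")
    return F - weight * Fnp


def baseline_f0(
    Fc: np.ndarray,
    rate: float,
    block_length: float = 42.0,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Per-block baseline: minimum of the Gaussian-filtered trace.

    The trace is cut into ``block_length``-second blocks (a trailing
    partial block uses its own minimum) and F0 is the minimum of each
    block's filtered trace, returned as a piecewise-constant array of the
    input shape.  ``smooth_sigma`` is in seconds.
    """
    Fc = np.asarray(Fc, float)
    n = Fc.shape[-1]
    block = max(int(round(block_length * rate)), 1)
    F0 = np.empty_like(Fc)
    for start in range(0, n, block):
        seg = gaussian_filter1d(Fc[..., start : start + block],
                                smooth_sigma * rate, axis=-1, mode="reflect",
                                truncate=FILTER_TRUNCATE)
        F0[..., start : start + block] = seg.min(axis=-1, keepdims=True)
    return F0


def dff(Fc: np.ndarray, F0: np.ndarray) -> np.ndarray:
    """Relative fluorescence change f = (Fc - F0) / F0; requires F0 > 0."""
    F0 = np.asarray(F0, float)
    if np.any(F0 <= 0):
        raise ValueError("baseline F0 must be positive (flag and exclude the neuron)")
    return (np.asarray(Fc, float) - F0) / F0


def deconvolve(f: np.ndarray, rate: float, tau: float = 2.0) -> np.ndarray:
    """Linear deconvolution r = f' + f/tau (forward difference x rate).

    Maps a calcium transient decaying as exp(-t/tau) to zero (up to the
    forward-difference discretization error) and, being linear, cannot by
    itself create integral asymmetries between a stimulus and its time
    reversal.  The last sample's derivative is taken as zero.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    f = np.asarray(f, float)
    r = np.empty_like(f)
    r[..., :-1] = np.diff(f, axis=-1) * rate
    r[..., -1] = 0.0
    r += f / tau
    return r


def preprocess_tensor(
    F: TrialTensor,
    Fnp: np.ndarray | None = None,
    neuropil_weight: float = 0.7,
    tau: float = 2.0,
    baseline_block: float = 42.0,
    baseline_sigma: float = 1.0,
) -> TrialTensor:
    """Full preprocessing chain on a trial tensor -> deconvolved rate.

    Applies neuropil correction (if a neuropil tensor is given), per-trace
    baseline estimation, dF/F and deconvolution.  Traces here are single
    stimulus presentations (a few seconds), shorter than an imaging block,
    so the baseline is per-trace.  Work proceeds in neuron chunks to bound
    peak memory on large populations; the result is float32.
    """
    out = np.empty(F.values.shape, dtype=np.float32)
    chunk = max(1, int(2e7 // max(np.prod(F.values.shape[1:]), 1)))
    for start in range(0, F.n_neurons, chunk):
        sl = slice(start, start + chunk)
        Fc = np.asarray(F.values[sl], dtype=float)
        if Fnp is not None:
            Fc -= neuropil_weight * np.asarray(Fnp[sl], dtype=float)
        F0 = baseline_f0(Fc, F.rate, block_length=baseline_block,
                         smooth_sigma=baseline_sigma)
        f = dff(Fc, F0)
        out[sl] = deconvolve(f, F.rate, tau=tau)
    return F.with_values(out)
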