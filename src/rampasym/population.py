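"""Population-pattern similarity and response-integral asymmetry statistics.

The population response at one time frame of one stimulus is the vector of
deconvolved rates across all neurons.  Similarity between two (stimulus,
frame) conditions is the mean Pearson correlation over all single-trial
vector pairs; for a condition against itself the same-trial pairs are
excluded, making the matrix diagonal a cross-trial reproducibility (and
generally well below 1 for noisy data).

Response integrals are taken over [onset, offset + 500 ms] of the
trial-averaged population rate, and up- vs down-ramp asymmetry is the
normalized integral difference 2 (I_up - I_down) / (I_up + I_down)
(alternatively (I_up - I_down) / I_down).  Across recording sessions,
per-condition one-sided rank tests with Benjamini-Hochberg correction and a
pooled signed-rank test quantify the asymmetry's significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multitest import multipletests

from .containers import TrialTensor

__all__ = [
    "smooth_population",
    "pattern_similarity",
    "similarity_matrix",
    "response_integral",
    "asymmetry_index",
    "asymmetry_tests",
    "AsymmetryResult",
]

log = logging.getLogger(__name__)


def smooth_population(tensor: TrialTensor, sigma: float = 0.060) -> TrialTensor:
    """Temporal Gaussian smoothing (sigma in seconds) per neuron and trial."""
    if sigma <= 0:
        return tensor
    vals = gaussian_filter1d(
        np.asarray(tensor.values, float), sigma * tensor.rate, axis=-1,
        mode="reflect", truncate=4.0,
    )
    return tensor.with_values(vals)


def _pairwise_mean_correlation(A: np.ndarray, B: np.ndarray, same: bool) -> float:
    """Mean Pearson rho over trial pairs of (neurons x trials) matrices.

    ``same=True`` excludes the diagonal pairs i == i'.  Zero-variance
    vectors make their pairs undefined; those pairs are skipped (logged).
    """
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    ok_a = sa > 0
    ok_b = sb > 0
    if not ok_a.all() or not ok_b.all():
        log.warning("skipping %d zero-variance population vectors",
                    int((~ok_a).sum() + (~ok_b).sum()))
    C = (A.T @ B)
    with np.errstate(invalid="ignore", divide="ignore"):
        C /= np.outer(sa, sb)
    valid = np.outer(ok_a, ok_b)
    if same:
        np.fill_diagonal(valid, False)
    if not valid.any():
        return np.nan
    return float(C[valid].mean())


def pattern_similarity(
    tensor: TrialTensor,
    cond_a: tuple[int, int],
    cond_b: tuple[int, int],
) -> float:
    """Similarity between two (stimulus, frame) population patterns.

    Mean Pearson correlation across the neuron dimension over all
    single-trial pairs; identical conditions exclude same-trial pairs
    (cross-trial reproducibility).
    """
    ja, ta = cond_a
    jb, tb = cond_b
    if tensor.n_trials < 2:
        raise ValueError("similarity requires at least 2 trials")
    A = np.asarray(tensor.values[:, ja, :, ta], float)  # neurons x trials
    B = np.asarray(tensor.values[:, jb, :, tb], float)
    return _pairwise_mean_correlation(A, B, same=(cond_a == cond_b))


def similarity_matrix(
    tensor: TrialTensor,
    stimuli: list[int] | None = None,
    frames: slice | None = None,
    sigma: float = 0.060,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Frame-by-frame similarity over a stimulus subset, after smoothing.

    Returns the symmetric matrix (rows/columns indexed by (stimulus, frame)
    pairs) and the axis labels.  The diagonal holds cross-trial
    reproducibilities.
    """
    sm = smooth_population(tensor, sigma)
    stimuli = list(range(sm.n_stimuli)) if stimuli is None else list(stimuli)
    fsl = frames if frames is not None else slice(0, sm.n_frames)
    idx = [(j, t) for j in stimuli for t in range(*fsl.indices(sm.n_frames))]
    # precompute centred/normalized trial matrices per condition
    mats = []
    for j, t in idx:
        A = np.asarray(sm.values[:, j, :, t], float)
        A = A - A.mean(axis=0)
        mats.append(A)
    n = len(idx)
    M = np.empty((n, n))
    for p in range(n):
        for q in range(p, n):
            M[p, q] = M[q, p] = _pairwise_mean_correlation(
                mats[p], mats[q], same=(p == q)
            )
    return M, idx


def response_integral(
    trace: np.ndarray,
    onset: int,
    offset: int,
    rate: float,
    pad: float = 0.5,
) -> float:
    """Trapezoidal integral of a trial-averaged trace over
    [onset, offset + pad seconds]."""
    stop = min(offset + int(round(pad * rate)), len(trace) - 1)
    if stop <= onset:
        raise ValueError("integration window is empty")
    seg = np.asarray(trace[onset : stop + 1], float)
    return float(np.trapezoid(seg, dx=1.0 / rate))


def asymmetry_index(i_up: float, i_down: float, mode: str = "mean") -> float:
    """Normalized up/down integral difference.

    ``mode="mean"``: 2 (I_up - I_down) / (I_up + I_down) (bounded in
    [-2, 2] for positive integrals); ``mode="down"``:
    (I_up - I_down) / I_down.  A zero denominator yields NaN.
    """
    if mode == "mean":
        denom = i_up + i_down
        return np.nan if denom == 0 else 2.0 * (i_up - i_down) / denom
    if mode == "down":
        return np.nan if i_down == 0 else (i_up - i_down) / i_down
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class AsymmetryResult:
    conditions: list[str]
    p_values: np.ndarray  # per condition, one-sided (up > down)
    rejected: np.ndarray  # BH decisions at alpha
    pooled_p: float  # signed-rank on all indices pooled
    indices: dict  # condition -> per-session indices


def asymmetry_tests(
    session_indices: dict,
    alpha: float = 0.05,
) -> AsymmetryResult:
    """Significance of up > down asymmetry across sessions.

    ``session_indices`` maps a condition name to either an array of
    per-session asymmetry indices, or a pair ``(I_up, I_down)`` of
    per-session integral arrays.  Per condition, a one-sided Wilcoxon
    rank-sum test (I_up vs I_down; or a sign test of indices against 0 when
    only indices are given) is computed, Benjamini-Hochberg corrected
    across conditions; all indices pooled enter a one-sided Wilcoxon
    signed-rank test against zero.
    """
    conditions = list(session_indices)
    pvals = []
    index_map = {}
    pooled = []
    for cond in conditions:
        val = session_indices[cond]
        if isinstance(val, tuple):
            i_up = np.asarray(val[0], float)
            i_down = np.asarray(val[1], float)
            if len(i_up) < 5:
                raise ValueError("need >= 5 sessions per condition")
            p = stats.ranksums(i_up, i_down, alternative="greater").pvalue
            idx = np.array(
                [asymmetry_index(u, d) for u, d in zip(i_up, i_down)]
            )
        else:
            idx = np.asarray(val, float)
            if len(idx) < 5:
                raise ValueError("need >= 5 sessions per condition")
            p = stats.wilcoxon(idx, alternative="greater").pvalue
        pvals.append(float(p))
        index_map[cond] = idx
        pooled.append(idx)
    pvals = np.array(pvals)
    rejected = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    pooled = np.concatenate(pooled)
    pooled_p = float(stats.wilcoxon(pooled, alternative="greater").pvalue)
    return AsymmetryResult(
        conditions=conditions, p_values=pvals, rejected=rejected,
        pooled_p=pooled_p, indices=index_map,
    )
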