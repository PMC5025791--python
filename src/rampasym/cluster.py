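"""Response-profile selection, SNR gating, hierarchical clustering and
centroid reassignment.

Neurons are kept if their pooled stimulus responses differ from baseline
(paired Wilcoxon signed-rank, P < 0.05) and differ across stimuli
(Kruskal-Wallis, P < 0.05).  The top 30% by SNR are clustered by
complete linkage on z-scored concatenated trial-mean profiles (smoothed
with a 31 ms Gaussian), the tree is cut at 50 clusters, clusters with
fewer than 10 cells are dropped, and every remaining selected cell is
assigned to the highest-correlating surviving centroid when that Pearson
correlation exceeds 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d

from .containers import TrialTensor

__all__ = [
    "responsiveness_filter",
    "compute_snr",
    "response_profiles",
    "hierarchical_cluster",
    "reassign",
    "cluster_pipeline",
    "ClusterResult",
]

SNR_CAP = 1e6  # guard for noiseless profiles


def _window_means(tensor: TrialTensor, pad: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial baseline and response means, (neurons, stimuli, trials).

    Baseline: the ``pad`` seconds before each onset; response: onset to
    offset + ``pad`` seconds (the integral convention).
    """
    n_pad = int(round(pad * tensor.rate))
    base = np.empty(tensor.values.shape[:3])
    resp = np.empty_like(base)
    for j in range(tensor.n_stimuli):
        on, off = tensor.onsets[j], tensor.offsets[j]
        b0 = max(on - n_pad, 0)
        base[:, j] = tensor.values[:, j, :, b0:on].mean(axis=-1)
        stop = min(off + n_pad, tensor.n_frames)
        resp[:, j] = tensor.values[:, j, :, on:stop].mean(axis=-1)
    return base, resp


def responsiveness_filter(
    tensor: TrialTensor, alpha: float = 0.05, pad: float = 0.5
) -> pd.DataFrame:
    """Responsive (vs baseline) and selective (across stimuli) flags.

    Responsive: paired Wilcoxon signed-rank over pooled (stimulus, trial)
    response-vs-baseline pairs.  Selective: Kruskal-Wallis of per-trial
    response means grouped by stimulus.  Cells passing both are kept.
    """
    base, resp = _window_means(tensor, pad)
    n = tensor.n_neurons
    out = np.zeros((n, 2), dtype=bool)
    for i in range(n):
        d = (resp[i] - base[i]).ravel()
        if np.allclose(d, 0):
            p_resp = 1.0
        else:
            p_resp = stats.wilcoxon(d).pvalue
        groups = [resp[i, j] for j in range(tensor.n_stimuli)]
        try:
            p_sel = stats.kruskal(*groups).pvalue
        except ValueError:  # all values identical
            p_sel = 1.0
        out[i] = (p_resp < alpha, p_sel < alpha)
    return pd.DataFrame(
        {"responsive": out[:, 0], "selective": out[:, 1],
         "keep": out[:, 0] & out[:, 1]}
    )


def compute_snr(trial_responses: np.ndarray) -> float:
    """SNR of a trial-resolved profile (trials x frames).

    Defined as the standard deviation over time of the trial-mean response
    divided by the mean over time of the across-trial standard deviation;
    capped for noiseless input.
    """
    x = np.asarray(trial_responses, float)
    if x.shape[0] < 2:
        raise ValueError("SNR requires at least 2 trials")
    sig = x.mean(axis=0).std()
    noise = x.std(axis=0, ddof=1).mean()
    if noise == 0:
        return SNR_CAP if sig > 0 else 0.0
    return float(min(sig / noise, SNR_CAP))


def response_profiles(
    tensor: TrialTensor, smooth_sigma: float = 0.031
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated smoothed trial-mean profiles and per-neuron SNR.

    Returns ``profiles`` (neurons x (stimuli * frames)) and ``snr``
    (neurons,).  SNR is computed on the concatenated trial-resolved
    profile before trial averaging.
    """
    vals = np.asarray(tensor.values, float)
    sm = gaussian_filter1d(vals, smooth_sigma * tensor.rate, axis=-1,
                           mode="reflect", truncate=4.0)
    mean = sm.mean(axis=2)  # neurons x stimuli x frames
    profiles = mean.reshape(tensor.n_neurons, -1)
    flat_trials = np.swapaxes(sm, 1, 2).reshape(
        tensor.n_neurons, tensor.n_trials, -1
    )
    snr = np.array([compute_snr(flat_trials[i]) for i in range(tensor.n_neurons)])
    return profiles, snr


def _zscore(profiles: np.ndarray) -> np.ndarray:
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (profiles - mu) / sd


def hierarchical_cluster(
    profiles: np.ndarray,
    n_cut: int = 50,
    min_size: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage clustering of z-scored profiles.

    The tree is cut to exactly ``n_cut`` clusters and clusters with fewer
    than ``min_size`` members are dropped.  Returns per-cell labels
    (surviving clusters renumbered 0..k-1, -1 for dropped cells) and the
    linkage matrix.
    """
    profiles = np.asarray(profiles, float)
    if len(profiles) < n_cut:
        raise ValueError(f"need at least n_cut={n_cut} cells, got {len(profiles)}")
    z = _zscore(profiles)
    Z = linkage(z, method="complete", metric="euclidean")
    raw = fcluster(Z, t=n_cut, criterion="maxclust")
    labels = np.full(len(profiles), -1)
    next_id = 0
    for cid in np.unique(raw):
        members = raw == cid
        if members.sum() >= min_size:
            labels[members] = next_id
            next_id += 1
    return labels, Z


def _centroids(profiles_z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels[labels >= 0])
    return np.stack([profiles_z[labels == c].mean(axis=0) for c in ids])


def _corr_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector x against each row of Y."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / denom
    return np.nan_to_num(r, nan=-1.0)


def reassign(
    profiles: np.ndarray,
    core_labels: np.ndarray,
    min_corr: float = 0.1,
) -> pd.DataFrame:
    """Assign non-core cells to the best-correlated surviving centroid.

    Each cell not in a core cluster is given the label of the centroid with
    the highest Pearson correlation to its profile, provided that
    correlation exceeds ``min_corr``; ties break to the lowest cluster id.
    Core cells keep their cluster.  Returns a frame with columns
    ``cluster`` (-1 for unassigned), ``route`` (core / reassigned /
    unassigned) and ``corr`` (correlation to the assigned centroid).
    """
    z = _zscore(np.asarray(profiles, float))
    cents = _centroids(z, core_labels)
    cluster = np.array(core_labels, dtype=int)
    route = np.where(core_labels >= 0, "core", "unassigned").astype(object)
    corr = np.full(len(profiles), np.nan)
    for i in range(len(profiles)):
        r = _corr_rows(z[i], cents)
        if core_labels[i] >= 0:
            corr[i] = r[core_labels[i]]
            continue
        best = int(np.argmax(r))  # argmax takes the lowest index on ties
        if r[best] > min_corr:
            cluster[i] = best
            route[i] = "reassigned"
            corr[i] = r[best]
    return pd.DataFrame({"cluster": cluster, "route": route, "corr": corr})


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Serialize a scipy linkage matrix as a newick tree string."""
    n = Z.shape[0] + 1
    names = leaf_names if leaf_names is not None else [str(i) for i in range(n)]

    def node(i: int, parent_h: float) -> str:
        if i < n:
            return f"{names[i]}:{parent_h:.6g}"
        left, right, h = int(Z[i - n, 0]), int(Z[i - n, 1]), Z[i - n, 2]
        return f"({node(left, h)},{node(right, h)}):{max(parent_h - h, 0.0):.6g}"

    root_h = Z[-1, 2]
    return node(2 * n - 2, root_h) + ";"


@dataclass
class ClusterResult:
    assignments: pd.DataFrame  # per selected neuron (original index kept)
    centroids: np.ndarray
    linkage: np.ndarray
    snr: np.ndarray
    selection: pd.DataFrame
    kept_index: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=True, index_label="neuron")


#: Reference over-segmentation granularity: a 50-cluster cut of ~700
#: clustered cells, i.e. ~14 cells per pre-prune cluster.
CELLS_PER_CUT_CLUSTER = 14


def cluster_pipeline(
    tensor: TrialTensor,
    alpha: float = 0.05,
    snr_quantile: float = 0.70,
    n_cut: int | None = None,
    min_size: int = 10,
    min_corr: float = 0.1,
    smooth_sigma: float = 0.031,
) -> ClusterResult:
    """Selection -> SNR gate -> clustering -> reassignment, end to end.

    The full deconvolved tensor goes in; the result carries assignments for
    the selected (responsive and selective) neurons, indexed by their
    original neuron index.

    ``n_cut`` defaults to ``min(50, n_clustered // 14)``: a 50-cluster cut
    over-segments a ~700-cell clustered set into ~14-cell pieces before the
    minimum-size prune, and that granularity — not the absolute count of
    50 — is what transfers across dataset sizes.  A forced 50-cut of a much
    smaller set would shatter it into pieces below ``min_size`` and prune
    everything.
    """
    selection = responsiveness_filter(tensor, alpha=alpha)
    keep = selection["keep"].to_numpy()
    kept_index = np.flatnonzero(keep)
    sub = tensor.with_values(tensor.values[keep])
    profiles, snr = response_profiles(sub, smooth_sigma=smooth_sigma)
    thr = np.quantile(snr, snr_quantile)
    top = snr >= thr
    if n_cut is None:
        n_cut = min(50, max(int(top.sum()) // CELLS_PER_CUT_CLUSTER, 2))
    core_labels_top, Z = hierarchical_cluster(profiles[top], n_cut=n_cut,
                                              min_size=min_size)
    core_labels = np.full(len(profiles), -1)
    core_labels[np.flatnonzero(top)] = core_labels_top
    assignments = reassign(profiles, core_labels, min_corr=min_corr)
    assignments.index = kept_index
    cents = _centroids(_zscore(profiles), core_labels)
    return ClusterResult(
        assignments=assignments, centroids=cents, linkage=Z, snr=snr,
        selection=selection, kept_index=kept_index,
    )
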