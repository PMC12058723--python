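"""Phase-informed initial segmentation for covariance-state HMMs.

Zero-mean Gaussian HMM likelihood surfaces on phase-coupled oscillatory
data are glassy: EM from generic random starts freezes into "shattered"
solutions whose states are temporal fragments blending several true
coupling patterns.  This module builds a physics-informed starting
segmentation that random restarts cannot reach:

1. pairwise instantaneous phase-difference phasors e^{i(theta_i-theta_j)}
   are smoothed in time, and the pairs whose smoothed phasor varies most
   across the session (the state-dependent couplings) are selected;
2. state-change boundaries are detected as peaks of the feature-jump
   statistic, deliberately over-segmenting (splitting a true occurrence
   is cheap, merging across a boundary is not);
3. segments are merged bottom-up by Ward's criterion on their mean
   phasor patterns, weighted by segment length, down to K clusters.

The resulting labels seed the EM covariances; because segments are
assigned wholesale, shattered configurations are excluded from the
initialization by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .phase_coupling import analytic_signal

__all__ = ["sync_features", "detect_boundaries", "ward_merge_segments",
           "phase_segmentation"]


def sync_features(X: np.ndarray, n_pairs: int = 400,
                  smooth: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed pairwise phase-difference phasors of the most
    state-dependent channel pairs.

    Returns (raw phasors [n_sel x T] complex, smoothed real features
    [2*n_sel x T]).  Pair selection ranks the temporal variance of the
    smoothed phasor: pairs locked in some states and free in others vary
    most, uncoupled drifting pairs average toward zero, and pairs locked
    throughout are constant.
    """
    P, T = X.shape
    theta = np.angle(analytic_signal(X))
    iu = np.triu_indices(P, k=1)
    phasor = np.exp(1j * (theta[iu[0]] - theta[iu[1]]))
    sm = (uniform_filter1d(phasor.real, smooth, axis=1)
          + 1j * uniform_filter1d(phasor.imag, smooth, axis=1))
    variability = sm.real.var(axis=1) + sm.imag.var(axis=1)
    sel = np.argsort(variability)[-min(n_pairs, len(iu[0])):]
    feats = np.concatenate([sm[sel].real, sm[sel].imag], axis=0)
    return phasor[sel], feats


def detect_boundaries(feats: np.ndarray, jump_lag: int = 10,
                      min_gap: int = 8, height_pctl: float = 35.0,
                      min_len: int = 2) -> list[tuple[int, int]]:
    """Candidate occurrence boundaries from feature-jump peaks.

    The statistic is the norm of the feature difference across
    `jump_lag` samples, lightly smoothed; peaks above the given
    percentile split the session into half-open segments.
    """
    T = feats.shape[1]
    jump = np.linalg.norm(feats[:, jump_lag:] - feats[:, :-jump_lag], axis=0)
    jump = uniform_filter1d(jump, 5)
    peaks, _ = find_peaks(jump, distance=min_gap,
                          height=np.percentile(jump, height_pctl))
    bounds = np.concatenate([[0], peaks + jump_lag // 2, [T]])
    bounds = np.unique(np.clip(bounds, 0, T))
    segs = [(int(bounds[i]), int(bounds[i + 1]))
            for i in range(len(bounds) - 1)
            if bounds[i + 1] - bounds[i] >= min_len]
    # re-attach any dropped slivers to the previous segment
    out: list[tuple[int, int]] = []
    cur = 0
    for a, b in segs:
        out.append((cur, b))
        cur = b
    if cur < T:
        if out:
            out[-1] = (out[-1][0], T)
        else:
            out = [(0, T)]
    return out


def ward_merge_segments(phasors: np.ndarray, segments: list[tuple[int, int]],
                        n_clusters: int) -> np.ndarray:
    """Merge segments bottom-up to `n_clusters` by Ward's criterion on
    length-weighted mean phasor patterns; returns per-sample labels."""
    n = len(segments)
    if n <= n_clusters:
        labels = np.empty(phasors.shape[1], dtype=np.int64)
        for k, (a, b) in enumerate(segments):
            labels[a:b] = min(k, n_clusters - 1)
        return labels
    mus = np.array([phasors[:, a:b].mean(axis=1) for a, b in segments])
    ns = np.array([float(b - a) for a, b in segments])
    active = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    # pairwise Ward costs via the Gram trick, updated after each merge
    sq = np.square(np.abs(mus)).sum(-1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * np.real(mus @ mus.conj().T), 0.0)
    w = (ns[:, None] * ns[None, :]) / (ns[:, None] + ns[None, :])
    cost = w * d2
    np.fill_diagonal(cost, np.inf)
    remaining = n
    while remaining > n_clusters:
        flat = np.argmin(cost)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        mus[i] = (ns[i] * mus[i] + ns[j] * mus[j]) / (ns[i] + ns[j])
        ns[i] += ns[j]
        members[i] += members[j]
        active[j] = False
        cost[j, :] = np.inf
        cost[:, j] = np.inf
        idx = np.flatnonzero(active)
        diff = np.square(np.abs(mus[idx] - mus[i])).sum(-1)
        wi = ns[idx] * ns[i] / (ns[idx] + ns[i])
        cost[i, idx] = cost[idx, i] = wi * diff
        cost[i, i] = np.inf
        remaining -= 1
    labels = np.empty(phasors.shape[1], dtype=np.int64)
    for k, i in enumerate(np.flatnonzero(active)):
        for si in members[i]:
            a, b = segments[si]
            labels[a:b] = k
    return labels


def phase_segmentation(X: np.ndarray, n_states: int, n_pairs: int = 400,
                       smooth: int = 25) -> np.ndarray:
    """Full pipeline: features -> boundaries -> Ward merge -> labels [T]."""
    phasors, feats = sync_features(X, n_pairs=n_pairs, smooth=smooth)
    segs = detect_boundaries(feats)
    return ward_merge_segments(phasors, segs, n_states)
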