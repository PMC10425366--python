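"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-sample / per-voxel loops over the
operational definitions, sharing no code with the package implementation,
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_darts(velocity, rate, cs_windows, shock_by_trial, *,
                      threshold=20.0, merge_gap=0.3, min_duration=0.0):
    """Per-sample dart scan.

    ``cs_windows``: list of (start_idx, stop_idx) sample windows (1-based
    trials implied by order); ``shock_by_trial``: dict trial -> shock onset
    sample index (dart search ends there).
    Returns a list of (trial, onset_idx, offset_idx, peak) tuples.
    """
    n = len(velocity)
    runs = []
    i = 0
    while i < n:
        if velocity[i] >= threshold:
            j = i
            while j < n and velocity[j] >= threshold:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) / rate < merge_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    events = []
    for start, stop in merged:
        if (stop - start) / rate < min_duration:
            continue
        for trial, (cs0, cs1) in enumerate(cs_windows, start=1):
            end = min(cs1, shock_by_trial.get(trial, cs1))
            if cs0 <= start < end:
                clip = min(stop, end)
                peak = max(velocity[start:clip])
                events.append((trial, start, clip, float(peak)))
                break
    return events


def brute_force_freezing(velocity, rate, *, threshold=0.5, min_bout=1.0):
    """Per-sample freezing scan; returns (onset_idx, offset_idx) bouts."""
    n = len(velocity)
    bouts = []
    i = 0
    while i < n:
        if velocity[i] < threshold:
            j = i
            while j < n and velocity[j] < threshold:
                j += 1
            if (j - i) / rate >= min_bout - 1e-12:
                bouts.append((i, j))
            i = j
        else:
            i += 1
    return bouts


def split_plot_anova(y, group_of_subject):
    """Brute-force balanced split-plot ANOVA sums of squares.

    ``y``: (n_subjects, k) response matrix; ``group_of_subject``: length-n
    integer group labels.  Returns dict of F statistics and df pairs for
    the between, within and interaction effects, from the textbook SS
    decomposition.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group_of_subject)
    n, k = y.shape
    groups = np.unique(g)
    G = len(groups)
    gm = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[g == gg].mean() for gg in groups])
    time_means = y.mean(axis=0)
    cell_means = np.array([y[g == gg].mean(axis=0) for gg in groups])
    n_g = np.array([(g == gg).sum() for gg in groups])

    ss_between = k * float(np.sum(n_g * (group_means - gm) ** 2))
    ss_subj = k * float(
        sum(
            ((subj_means[g == gg] - group_means[i]) ** 2).sum()
            for i, gg in enumerate(groups)
        )
    )
    ss_time = n * float(((time_means - gm) ** 2).sum())
    ss_inter = float(
        sum(
            n_g[i]
            * ((cell_means[i] - group_means[i] - time_means + gm) ** 2).sum()
            for i in range(G)
        )
    )
    ss_err = 0.0
    for i, gg in enumerate(groups):
        sub = y[g == gg]
        sm = sub.mean(axis=1, keepdims=True)
        ss_err += float(((sub - cell_means[i] - sm + group_means[i]) ** 2).sum())

    df_b = (G - 1, n - G)
    df_w = (k - 1, (n - G) * (k - 1))
    f_b = (ss_between / df_b[0]) / (ss_subj / df_b[1])
    f_w = (ss_time / df_w[0]) / (ss_err / df_w[1])
    f_i = (ss_inter / ((G - 1) * (k - 1))) / (ss_err / df_w[1])
    return {
        "between": (f_b, df_b),
        "within": (f_w, df_w),
        "interaction": (f_i, ((G - 1) * (k - 1), (n - G) * (k - 1))),
    }


def brute_force_shell(soma, radius_px):
    """Per-voxel in-plane shell: min Euclidean distance to soma pixels.

    O(n^2) per slice via explicit pairwise distances; exact, so the EDT
    implementation must agree voxel for voxel.
    """
    from scipy.spatial.distance import cdist

    soma = np.asarray(soma, dtype=bool)
    shell = np.zeros_like(soma)
    for z in range(soma.shape[0]):
        pts = np.argwhere(soma[z])
        if len(pts) == 0:
            continue
        all_px = np.argwhere(np.ones_like(soma[z]))
        d = cdist(all_px.astype(float), pts.astype(float)).min(axis=1)
        mask = (d > 0) & (d <= radius_px)
        shell[z][tuple(all_px[mask].T)] = True
    return shell
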