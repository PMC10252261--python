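"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most transparent method available
(explicit loops, exhaustive enumeration, closed forms) and is kept
deliberately independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bruteforce_roi_circle_stats(slab, cx, cy, r_mm, sx, sy):
    """Mean/sample-SD over a circular ROI by explicit per-voxel loops."""
    values = []
    nx, ny = slab.shape
    for i in range(nx):
        for j in range(ny):
            dx = (i - cx) * sx
            dy = (j - cy) * sy
            if dx * dx + dy * dy <= r_mm * r_mm:
                values.append(float(slab[i, j]))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var**0.5, n


def _neighbor_offsets(connectivity: str):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if connectivity == "face" and sum(abs(v) for v in d) != 1:
            continue
        offs.append(d)
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: str = "face_edge_vertex"):
    """Connected components by breadth-first flood fill.

    Returns a label array (0 background; components numbered in first-voxel
    scan order) and the list of component voxel-index sets.
    """
    mask = np.asarray(mask, dtype=bool)
    offsets = _neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    components = []
    nx, ny, nz = mask.shape
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        labels[start] = next_label
        comp = {start}
        queue = deque([start])
        while queue:
            x, y, z = queue.popleft()
            for ox, oy, oz in offsets:
                nxt = (x + ox, y + oy, z + oz)
                if not (0 <= nxt[0] < nx and 0 <= nxt[1] < ny and 0 <= nxt[2] < nz):
                    continue
                if mask[nxt] and not labels[nxt]:
                    labels[nxt] = next_label
                    comp.add(nxt)
                    queue.append(nxt)
        components.append(comp)
    return labels, components


def anova_icc(table: np.ndarray, definition: str = "consistency"):
    """ICC point estimate from explicitly looped ANOVA sums of squares."""
    arr = np.asarray(table, dtype=float)
    n, k = arr.shape
    grand = arr.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        row_mean = arr[i].sum() / k
        ss_rows += k * (row_mean - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        col_mean = arr[:, j].sum() / n
        ss_cols += n * (col_mean - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (arr[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if definition == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def exact_wilcoxon_p(x, y):
    """Two-sided signed-rank p-value by exhaustive sign enumeration.

    Assumes no zero differences and no tied |d|.  Uses the standard
    two-sided convention 2*min(P(W<=w), P(W>=w)), capped at 1.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def exact_mannwhitney_p(x, y):
    """Two-sided Mann-Whitney p-value by exhaustive group relabeling."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return float(gt) + 0.5 * float(eq)

    u_obs = u_stat(range(n1))
    n = pooled.size
    mean_u = n1 * (n - n1) / 2.0
    us = np.array([u_stat(c) for c in itertools.combinations(range(n), n1)])
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))
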