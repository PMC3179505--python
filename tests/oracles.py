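"""Independent brute-force oracles the implementation is checked against.

Each routine here deliberately uses a different algorithm (and often a
different numerical route) from the package code it validates.
"""

from __future__ import annotations

import numpy as np
from mpmath import mp


def rmsd_by_rotation_grid(mobile, reference, step_deg: float = 2.0) -> float:
    """Minimum RMSD over an exhaustive z-y-z Euler-angle grid."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    alphas = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    betas = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    gammas = np.deg2rad(np.arange(0.0, 360.0, step_deg))

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        out = np.zeros(t.shape + (3, 3))
        out[..., 0, 0] = c
        out[..., 0, 1] = -s
        out[..., 1, 0] = s
        out[..., 1, 1] = c
        out[..., 2, 2] = 1.0
        return out

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        out = np.zeros(t.shape + (3, 3))
        out[..., 0, 0] = c
        out[..., 0, 2] = s
        out[..., 2, 0] = -s
        out[..., 2, 2] = c
        out[..., 1, 1] = 1.0
        return out

    best = np.inf
    rg = rz(gammas)  # (G,3,3)
    for alpha in alphas:
        ra = rz(np.array(alpha))
        for beta in betas:
            rab = ra @ ry(np.array(beta))  # (3,3)
            rots = np.einsum("ij,gjk->gik", rab, rg)
            moved = np.einsum("gij,nj->gni", rots, a)
            rmsd = np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=2), axis=1))
            m = rmsd.min()
            if m < best:
                best = float(m)
    return best


def path_cv_mpmath(config, frames, align_idx, disp_idx, lam, msd_func, dps: int = 50):
    """S, Z by direct summation in 50-digit arithmetic.

    The MSD values come from ``msd_func`` (the metric under test is not
    re-derived here — this oracle checks the exponential-sum evaluation,
    including its log-sum-exp stability, not the metric).
    """
    with mp.workdps(dps):
        dvals = [mp.mpf(repr(msd_func(config, frames[p], align_idx, disp_idx)))
                 for p in range(len(frames))]
        lam_hp = mp.mpf(repr(float(lam)))
        weights = [mp.e ** (-lam_hp * d) for d in dvals]
        wsum = mp.fsum(weights)
        s = mp.fsum((p + 1) * w for p, w in enumerate(weights)) / wsum
        z = -mp.log(wsum) / lam_hp
        return float(s), float(z)


def naive_bias_sum(s, z, times, s_c, z_c, heights, sig_s, sig_z, t):
    """Plain double-loop hill summation."""
    total = 0.0
    for k in range(len(times)):
        if times[k] < t:
            total += (
                heights[k]
                * np.exp(-((s - s_c[k]) ** 2) / (2.0 * sig_s[k] ** 2))
                * np.exp(-((z - z_c[k]) ** 2) / (2.0 * sig_z[k] ** 2))
            )
    return total


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def clusters_by_union_find(dist_matrix, cutoff):
    """Connected components of the thresholded distance graph."""
    n = dist_matrix.shape[0]
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if dist_matrix[i, j] <= cutoff:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def minimax_barrier_by_percolation(values, start, goal):
    """Lowest maximal cell value along any 4-connected path, minus the
    value at start — found by threshold percolation (binary search over
    the sorted cell values, flood fill at each threshold)."""
    levels = np.unique(values)
    ns, nz = values.shape

    def connected(thr):
        if values[start] > thr or values[goal] > thr:
            return False
        seen = np.zeros_like(values, dtype=bool)
        stack = [start]
        seen[start] = True
        while stack:
            i, j = stack.pop()
            if (i, j) == goal:
                return True
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < ns and 0 <= b < nz and not seen[a, b] and values[a, b] <= thr:
                    seen[a, b] = True
                    stack.append((a, b))
        return False

    lo, hi = 0, len(levels) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(levels[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(levels[lo] - values[start])


def finite_difference_gradient(func, x, eps=1e-5):
    """Central finite differences of a scalar function of (N, 3) coords."""
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for c in range(3):
            xp = x.copy()
            xm = x.copy()
            xp[i, c] += eps
            xm[i, c] -= eps
            g[i, c] = (func(xp) - func(xm)) / (2.0 * eps)
    return g
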