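"""Independent numerical oracles used by the test suite.

These deliberately avoid the library's analytic/search code paths:
profiles come from dense-grid discrete convolution, rank-test p-values
from exhaustive enumeration of permutations/sign assignments.
"""

import itertools
import math

import numpy as np
from scipy import ndimage


def discrete_convolution_oracle(R, sigma, radii, dx=0.25, n_dirs=8, seed=123):
    """Radial profile of a unit sphere blurred by an isotropic Gaussian,
    from brute-force convolution of an anti-aliased sphere mask on a
    fine grid; evaluated by spline interpolation averaged over random
    directions."""
    half = R + 6.0 * sigma + 2.0
    n = int(math.ceil(2 * half / dx)) | 1  # odd so a node sits at the center
    ax = (np.arange(n) - (n - 1) / 2) * dx
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    d = np.sqrt(X**2 + Y**2 + Z**2)
    mask = (d <= R).astype(np.float32)
    band = np.abs(d - R) <= dx * math.sqrt(3.0) / 2.0
    if np.any(band):
        idx = np.argwhere(band)
        centers = (idx - (n - 1) / 2) * dx
        sub = 4
        offs = ((np.arange(sub) + 0.5) / sub - 0.5) * dx
        acc = np.zeros(len(centers), dtype=np.float64)
        for ox in offs:
            for oy in offs:
                for oz in offs:
                    p = centers + np.array([ox, oy, oz])
                    acc += (np.linalg.norm(p, axis=1) <= R)
        mask[band] = (acc / sub**3).astype(np.float32)
    blurred = ndimage.gaussian_filter(mask, sigma=sigma / dx, truncate=6.0)
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.asarray(radii, dtype=float)
    pts = (radii[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
    coords = (pts - ax[0]) / dx  # index units
    vals = ndimage.map_coordinates(blurred.astype(np.float64), coords.T, order=3)
    return vals.reshape(len(radii), n_dirs).mean(axis=1)


def wilcoxon_signed_rank_exact_p(d):
    """Two-sided p by enumerating all 2^n sign assignments of |d| ranks."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats, dtype=float)
    p_low = np.mean(stats <= w_obs + 1e-12)
    p_high = np.mean(stats >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney_exact_p(a, b):
    """Two-sided p by enumerating all group assignments of the pooled
    sample (via permutations, counting duplicates naturally)."""
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x_idx):
        ranks = rankdata(pooled)
        r1 = ranks[list(x_idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_stat(range(n1))
    mu = n1 * len(b) / 2.0
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    us = np.asarray(us)
    p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return min(1.0, float(p))


def kruskal_exact_p(groups):
    """Exact p for the tie-corrected H by permuting pooled values."""
    from scipy.stats import rankdata

    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts**3 - counts))

    def h_of(perm):
        h = 0.0
        start = 0
        for sz in sizes:
            rsum = ranks[list(perm[start:start + sz])].sum()
            h += rsum**2 / sz
            start += sz
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        if tie > 0:
            h /= 1.0 - tie / (n**3 - n)
        return h

    h_obs = h_of(list(range(n)))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        if h_of(perm) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total
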