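"""Binned kernel-density utilities.

Both the primary gate and marker-threshold estimation work on smoothed
histograms (a binned KDE): exact Gaussian KDE is O(n * grid) and far too
slow at cytometry event counts, while histogram + Gaussian filter is a
standard, numerically equivalent approximation once the bin width is well
below the bandwidth.  Bandwidths follow Silverman's rule, computed from the
number of *distinct* values so that duplicating events leaves every density
— and hence every derived cutoff — bit-identical.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

__all__ = ["smoothed_density_1d", "find_modes_1d", "density_grid_2d",
           "grid_basins", "merge_shallow_basins"]


def _silverman(x: np.ndarray, d: int = 1) -> float:
    """Silverman bandwidth; n counts distinct values (duplication-invariant)."""
    n = np.unique(x).size
    if n < 2:
        return 1e-12
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        return 1e-12
    exponent = -1.0 / (d + 4)
    return 0.9 * scale * n ** exponent if d == 1 else scale * n ** exponent


def smoothed_density_1d(x: np.ndarray, bins: int = 512):
    """Return (bin_centers, smoothed density, bandwidth) for 1-D data."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    pad = 0.05 * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    width = edges[1] - edges[0]
    bw = max(_silverman(x), width)
    dens = gaussian_filter1d(counts.astype(float), sigma=bw / width, mode="constant")
    dens /= max(dens.sum() * width, 1e-300)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens, bw


def find_modes_1d(dens: np.ndarray, floor_frac: float = 1e-3,
                  merge_frac: float = 0.5) -> list[int]:
    """Indices of well-separated local maxima of a smoothed density.

    Local maxima below ``floor_frac`` of the global maximum are discarded
    (they are histogram noise); of any two maxima whose intervening valley
    does not dip below ``merge_frac`` of the smaller peak, the smaller is
    dropped (a shoulder, not a population).  Sorted by position.
    """
    d = np.asarray(dens)
    interior = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    peaks = [int(i) for i in interior if d[i] >= floor_frac * d.max()]
    if d.size and d[0] > d[1] and d[0] >= floor_frac * d.max():
        peaks.insert(0, 0)
    if d.size and d[-1] > d[-2] and d[-1] >= floor_frac * d.max():
        peaks.append(d.size - 1)
    peaks = sorted(set(peaks))
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        best_j, best_rel = -1, -1.0
        for j in range(len(peaks) - 1):
            a, b = peaks[j], peaks[j + 1]
            valley = d[a:b + 1].min()
            rel = valley / min(d[a], d[b])
            if rel > best_rel:
                best_rel, best_j = rel, j
        if best_rel >= merge_frac:
            a, b = peaks[best_j], peaks[best_j + 1]
            peaks.remove(a if d[a] < d[b] else b)
            changed = True
    return peaks


def density_grid_2d(x: np.ndarray, y: np.ndarray, bins: int = 128):
    """Smoothed 2-D histogram density.

    Returns ``(H, x_centers, y_centers)`` with ``H[i, j]`` the density at
    ``(x_centers[i], y_centers[j])``.
    """
    def edges_for(v):
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi <= lo:
            hi = lo + 1.0
        pad = 0.05 * (hi - lo)
        return np.linspace(lo - pad, hi + pad, bins + 1)

    ex, ey = edges_for(x), edges_for(y)
    H, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    wx, wy = ex[1] - ex[0], ey[1] - ey[0]
    bx = max(_silverman(x, d=2), wx)
    by = max(_silverman(y, d=2), wy)
    H = gaussian_filter(H, sigma=(bx / wx, by / wy), mode="constant")
    return H, 0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:]), ex, ey


def grid_basins(H: np.ndarray) -> np.ndarray:
    """Steepest-ascent basin of attraction for every grid cell.

    Each cell points at its largest 3x3 neighbour (itself if it is the
    local maximum); pointer-jumping converges to a flat array mapping every
    cell to the flat index of the mode whose basin contains it.
    """
    n0, n1 = H.shape
    padded = np.full((n0 + 2, n1 + 2), -np.inf)
    padded[1:-1, 1:-1] = H
    best = np.full(H.shape, -np.inf)
    target = np.zeros(H.shape, dtype=np.int64)
    idx = np.arange(n0 * n1).reshape(H.shape)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            neigh = padded[1 + di:1 + di + n0, 1 + dj:1 + dj + n1]
            # strict improvement keeps self-pointing on plateaus deterministic
            take = neigh > best
            best[take] = neigh[take]
            ti = np.clip(np.arange(n0)[:, None] + di, 0, n0 - 1)
            tj = np.clip(np.arange(n1)[None, :] + dj, 0, n1 - 1)
            tgt = (ti * n1 + tj)
            target[take] = np.broadcast_to(tgt, H.shape)[take]
    ptr = target.ravel()
    for _ in range(64):  # pointer jumping: converges in O(log path length)
        nxt = ptr[ptr]
        if np.array_equal(nxt, ptr):
            break
        ptr = nxt
    return ptr


def merge_shallow_basins(H: np.ndarray, basins: np.ndarray,
                         merge_frac: float = 0.5) -> np.ndarray:
    """Watershed merging of basins separated by shallow saddles.

    Two basins whose boundary saddle density does not dip below
    ``merge_frac`` of the smaller peak describe one population (a shoulder,
    not a separate cluster), mirroring the 1-D mode-merge rule.  Returns a
    flat array mapping every cell to its merged representative root (the
    highest peak of its merged group).
    """
    n0, n1 = H.shape
    lab = basins.reshape(n0, n1)
    saddle: dict = {}

    def accumulate(a_lab, b_lab, a_h, b_h):
        diff = a_lab != b_lab
        if not np.any(diff):
            return
        ra, rb = a_lab[diff], b_lab[diff]
        lo, hi = np.minimum(ra, rb), np.maximum(ra, rb)
        val = np.minimum(a_h[diff], b_h[diff])
        for key, v in zip(lo * (n0 * n1) + hi, val):
            k = int(key)
            if v > saddle.get(k, -np.inf):
                saddle[k] = float(v)

    accumulate(lab[:, :-1], lab[:, 1:], H[:, :-1], H[:, 1:])
    accumulate(lab[:-1, :], lab[1:, :], H[:-1, :], H[1:, :])
    accumulate(lab[:-1, :-1], lab[1:, 1:], H[:-1, :-1], H[1:, 1:])
    accumulate(lab[:-1, 1:], lab[1:, :-1], H[:-1, 1:], H[1:, :-1])

    height = {int(r): float(H.ravel()[int(r)]) for r in np.unique(basins)}
    rep = {r: r for r in height}

    def find(r):
        while rep[r] != r:
            rep[r] = rep[rep[r]]
            r = rep[r]
        return r

    pairs = {(k // (n0 * n1), k % (n0 * n1)): v for k, v in saddle.items()}
    changed = True
    while changed:
        changed = False
        best, best_rel = None, merge_frac
        for (a, b), v in pairs.items():
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            denom = min(height[ra], height[rb])
            if denom <= 0:  # empty-space basin: holds no events, never merge
                continue
            rel = v / denom
            if rel >= best_rel:
                best_rel, best = rel, (ra, rb)
        if best is not None:
            ra, rb = best
            keep, drop = (ra, rb) if height[ra] >= height[rb] else (rb, ra)
            rep[drop] = keep
            changed = True
    return np.array([find(int(r)) for r in basins])
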