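"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately written without the shortcuts (statsmodels fits,
np.interp, greedy clumping) used by the package, so agreement is a genuine
cross-check rather than a tautology.
"""

import numpy as np


def wls_origin(x, y, w):
    """Origin-constrained weighted least squares by direct summation.

    Returns (slope, fixed-effect se, residual variance scale RSS_w/(n-1)).
    """
    x, y, w = map(np.asarray, (x, y, w))
    sxx = float(sum(wi * xi * xi for wi, xi in zip(w, x)))
    sxy = float(sum(wi * xi * yi for wi, xi, yi in zip(w, x, y)))
    b = sxy / sxx
    rss = float(sum(wi * (yi - b * xi) ** 2 for wi, xi, yi in zip(w, x, y)))
    scale = rss / (len(x) - 1) if len(x) > 1 else 0.0
    return b, 1.0 / sxx**0.5, scale


def wls_intercept(x, y, w):
    """Weighted least squares with intercept via explicit normal equations.

    Returns (intercept, slope, se_intercept, se_slope, scale) with the SEs
    unscaled (sampling-variance weights taken at face value) and scale the
    weighted residual variance RSS_w/(n-2).
    """
    x, y, w = map(np.asarray, (x, y, w))
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    a_mat = np.array([[sw, swx], [swx, swxx]])
    rhs = np.array([swy, swxy])
    b0, b1 = np.linalg.solve(a_mat, rhs)
    cov = np.linalg.inv(a_mat)
    rss = float((w * (y - b0 - b1 * x) ** 2).sum())
    scale = rss / (len(x) - 2)
    return float(b0), float(b1), float(cov[0, 0] ** 0.5), float(cov[1, 1] ** 0.5), scale


def weighted_median_scan(r, w):
    """Interpolated weighted median by explicit bracketing of the quantile
    function, no vectorized interpolation."""
    order = np.argsort(r, kind="stable")
    r = np.asarray(r)[order]
    w = np.asarray(w)[order]
    total = w.sum()
    cum = 0.0
    p = []
    for wi in w:
        p.append((cum + 0.5 * wi) / total)
        cum += wi
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    for i in range(len(p) - 1):
        if p[i] <= 0.5 <= p[i + 1]:
            frac = (0.5 - p[i]) / (p[i + 1] - p[i])
            return float(r[i] + frac * (r[i + 1] - r[i]))
    raise AssertionError("unreachable")


def kernel_mode_grid(r, w, bandwidth, n_grid=20001):
    """Mode of the weighted normal-kernel density by dense grid search."""
    r = np.asarray(r, float)
    w = np.asarray(w, float)
    grid = np.linspace(r.min() - 3 * bandwidth, r.max() + 3 * bandwidth, n_grid)
    dens = np.zeros_like(grid)
    for ri, wi in zip(r, w):
        dens += wi * np.exp(-0.5 * ((grid - ri) / bandwidth) ** 2)
    return float(grid[int(np.argmax(dens))])


def clump_valid(table_df, ld, retained, r2_threshold, window_kb):
    """Exhaustively verify a clumping result: no retained pair conflicts,
    and every dropped variant conflicts with a retained variant of smaller
    (p-value, snp_id) rank."""
    df = table_df.set_index("snp_id")
    rank = {
        sid: (df.loc[sid, "pval"], sid) for sid in df.index
    }

    def conflicts(a, b):
        ra, rb = df.loc[a], df.loc[b]
        same_chrom = str(ra["chrom"]) == str(rb["chrom"])
        close = abs(float(ra["pos"]) - float(rb["pos"])) <= window_kb * 1000
        return same_chrom and close and ld.r2_between(a, b) >= r2_threshold

    retained_set = set(retained)
    for a in retained:
        for b in retained:
            if a < b and conflicts(a, b):
                return False
    for sid in df.index:
        if sid in retained_set:
            continue
        if not any(
            conflicts(sid, kept) and rank[kept] < rank[sid] for kept in retained
        ):
            return False
    return True
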