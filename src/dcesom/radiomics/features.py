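"""Texture-matrix construction and feature computation for one analysis window.

All computations follow the Image Biomarker Standardisation Initiative (IBSI)
reference definitions, specialized to the 2-D convolutional setting used
here: a square window of quantized gray levels (1..Ng), Chebyshev distance 1,
8-connected neighborhoods.  Gray-level co-occurrence and run-length matrices
are built per 2-D direction (0, 45, 90, 135 degrees) and their features
averaged over directions; size-zone, distance-zone, gray-tone-difference and
gray-level-dependence matrices are built once per window.

Degenerate-case conventions (documented here, mirrored by the tests'
brute-force oracle): statistics normalized by a vanishing spread (skewness,
kurtosis, correlation-type features) fall back to 0, except GLCM correlation
which is 1 for a constant window; NGTDM coarseness saturates at 1e6 when its
denominator vanishes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sklabel

_LOG2 = np.log(2.0)
COARSENESS_CAP = 1e6

#: (drow, dcol) offsets for the four 2-D directions at Chebyshev distance 1
DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p) / _LOG2).sum())


def _percentile(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q))


# ---------------------------------------------------------------------------
# intensity statistics (shared by the histogram and intensity-based families)


def _moment_stats(x: np.ndarray) -> dict[str, float]:
    n = x.size
    mean = x.mean()
    var = float(((x - mean) ** 2).mean())
    sd = np.sqrt(var)
    skew = float((((x - mean) / sd) ** 3).mean()) if sd > 0 else 0.0
    kurt = float((((x - mean) / sd) ** 4).mean()) - 3.0 if sd > 0 else 0.0
    p10, p25, p50, p75, p90 = (float(v) for v in np.percentile(x, (10, 25, 50, 75, 90)))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    return {
        "mean": float(mean),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": p50,
        "minimum": float(x.min()),
        "p10": p10,
        "p90": p90,
        "maximum": float(x.max()),
        "interquartile_range": p75 - p25,
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": rmad,
        "median_absolute_deviation": float(np.abs(x - p50).mean()),
        "coefficient_of_variation": float(sd / mean) if mean != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (
            float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0
        ),
    }


def ih_features(levels: np.ndarray, ng: int) -> dict[str, float]:
    """21 intensity-histogram features of the quantized window."""
    x = np.asarray(levels, dtype=float).ravel()
    out = {f"ih_{k}": v for k, v in _moment_stats(x).items()}
    counts = np.bincount(levels.ravel().astype(int), minlength=ng + 1)[1:]
    p = counts / counts.sum()
    modes = np.flatnonzero(counts == counts.max()) + 1
    out["ih_mode"] = float(modes[0])  # ties -> lowest level
    out["ih_entropy"] = _entropy(p)
    out["ih_uniformity"] = float((p**2).sum())
    grad = np.empty(ng)
    grad[0] = counts[1] - counts[0]
    grad[-1] = counts[-1] - counts[-2]
    grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    out["ih_max_gradient"] = float(grad.max())
    out["ih_min_gradient"] = float(grad.min())
    return out


def ibs_features(values: np.ndarray) -> dict[str, float]:
    """17 intensity-based statistical features of the raw (unquantized) window."""
    x = np.asarray(values, dtype=float).ravel()
    out = {f"ibs_{k}": v for k, v in _moment_stats(x).items()}
    out["ibs_energy"] = float((x**2).sum())
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(window: np.ndarray, direction: tuple[int, int], ng: int) -> np.ndarray:
    """Symmetric co-occurrence probability matrix (ng x ng) for one direction."""
    lv, p = glcm_compact(window, direction)
    dense = np.zeros((ng, ng))
    dense[np.ix_(lv - 1, lv - 1)] = p
    return dense


def glcm_compact(window: np.ndarray, direction: tuple[int, int]):
    """Co-occurrence probabilities over the levels present in the window.

    Returns ``(levels, p)`` with ``levels`` the sorted distinct gray levels
    and ``p`` the symmetric normalized co-occurrence matrix on that support.
    """
    lv, inv = np.unique(window, return_inverse=True)
    idx = inv.reshape(window.shape)
    return lv.astype(np.int64), _glcm_prob(idx, lv.size, direction)


def _glcm_prob(idx: np.ndarray, n_levels: int, direction: tuple[int, int]) -> np.ndarray:
    """Symmetric co-occurrence probabilities of a relabeled (0..L-1) window."""
    dr, dc = direction
    nr, nc = idx.shape
    r0 = max(0, -dr)
    r1 = min(nr, nr - dr)
    c0 = max(0, -dc)
    c1 = min(nc, nc - dc)
    a = idx[r0:r1, c0:c1].ravel()
    b = idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).astype(float)
    counts = counts.reshape(n_levels, n_levels)
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(levels: np.ndarray, p: np.ndarray, ng: int) -> dict[str, float]:
    """25 co-occurrence features from a normalized symmetric GLCM.

    ``levels`` carries the gray-level value of each row/column of ``p`` so a
    compact support can be used; ``ng`` enters only the normalized variants.
    """
    idx = np.asarray(levels, dtype=float)
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float(idx @ px)
    sigma2 = float(((idx - mu) ** 2) @ px)

    ii = idx[:, None]
    jj = idx[None, :]
    diff = np.abs(ii - jj)

    # difference / sum marginals, grouped by integer |i-j| and i+j
    diff_int = np.abs(levels[:, None] - levels[None, :]).ravel()
    p_diff = np.bincount(diff_int, weights=p.ravel())
    k_diff = np.arange(p_diff.size, dtype=float)
    sum_int = (levels[:, None] + levels[None, :]).ravel()
    p_sum_full = np.bincount(sum_int, weights=p.ravel())
    k_sum = np.arange(p_sum_full.size, dtype=float)

    da = float(k_diff @ p_diff)
    sa = float(k_sum @ p_sum_full)
    joint_avg = float((ii * p).sum())

    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    outer = px[:, None] * px[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_outer = np.where(outer > 0, np.log(outer) / _LOG2, 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer * log_outer).sum())

    inv_var_mask = diff > 0
    corr = float(((ii * jj * p).sum() - mu * mu) / sigma2) if sigma2 > 0 else 1.0

    out = {
        "glcm_joint_maximum": float(p.max()),
        "glcm_joint_average": joint_avg,
        "glcm_joint_variance": float((((ii - joint_avg) ** 2) * p).sum()),
        "glcm_joint_entropy": hxy,
        "glcm_difference_average": da,
        "glcm_difference_variance": float(((k_diff - da) ** 2) @ p_diff),
        "glcm_difference_entropy": _entropy(p_diff),
        "glcm_sum_average": sa,
        "glcm_sum_variance": float(((k_sum - sa) ** 2) @ p_sum_full),
        "glcm_sum_entropy": _entropy(p_sum_full),
        "glcm_angular_second_moment": float((p**2).sum()),
        "glcm_contrast": float((diff**2 * p).sum()),
        "glcm_dissimilarity": float((diff * p).sum()),
        "glcm_inverse_difference": float((p / (1.0 + diff)).sum()),
        "glcm_inverse_difference_normalized": float((p / (1.0 + diff / ng)).sum()),
        "glcm_inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "glcm_inverse_difference_moment_normalized": float(
            (p / (1.0 + diff**2 / ng**2)).sum()
        ),
        "glcm_inverse_variance": float((p[inv_var_mask] / diff[inv_var_mask] ** 2).sum()),
        "glcm_correlation": corr,
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_tendency": float((((ii + jj - 2 * mu) ** 2) * p).sum()),
        "glcm_cluster_shade": float((((ii + jj - 2 * mu) ** 3) * p).sum()),
        "glcm_cluster_prominence": float((((ii + jj - 2 * mu) ** 4) * p).sum()),
        "glcm_information_correlation_1": (
            float((hxy - hxy1) / hx) if hx > 0 else 0.0
        ),
        "glcm_information_correlation_2": float(
            np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
        ),
    }
    return out


# ---------------------------------------------------------------------------
# run-length / zone families (shared 16-feature template)


def _rlm_style_features(
    prefix: str,
    counts: np.ndarray,  # (n_levels, n_sizes) raw counts, level i=1.., size j=1..
    n_voxels: int,
    size_names: tuple[str, str, str, str, str, str],
) -> dict[str, float]:
    """The 16-feature template shared by GLRLM/GLSZM/GLDZM.

    ``size_names`` supplies the family-specific names for (small-emphasis,
    large-emphasis, size-nonuniformity, size-nonuniformity-normalized,
    size-variance, size-entropy) in that order.
    """
    ns = counts.sum()
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    ri = counts.sum(axis=1)
    rj = counts.sum(axis=0)
    p = counts / ns
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    small, large, nu, nun, var, ent = size_names
    return {
        f"{prefix}_{small}": float((counts / j**2).sum() / ns),
        f"{prefix}_{large}": float((counts * j**2).sum() / ns),
        f"{prefix}_low_grey_level_emphasis": float((counts / i**2).sum() / ns),
        f"{prefix}_high_grey_level_emphasis": float((counts * i**2).sum() / ns),
        f"{prefix}_{small}_low_grey_level": float((counts / (i**2 * j**2)).sum() / ns),
        f"{prefix}_{small}_high_grey_level": float((counts * i**2 / j**2).sum() / ns),
        f"{prefix}_{large}_low_grey_level": float((counts * j**2 / i**2).sum() / ns),
        f"{prefix}_{large}_high_grey_level": float((counts * i**2 * j**2).sum() / ns),
        f"{prefix}_grey_level_nonuniformity": float((ri**2).sum() / ns),
        f"{prefix}_grey_level_nonuniformity_normalized": float((ri**2).sum() / ns**2),
        f"{prefix}_{nu}": float((rj**2).sum() / ns),
        f"{prefix}_{nun}": float((rj**2).sum() / ns**2),
        f"{prefix}_percentage": float(ns / n_voxels),
        f"{prefix}_grey_level_variance": float((((i - mu_i) ** 2) * p).sum()),
        f"{prefix}_{var}": float((((j - mu_j) ** 2) * p).sum()),
        f"{prefix}_{ent}": _entropy(p.ravel()),
    }


_GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_length_variance",
    "run_entropy",
)
_GLSZM_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "zone_size_nonuniformity",
    "zone_size_nonuniformity_normalized",
    "zone_size_variance",
    "zone_size_entropy",
)
_GLDZM_NAMES = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "zone_distance_nonuniformity",
    "zone_distance_nonuniformity_normalized",
    "zone_distance_variance",
    "zone_distance_entropy",
)


def glrlm_counts(window: np.ndarray, direction: tuple[int, int], ng: int) -> np.ndarray:
    """Run-length count matrix (ng x max_run) along one direction."""
    nr, nc = window.shape
    max_run = max(nr, nc)
    counts = np.zeros((ng, max_run))
    dr, dc = direction
    for r in range(nr):
        for c in range(nc):
            rr, cc = r - dr, c - dc
            if 0 <= rr < nr and 0 <= cc < nc and window[rr, cc] == window[r, c]:
                continue  # not the start of a maximal run
            length = 1
            rr, cc = r + dr, c + dc
            while 0 <= rr < nr and 0 <= cc < nc and window[rr, cc] == window[r, c]:
                length += 1
                rr, cc = rr + dr, cc + dc
            counts[window[r, c] - 1, length - 1] += 1
    return counts


def glrlm_features(window: np.ndarray, direction: tuple[int, int], ng: int) -> dict[str, float]:
    counts = glrlm_counts(window, direction, ng)
    return _rlm_style_features("glrlm", counts, window.size, _GLRLM_NAMES)


def _zones(window: np.ndarray):
    """8-connected equal-level zones: list of (level, size, distance)."""
    nr, nc = window.shape
    rows = (np.arange(nr)[:, None] + 1) * np.ones((1, nc), dtype=int)
    cols = (np.arange(nc)[None, :] + 1) * np.ones((nr, 1), dtype=int)
    border = np.minimum(np.minimum(rows, nr - rows + 1), np.minimum(cols, nc - cols + 1))
    lab = _sklabel(window, connectivity=2)  # same-value 8-connected zones
    nlab = lab.max()
    flat_lab = lab.ravel() - 1
    sizes = np.bincount(flat_lab, minlength=nlab)
    levels = np.zeros(nlab, dtype=int)
    levels[flat_lab] = window.ravel()
    dists = np.full(nlab, np.iinfo(np.int64).max)
    np.minimum.at(dists, flat_lab, border.ravel())
    return [(int(levels[z]), int(sizes[z]), int(dists[z])) for z in range(nlab)]


def glszm_features(window: np.ndarray, ng: int, zones=None) -> dict[str, float]:
    zones = _zones(window) if zones is None else zones
    counts = np.zeros((ng, window.size))
    for level, size, _dist in zones:
        counts[level - 1, size - 1] += 1
    return _rlm_style_features("glszm", counts, window.size, _GLSZM_NAMES)


def gldzm_features(window: np.ndarray, ng: int, zones=None) -> dict[str, float]:
    zones = _zones(window) if zones is None else zones
    max_dist = (min(window.shape) + 1) // 2
    counts = np.zeros((ng, max_dist))
    for level, _size, dist in zones:
        counts[level - 1, dist - 1] += 1
    return _rlm_style_features("gldzm", counts, window.size, _GLDZM_NAMES)


# ---------------------------------------------------------------------------
# NGTDM / NGLDM


def _neighbor_sums(window: np.ndarray):
    """Sum and count of 8-neighborhood values for every voxel (partial at edges)."""
    w = np.asarray(window, dtype=float)
    total = ndimage.correlate(w, _EIGHT_CONN.astype(float), mode="constant", cval=0.0)
    ones = np.ones_like(w)
    cnt = ndimage.correlate(ones, _EIGHT_CONN.astype(float), mode="constant", cval=0.0)
    return total - w, cnt - 1.0


def ngtdm_features(window: np.ndarray, ng: int) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    nsum, ncnt = _neighbor_sums(window)
    nbar = nsum / ncnt
    nv = window.size
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    for level in range(1, ng + 1):
        sel = window == level
        if sel.any():
            n_i[level - 1] = sel.sum()
            s[level - 1] = np.abs(level - nbar[sel]).sum()
    p = n_i / nv
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=float)

    denom_coarse = float((p * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    ip = i[present]
    pp = p[present]
    sp = s[present]
    if ngp > 1:
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float(
            (pp[:, None] * pp[None, :] * dij2).sum() / (ngp * (ngp - 1)) * (sp.sum() / nv)
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = float((pp * sp).sum() / busy_den) if busy_den > 0 else 0.0
        comp = np.abs(ip[:, None] - ip[None, :]) * (
            (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :])
        )
        complexity = float(comp.sum() / nv)
        strength_num = float(((pp[:, None] + pp[None, :]) * dij2).sum())
        strength = strength_num / sp.sum() if sp.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": float(strength),
    }


def ngldm_counts(window: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence-count matrix s(i, j): level i, j = (#equal neighbors) + 1."""
    nr, nc = window.shape
    max_dep = 9  # 8 neighbors + 1
    counts = np.zeros((ng, max_dep))
    for r in range(nr):
        for c in range(nc):
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        if abs(int(window[rr, cc]) - int(window[r, c])) <= alpha:
                            dep += 1
            counts[window[r, c] - 1, dep] += 1
    return counts


def ngldm_features(window: np.ndarray, ng: int) -> dict[str, float]:
    """17 neighboring gray-level dependence features."""
    counts = ngldm_counts(window, ng)
    ns = counts.sum()
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    si = counts.sum(axis=1)
    sj = counts.sum(axis=0)
    p = counts / ns
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    return {
        "ngldm_low_dependence_emphasis": float((counts / j**2).sum() / ns),
        "ngldm_high_dependence_emphasis": float((counts * j**2).sum() / ns),
        "ngldm_low_grey_level_count_emphasis": float((counts / i**2).sum() / ns),
        "ngldm_high_grey_level_count_emphasis": float((counts * i**2).sum() / ns),
        "ngldm_low_dependence_low_grey_level_emphasis": float(
            (counts / (i**2 * j**2)).sum() / ns
        ),
        "ngldm_low_dependence_high_grey_level_emphasis": float(
            (counts * i**2 / j**2).sum() / ns
        ),
        "ngldm_high_dependence_low_grey_level_emphasis": float(
            (counts * j**2 / i**2).sum() / ns
        ),
        "ngldm_high_dependence_high_grey_level_emphasis": float(
            (counts * i**2 * j**2).sum() / ns
        ),
        "ngldm_grey_level_nonuniformity": float((si**2).sum() / ns),
        "ngldm_grey_level_nonuniformity_normalized": float((si**2).sum() / ns**2),
        "ngldm_dependence_count_nonuniformity": float((sj**2).sum() / ns),
        "ngldm_dependence_count_nonuniformity_normalized": float((sj**2).sum() / ns**2),
        "ngldm_dependence_count_percentage": float(ns / window.size),
        "ngldm_grey_level_variance": float((((i - mu_i) ** 2) * p).sum()),
        "ngldm_dependence_count_variance": float((((j - mu_j) ** 2) * p).sum()),
        "ngldm_dependence_count_entropy": _entropy(p.ravel()),
        "ngldm_dependence_count_energy": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# whole-window driver


def texture_matrices(window: np.ndarray, ng: int) -> dict[str, object]:
    """All texture matrices of one quantized window (for inspection/tests)."""
    return {
        "glcm": [glcm_matrix(window, d, ng) for d in DIRECTIONS],  # dense, for audit
        "glrlm": [glrlm_counts(window, d, ng) for d in DIRECTIONS],
        "glszm": _zones(window),
        "ngldm": ngldm_counts(window, ng),
    }


def window_features(
    quant_window: np.ndarray,
    raw_window: np.ndarray | None,
    ng: int,
    categories: tuple[str, ...] = ("ih", "ibs", "glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm"),
) -> dict[str, float]:
    """All requested feature families for one window.

    GLCM/GLRLM use the by-direction-then-average (BTW3) aggregation; the
    remaining matrix families are computed once per window (8QNN); intensity
    families come straight from the window values (DHQ4).
    """
    quant_window = np.asarray(quant_window)
    out: dict[str, float] = {}
    if "ih" in categories:
        out.update(ih_features(quant_window, ng))
    if "ibs" in categories:
        if raw_window is None:
            raise ValueError("intensity-based features need the unquantized window")
        out.update(ibs_features(raw_window))
    if "glcm" in categories:
        lv, inv = np.unique(quant_window, return_inverse=True)
        idx_win = inv.reshape(quant_window.shape)
        per_dir = [
            glcm_features(lv.astype(np.int64), _glcm_prob(idx_win, lv.size, d), ng)
            for d in DIRECTIONS
        ]
        for key in per_dir[0]:
            out[key] = float(np.mean([d[key] for d in per_dir]))
    if "glrlm" in categories:
        per_dir = [glrlm_features(quant_window, d, ng) for d in DIRECTIONS]
        for key in per_dir[0]:
            out[key] = float(np.mean([d[key] for d in per_dir]))
    zones = _zones(quant_window) if ("glszm" in categories or "gldzm" in categories) else None
    if "glszm" in categories:
        out.update(glszm_features(quant_window, ng, zones))
    if "gldzm" in categories:
        out.update(gldzm_features(quant_window, ng, zones))
    if "ngtdm" in categories:
        out.update(ngtdm_features(quant_window, ng))
    if "ngldm" in categories:
        out.update(ngldm_features(quant_window, ng))
    return out
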