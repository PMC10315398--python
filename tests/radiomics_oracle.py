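"""Straight-from-definition brute-force radiomics oracle.

Every feature is computed here by literal translation of its definition —
plain Python loops, dict-based matrices, breadth-first flood fill for zones —
with no code shared with the package implementation.  Conventions (percentile
interpolation, tie-breaks, degenerate fallbacks) follow the package's
documented contracts.
"""

from __future__ import annotations

import math
from collections import defaultdict

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def _log2(x: float) -> float:
    return math.log(x) / math.log(2.0)


def _percentile(sorted_vals: list[float], q: float) -> float:
    # linear interpolation between closest ranks
    n = len(sorted_vals)
    rank = q / 100.0 * (n - 1)
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def _stats_block(values: list[float]) -> dict[str, float]:
    n = len(values)
    s = sorted(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(var)
    skew = sum(((v - mean) / sd) ** 3 for v in values) / n if sd > 0 else 0.0
    kurt = sum(((v - mean) / sd) ** 4 for v in values) / n - 3.0 if sd > 0 else 0.0
    p10 = _percentile(s, 10)
    p25 = _percentile(s, 25)
    p50 = _percentile(s, 50)
    p75 = _percentile(s, 75)
    p90 = _percentile(s, 90)
    robust = [v for v in values if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": p50,
        "minimum": min(values),
        "p10": p10,
        "p90": p90,
        "maximum": max(values),
        "interquartile_range": p75 - p25,
        "range": max(values) - min(values),
        "mean_absolute_deviation": sum(abs(v - mean) for v in values) / n,
        "robust_mean_absolute_deviation": (
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0
        ),
        "median_absolute_deviation": sum(abs(v - p50) for v in values) / n,
        "coefficient_of_variation": sd / mean if mean != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (
            (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
        ),
    }


def oracle_ih(window: list[list[int]], ng: int) -> dict[str, float]:
    values = [float(v) for row in window for v in row]
    out = {f"ih_{k}": v for k, v in _stats_block(values).items()}
    counts = [0] * (ng + 1)
    for row in window:
        for v in row:
            counts[v] += 1
    n = len(values)
    probs = [c / n for c in counts[1:]]
    best = max(counts[1:])
    out["ih_mode"] = float(next(i for i in range(1, ng + 1) if counts[i] == best))
    out["ih_entropy"] = -sum(p * _log2(p) for p in probs if p > 0)
    out["ih_uniformity"] = sum(p * p for p in probs)
    hist = counts[1:]
    grads = []
    for i in range(ng):
        if i == 0:
            grads.append(hist[1] - hist[0])
        elif i == ng - 1:
            grads.append(hist[ng - 1] - hist[ng - 2])
        else:
            grads.append((hist[i + 1] - hist[i - 1]) / 2.0)
    out["ih_max_gradient"] = float(max(grads))
    out["ih_min_gradient"] = float(min(grads))
    return out


def oracle_ibs(raw: list[list[float]]) -> dict[str, float]:
    values = [float(v) for row in raw for v in row]
    out = {f"ibs_{k}": v for k, v in _stats_block(values).items()}
    out["ibs_energy"] = sum(v * v for v in values)
    return out


def _glcm_probs(window, direction):
    dr, dc = direction
    nr, nc = len(window), len(window[0])
    counts: dict[tuple[int, int], float] = defaultdict(float)
    for r in range(nr):
        for c in range(nc):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                counts[(window[r][c], window[rr][cc])] += 1.0
                counts[(window[rr][cc], window[r][c])] += 1.0  # symmetric
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def oracle_glcm_direction(window, direction, ng: int) -> dict[str, float]:
    p = _glcm_probs(window, direction)
    px: dict[int, float] = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * v for i, v in px.items())
    sigma2 = sum((i - mu) ** 2 * v for i, v in px.items())
    joint_avg = sum(i * v for (i, j), v in p.items())

    p_diff: dict[int, float] = defaultdict(float)
    p_sum: dict[int, float] = defaultdict(float)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j] += v
    da = sum(k * v for k, v in p_diff.items())
    sa = sum(k * v for k, v in p_sum.items())

    hxy = -sum(v * _log2(v) for v in p.values() if v > 0)
    hx = -sum(v * _log2(v) for v in px.values() if v > 0)
    hxy1 = -sum(
        v * _log2(px[i] * px[j]) for (i, j), v in p.items() if px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j])
        for i in px
        for j in px
        if px[i] * px[j] > 0
    )

    corr = (
        (sum(i * j * v for (i, j), v in p.items()) - mu * mu) / sigma2
        if sigma2 > 0
        else 1.0
    )
    ic2_arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
    return {
        "glcm_joint_maximum": max(p.values()),
        "glcm_joint_average": joint_avg,
        "glcm_joint_variance": sum((i - joint_avg) ** 2 * v for (i, j), v in p.items()),
        "glcm_joint_entropy": hxy,
        "glcm_difference_average": da,
        "glcm_difference_variance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "glcm_difference_entropy": -sum(v * _log2(v) for v in p_diff.values() if v > 0),
        "glcm_sum_average": sa,
        "glcm_sum_variance": sum((k - sa) ** 2 * v for k, v in p_sum.items()),
        "glcm_sum_entropy": -sum(v * _log2(v) for v in p_sum.values() if v > 0),
        "glcm_angular_second_moment": sum(v * v for v in p.values()),
        "glcm_contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "glcm_dissimilarity": sum(abs(i - j) * v for (i, j), v in p.items()),
        "glcm_inverse_difference": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "glcm_inverse_difference_normalized": sum(
            v / (1 + abs(i - j) / ng) for (i, j), v in p.items()
        ),
        "glcm_inverse_difference_moment": sum(
            v / (1 + (i - j) ** 2) for (i, j), v in p.items()
        ),
        "glcm_inverse_difference_moment_normalized": sum(
            v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()
        ),
        "glcm_inverse_variance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "glcm_correlation": corr,
        "glcm_autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "glcm_cluster_tendency": sum((i + j - 2 * mu) ** 2 * v for (i, j), v in p.items()),
        "glcm_cluster_shade": sum((i + j - 2 * mu) ** 3 * v for (i, j), v in p.items()),
        "glcm_cluster_prominence": sum(
            (i + j - 2 * mu) ** 4 * v for (i, j), v in p.items()
        ),
        "glcm_information_correlation_1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_information_correlation_2": math.sqrt(max(0.0, ic2_arg)),
    }


def _rlm_template(prefix, entries, n_voxels, size_names):
    """entries: list of (level, size, count); the shared 16-feature template."""
    ns = sum(cnt for _l, _s, cnt in entries)
    ri: dict[int, float] = defaultdict(float)
    rj: dict[int, float] = defaultdict(float)
    for lvl, size, cnt in entries:
        ri[lvl] += cnt
        rj[size] += cnt
    mu_i = sum(lvl * cnt for lvl, _s, cnt in entries) / ns
    mu_j = sum(size * cnt for _l, size, cnt in entries) / ns
    small, large, nu, nun, var, ent = size_names
    probs = [cnt / ns for _l, _s, cnt in entries]
    return {
        f"{prefix}_{small}": sum(cnt / s**2 for _l, s, cnt in entries) / ns,
        f"{prefix}_{large}": sum(cnt * s**2 for _l, s, cnt in entries) / ns,
        f"{prefix}_low_grey_level_emphasis": sum(cnt / l**2 for l, _s, cnt in entries) / ns,
        f"{prefix}_high_grey_level_emphasis": sum(cnt * l**2 for l, _s, cnt in entries) / ns,
        f"{prefix}_{small}_low_grey_level": sum(
            cnt / (l**2 * s**2) for l, s, cnt in entries
        )
        / ns,
        f"{prefix}_{small}_high_grey_level": sum(
            cnt * l**2 / s**2 for l, s, cnt in entries
        )
        / ns,
        f"{prefix}_{large}_low_grey_level": sum(
            cnt * s**2 / l**2 for l, s, cnt in entries
        )
        / ns,
        f"{prefix}_{large}_high_grey_level": sum(
            cnt * l**2 * s**2 for l, s, cnt in entries
        )
        / ns,
        f"{prefix}_grey_level_nonuniformity": sum(v**2 for v in ri.values()) / ns,
        f"{prefix}_grey_level_nonuniformity_normalized": sum(v**2 for v in ri.values())
        / ns**2,
        f"{prefix}_{nu}": sum(v**2 for v in rj.values()) / ns,
        f"{prefix}_{nun}": sum(v**2 for v in rj.values()) / ns**2,
        f"{prefix}_percentage": ns / n_voxels,
        f"{prefix}_grey_level_variance": sum(
            (l - mu_i) ** 2 * cnt / ns for l, _s, cnt in entries
        ),
        f"{prefix}_{var}": sum((s - mu_j) ** 2 * cnt / ns for _l, s, cnt in entries),
        f"{prefix}_{ent}": -sum(v * _log2(v) for v in probs if v > 0),
    }


def _runs(window, direction):
    dr, dc = direction
    nr, nc = len(window), len(window[0])
    runs: dict[tuple[int, int], float] = defaultdict(float)
    for r in range(nr):
        for c in range(nc):
            pr, pc = r - dr, c - dc
            if 0 <= pr < nr and 0 <= pc < nc and window[pr][pc] == window[r][c]:
                continue
            length = 1
            rr, cc = r + dr, c + dc
            while 0 <= rr < nr and 0 <= cc < nc and window[rr][cc] == window[r][c]:
                length += 1
                rr, cc = rr + dr, cc + dc
            runs[(window[r][c], length)] += 1
    return [(lvl, length, cnt) for (lvl, length), cnt in runs.items()]


GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_length_variance",
    "run_entropy",
)
GLSZM_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "zone_size_nonuniformity",
    "zone_size_nonuniformity_normalized",
    "zone_size_variance",
    "zone_size_entropy",
)
GLDZM_NAMES = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "zone_distance_nonuniformity",
    "zone_distance_nonuniformity_normalized",
    "zone_distance_variance",
    "zone_distance_entropy",
)


def _flood_zones(window):
    """8-connected equal-level zones via breadth-first flood fill."""
    nr, nc = len(window), len(window[0])
    seen = [[False] * nc for _ in range(nr)]
    zones = []
    for r in range(nr):
        for c in range(nc):
            if seen[r][c]:
                continue
            level = window[r][c]
            queue = [(r, c)]
            seen[r][c] = True
            members = []
            while queue:
                cr, cc = queue.pop()
                members.append((cr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc2 = cr + dr, cc + dc
                        if (
                            0 <= rr < nr
                            and 0 <= cc2 < nc
                            and not seen[rr][cc2]
                            and window[rr][cc2] == level
                        ):
                            seen[rr][cc2] = True
                            queue.append((rr, cc2))
            dist = min(
                min(rr + 1, nr - rr, cc2 + 1, nc - cc2) for rr, cc2 in members
            )
            zones.append((level, len(members), dist))
    return zones


def oracle_glszm(window) -> dict[str, float]:
    zones = _flood_zones(window)
    agg: dict[tuple[int, int], float] = defaultdict(float)
    for level, size, _d in zones:
        agg[(level, size)] += 1
    entries = [(l, s, cnt) for (l, s), cnt in agg.items()]
    nv = len(window) * len(window[0])
    return _rlm_template("glszm", entries, nv, GLSZM_NAMES)


def oracle_gldzm(window) -> dict[str, float]:
    zones = _flood_zones(window)
    agg: dict[tuple[int, int], float] = defaultdict(float)
    for level, _s, dist in zones:
        agg[(level, dist)] += 1
    entries = [(l, d, cnt) for (l, d), cnt in agg.items()]
    nv = len(window) * len(window[0])
    return _rlm_template("gldzm", entries, nv, GLDZM_NAMES)


def oracle_ngtdm(window, ng: int) -> dict[str, float]:
    nr, nc = len(window), len(window[0])
    nv = nr * nc
    s: dict[int, float] = defaultdict(float)
    n_i: dict[int, float] = defaultdict(float)
    for r in range(nr):
        for c in range(nc):
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        neigh.append(window[rr][cc])
            nbar = sum(neigh) / len(neigh)
            lvl = window[r][c]
            n_i[lvl] += 1
            s[lvl] += abs(lvl - nbar)
    p = {lvl: n / nv for lvl, n in n_i.items()}
    present = sorted(p)
    ngp = len(present)
    denom = sum(p[i] * s[i] for i in present)
    coarseness = min(1.0 / denom, 1e6) if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * sum(s[i] for i in present)
            / nv
        )
        busy_den = sum(
            abs(i * p[i] - j * p[j]) for i in present for j in present
        )
        busyness = sum(p[i] * s[i] for i in present) / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / nv
        )
        s_total = sum(s[i] for i in present)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def oracle_ngldm(window) -> dict[str, float]:
    nr, nc = len(window), len(window[0])
    nv = nr * nc
    counts: dict[tuple[int, int], float] = defaultdict(float)
    for r in range(nr):
        for c in range(nc):
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and window[rr][cc] == window[r][c]:
                        dep += 1
            counts[(window[r][c], dep + 1)] += 1  # dependence j = count + 1
    ns = sum(counts.values())
    si: dict[int, float] = defaultdict(float)
    sj: dict[int, float] = defaultdict(float)
    for (i, j), v in counts.items():
        si[i] += v
        sj[j] += v
    mu_i = sum(i * v for (i, j), v in counts.items()) / ns
    mu_j = sum(j * v for (i, j), v in counts.items()) / ns
    probs = [v / ns for v in counts.values()]
    return {
        "ngldm_low_dependence_emphasis": sum(v / j**2 for (i, j), v in counts.items()) / ns,
        "ngldm_high_dependence_emphasis": sum(v * j**2 for (i, j), v in counts.items()) / ns,
        "ngldm_low_grey_level_count_emphasis": sum(
            v / i**2 for (i, j), v in counts.items()
        )
        / ns,
        "ngldm_high_grey_level_count_emphasis": sum(
            v * i**2 for (i, j), v in counts.items()
        )
        / ns,
        "ngldm_low_dependence_low_grey_level_emphasis": sum(
            v / (i**2 * j**2) for (i, j), v in counts.items()
        )
        / ns,
        "ngldm_low_dependence_high_grey_level_emphasis": sum(
            v * i**2 / j**2 for (i, j), v in counts.items()
        )
        / ns,
        "ngldm_high_dependence_low_grey_level_emphasis": sum(
            v * j**2 / i**2 for (i, j), v in counts.items()
        )
        / ns,
        "ngldm_high_dependence_high_grey_level_emphasis": sum(
            v * i**2 * j**2 for (i, j), v in counts.items()
        )
        / ns,
        "ngldm_grey_level_nonuniformity": sum(v**2 for v in si.values()) / ns,
        "ngldm_grey_level_nonuniformity_normalized": sum(v**2 for v in si.values())
        / ns**2,
        "ngldm_dependence_count_nonuniformity": sum(v**2 for v in sj.values()) / ns,
        "ngldm_dependence_count_nonuniformity_normalized": sum(
            v**2 for v in sj.values()
        )
        / ns**2,
        "ngldm_dependence_count_percentage": ns / nv,
        "ngldm_grey_level_variance": sum(
            (i - mu_i) ** 2 * v / ns for (i, j), v in counts.items()
        ),
        "ngldm_dependence_count_variance": sum(
            (j - mu_j) ** 2 * v / ns for (i, j), v in counts.items()
        ),
        "ngldm_dependence_count_entropy": -sum(v * _log2(v) for v in probs if v > 0),
        "ngldm_dependence_count_energy": sum(v**2 for v in probs),
    }


def oracle_all_features(window, raw, ng: int) -> dict[str, float]:
    """All 133 features of one window, aggregated as the pipeline does."""
    win = [[int(v) for v in row] for row in window]
    out = {}
    out.update(oracle_ih(win, ng))
    out.update(oracle_ibs([[float(v) for v in row] for row in raw]))
    per_dir = [oracle_glcm_direction(win, d, ng) for d in DIRECTIONS]
    for key in per_dir[0]:
        out[key] = sum(d[key] for d in per_dir) / len(per_dir)
    rl_dirs = [
        _rlm_template("glrlm", _runs(win, d), len(win) * len(win[0]), GLRLM_NAMES)
        for d in DIRECTIONS
    ]
    for key in rl_dirs[0]:
        out[key] = sum(d[key] for d in rl_dirs) / len(rl_dirs)
    out.update(oracle_glszm(win))
    out.update(oracle_gldzm(win))
    out.update(oracle_ngtdm(win, ng))
    out.update(oracle_ngldm(win))
    return out
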