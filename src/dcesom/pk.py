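"""Nested-model pharmacokinetic fitting and parsimony-based model selection.

Each voxel's DeltaR1 trace is fitted by three nested observation models
(intact barrier; leakage without backflux; leakage with backflux; see
:mod:`dcesom.forward`) and the most parsimonious model that significantly
improves the fit is selected by sequential F-tests.  Models 1 and 2 are
linear in their parameters and are solved exactly by least squares; model 3
is nonlinear only in kep, which is handled either by a downhill-simplex
search (single-curve API) or by a variable-projection kep grid with local
refinement (whole-map API).  The two routes minimize the same residual sum
of squares.

The F-tests use unconstrained least-squares residuals, which is what makes
the classical F(1, N-k) null distribution exact; non-negativity of the
reported parameter maps is enforced at export, not inside the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .forward import SEC_PER_MIN, cumtrapz_grid, exp_convolution, exp_convolution_matrix

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when the reference region carries no enhancement to normalize to."""


REFERENCE_VP = 0.01  # caudate putamen plasma volume fraction, by assumption


@dataclass
class NormalizedAIF:
    """Plasma input trace scaled so the reference region fits vp = 0.01."""

    cp: np.ndarray  # 1/s, on the acquisition grid
    scale: float
    reference_vp: float = REFERENCE_VP


@dataclass
class SingleModelFit:
    model_id: int
    vp: float
    ktrans: float  # 1/min
    kep: float  # 1/min
    rss: float
    n_params: int
    converged: bool

    @property
    def ve(self) -> float:
        return self.ktrans / self.kep if self.kep > 0 else 0.0


@dataclass
class PKFitResult:
    """All three nested fits for one curve plus the selected model id."""

    fits: dict[int, SingleModelFit]
    selected_model: int | None

    @property
    def selected(self) -> SingleModelFit | None:
        return None if self.selected_model is None else self.fits[self.selected_model]


@dataclass
class ModelChoiceMap:
    """Voxelwise selected-model labels and selected-model parameter maps."""

    labels: np.ndarray  # {0 excluded, 1, 2, 3}
    vp: np.ndarray
    ktrans: np.ndarray  # 1/min
    kep: np.ndarray  # 1/min
    ve: np.ndarray
    rss: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# AIF normalization


def _model1_vp(curve: np.ndarray, cp: np.ndarray, hct: float) -> float:
    # model-1 fit with a baseline nuisance offset: slope of curve on Cp/(1-Hct)
    x = cp / (1.0 - hct)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise NormalizationError("plasma trace is identically zero")
    return float(curve @ xc) / denom


def normalize_aif(
    raw_trace: np.ndarray,
    reference_curves: np.ndarray,
    hct: float,
    min_reference_voxels: int = 10,
) -> NormalizedAIF:
    """Scale a raw arterial trace against the reference-region mean curve.

    The scale is chosen in closed form (the model-1 fit is linear in Cp) so
    that fitting model 1 to the reference mean curve returns vp = 0.01.
    """
    raw = np.asarray(raw_trace, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw AIF trace must be non-negative")
    curves = np.atleast_2d(np.asarray(reference_curves, dtype=float))
    if curves.shape[0] < min_reference_voxels:
        raise NormalizationError(
            f"reference region must contain >= {min_reference_voxels} valid voxels"
        )
    mean_curve = curves.mean(axis=0)
    vp_raw = _model1_vp(mean_curve, raw, hct)
    if vp_raw <= 1e-12:
        raise NormalizationError("reference region shows no enhancement")
    scale = vp_raw / REFERENCE_VP
    return NormalizedAIF(cp=scale * raw, scale=scale)


# ---------------------------------------------------------------------------
# Single-curve fitting


def _design_vectors(cp: np.ndarray, times: np.ndarray, hct: float):
    scale = 1.0 / (1.0 - hct)
    x1 = scale * cp
    x2 = scale * cumtrapz_grid(cp, times)
    return x1, x2


def _offset_cols(fit_offset: bool, n: int) -> list:
    return [np.ones(n)] if fit_offset else []


def _lstsq_rss(y: np.ndarray, cols: list[np.ndarray]):
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def fit_model(
    curve: np.ndarray,
    cp: np.ndarray,
    hct: float,
    model_id: int,
    times: np.ndarray,
    kep_starts: tuple[float, ...] = (0.05, 0.2, 0.6),
    seed: int = 0,
    maxiter: int = 400,
    fit_offset: bool = True,
) -> SingleModelFit:
    """Fit one nested observation model to a single DeltaR1 curve.

    A per-voxel baseline nuisance offset is estimated alongside the kinetic
    parameters by default (``fit_offset``); it absorbs the correlated
    baseline error the log-domain DeltaR1 estimator leaves in noisy data.
    Models 1-2 are linear and solved exactly by least squares.  Model 3 runs
    a downhill simplex over (vp, Ktrans, sqrt(kep)) — the offset profiled
    analytically — from the model-2 solution plus seeded jittered restarts
    at several kep starting points (1/min), keeping the best RSS.
    """
    curve = np.asarray(curve, dtype=float)
    cp = np.asarray(cp, dtype=float)
    times = np.asarray(times, dtype=float)
    if curve.shape != cp.shape or cp.shape != times.shape:
        raise ValueError("curve, cp, and times must share a grid")
    x1, x2 = _design_vectors(cp, times, hct)
    extra = _offset_cols(fit_offset, times.size)

    if model_id == 1:
        beta, rss = _lstsq_rss(curve, [x1] + extra)
        return SingleModelFit(1, float(beta[0]), 0.0, 0.0, rss, 1, True)
    if model_id == 2:
        beta, rss = _lstsq_rss(curve, [x1, x2] + extra)
        return SingleModelFit(
            2, float(beta[0]), float(beta[1]) * SEC_PER_MIN, 0.0, rss, 2, True
        )
    if model_id != 3:
        raise ValueError("model_id must be in {1, 2, 3}")

    scale = 1.0 / (1.0 - hct)

    def objective(params: np.ndarray) -> float:
        vp, kt_s, z = params
        kep_s = z * z
        conv = exp_convolution(cp, times, kep_s)
        resid = curve - scale * (vp * cp + kt_s * conv)
        if fit_offset:
            resid = resid - resid.mean()
        return float(resid @ resid)

    beta2, rss2 = _lstsq_rss(curve, [x1, x2] + extra)
    rng = np.random.default_rng(seed)
    best = None
    for i, kep0 in enumerate(kep_starts):
        x0 = np.array(
            [beta2[0], beta2[1], np.sqrt(kep0 / SEC_PER_MIN)], dtype=float
        )
        if i > 0:  # jittered restarts; the first start is the nested init
            x0[:2] *= 1.0 + 0.05 * rng.standard_normal(2)
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-14, "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
    vp, kt_s, z = best.x
    rss3 = float(best.fun)
    converged = bool(best.success) or rss3 <= rss2 + 1e-12
    if rss3 > rss2:  # kep boundary: model 2 is the better nested solution
        vp, kt_s, z, rss3 = float(beta2[0]), float(beta2[1]), 0.0, rss2
    return SingleModelFit(
        3, float(vp), float(kt_s) * SEC_PER_MIN, float(z * z) * SEC_PER_MIN, rss3, 3, converged
    )


def fit_all_models(curve, cp, hct, times, **kwargs) -> dict[int, SingleModelFit]:
    return {m: fit_model(curve, cp, hct, m, times, **kwargs) for m in (1, 2, 3)}


# ---------------------------------------------------------------------------
# Selection


#: RSS improvements below this fraction of the curve energy are treated as
#: exact ties — they are floating-point residue, not evidence for a model.
RSS_REL_FLOOR = 1e-12


def f_test_statistic(
    rss_simple: float,
    rss_complex: float,
    df_complex: int,
    energy: float = 0.0,
    df_num: int = 1,
) -> float:
    """F = [(RSS_s - RSS_c)/df_num] / [RSS_c / df_c] for nested LS fits.

    ``energy`` (sum of squared curve values) sets the numerical tie floor; a
    perfect complex fit of a genuinely imperfect simple fit returns inf.
    """
    gain = rss_simple - rss_complex
    if gain <= RSS_REL_FLOOR * energy:
        return 0.0
    if rss_complex == 0.0:
        return np.inf
    return (gain / df_num) / (rss_complex / df_complex)


def select_model(
    fits: dict[int, SingleModelFit],
    n_timepoints: int,
    alpha: float = 0.05,
    energy: float = 0.0,
    n_nuisance: int = 1,
) -> int | None:
    """Sequential parsimony selection: advance only on a significant F-test.

    ``n_nuisance`` counts non-kinetic parameters shared by all models (the
    baseline offset by default) so the residual degrees of freedom are right.
    """
    if n_timepoints <= 3 + n_nuisance:
        raise ValueError("too few timepoints for selection")
    if not all(fits[m].converged for m in (1, 2, 3)):
        return None
    # Gate on the full model: a 2-df F of model 3 against model 1.  A strict
    # 1-vs-2 gate is blind to washout voxels, whose rise-and-fall curves the
    # monotone model-2 term cannot approximate at all (RSS2 ~ RSS1 even when
    # model 3 fits perfectly).
    df13 = n_timepoints - 3 - n_nuisance
    f13 = f_test_statistic(fits[1].rss, fits[3].rss, df13, energy, df_num=2)
    if not (np.isinf(f13) or f13 > stats.f.isf(alpha, 2, df13)):
        return 1
    f23 = f_test_statistic(fits[2].rss, fits[3].rss, df13, energy)
    if not (np.isinf(f23) or f23 > stats.f.isf(alpha, 1, df13)):
        return 2
    return 3


def fit_and_select(curve, cp, hct, times, alpha: float = 0.05, **kwargs) -> PKFitResult:
    fits = fit_all_models(curve, cp, hct, times, **kwargs)
    curve = np.asarray(curve, dtype=float)
    selected = select_model(fits, len(times), alpha, energy=float(curve @ curve))
    return PKFitResult(fits=fits, selected_model=selected)


# ---------------------------------------------------------------------------
# Whole-map fitting (variable projection over a kep grid)

DEFAULT_KEP_GRID = np.geomspace(0.02, 5.0, 60)  # 1/min


def _fit_maps_arrays(
    y: np.ndarray,
    cp: np.ndarray,
    times: np.ndarray,
    hct: float,
    kep_grid: np.ndarray,
    fit_offset: bool = True,
):
    """Exact LS fits of all three models for a stack of curves y (nvox, nt).

    Returns per-model RSS arrays and parameter arrays; model-3 kep comes from
    the grid argmin refined by log-parabolic interpolation plus one exact
    re-solve at the refined kep.  With ``fit_offset`` every model carries a
    baseline nuisance intercept, handled exactly by centering (slopes and RSS
    of the intercept model equal those of the centered regression).
    """
    x1, x2 = _design_vectors(cp, times, hct)
    if fit_offset:
        y = y - y.mean(axis=1, keepdims=True)
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
    yy = np.einsum("ij,ij->i", y, y)

    # model 1
    a11 = float(x1 @ x1)
    u = y @ x1
    vp1 = u / a11
    rss1 = np.maximum(yy - vp1 * u, 0.0)

    # model 2
    g = np.array([[x1 @ x1, x1 @ x2], [x2 @ x1, x2 @ x2]])
    rhs = np.stack([u, y @ x2], axis=1)
    beta2 = rhs @ np.linalg.inv(g).T
    rss2 = np.maximum(yy - np.einsum("ij,ij->i", beta2, rhs), 0.0)

    # model 3: profile over kep
    kep_s = np.asarray(kep_grid, dtype=float) / SEC_PER_MIN
    convs = exp_convolution_matrix(cp, times, kep_s) / (1.0 - hct)  # (nk, nt)
    if fit_offset:
        convs = convs - convs.mean(axis=1, keepdims=True)
    b = convs @ x1  # (nk,)
    d = np.einsum("kj,kj->k", convs, convs)
    w = y @ convs.T  # (nvox, nk)
    det = a11 * d - b * b
    det = np.where(det <= 0, np.inf, det)
    vp_k = (d[None, :] * u[:, None] - b[None, :] * w) / det[None, :]
    kt_k = (a11 * w - b[None, :] * u[:, None]) / det[None, :]
    rss_k = yy[:, None] - (vp_k * u[:, None] + kt_k * w)

    k_best = np.argmin(rss_k, axis=1)
    log_kep = np.log(kep_s)
    kep_ref = kep_s[k_best].copy()
    interior = (k_best > 0) & (k_best < kep_s.size - 1)
    if interior.any():
        i = k_best[interior]
        r0 = rss_k[interior, i - 1]
        r1 = rss_k[interior, i]
        r2 = rss_k[interior, i + 1]
        h = log_kep[1] - log_kep[0]  # geometric grid: uniform in log
        denom = r0 - 2 * r1 + r2
        shift = np.where(denom > 0, 0.5 * h * (r0 - r2) / np.maximum(denom, 1e-300), 0.0)
        shift = np.clip(shift, -h, h)
        kep_ref[interior] = np.exp(log_kep[i] + shift)

    # one exact re-solve at the refined kep per voxel
    nvox = y.shape[0]
    vp3 = np.empty(nvox)
    kt3 = np.empty(nvox)
    rss3 = np.empty(nvox)
    unique_kep, inverse = np.unique(kep_ref, return_inverse=True)
    convs_ref = exp_convolution_matrix(cp, times, unique_kep) / (1.0 - hct)
    if fit_offset:
        convs_ref = convs_ref - convs_ref.mean(axis=1, keepdims=True)
    b_ref = convs_ref @ x1
    d_ref = np.einsum("kj,kj->k", convs_ref, convs_ref)
    for kidx in range(unique_kep.size):
        sel = inverse == kidx
        c = convs_ref[kidx]
        wv = y[sel] @ c
        det1 = a11 * d_ref[kidx] - b_ref[kidx] ** 2
        vp_v = (d_ref[kidx] * u[sel] - b_ref[kidx] * wv) / det1
        kt_v = (a11 * wv - b_ref[kidx] * u[sel]) / det1
        vp3[sel] = vp_v
        kt3[sel] = kt_v
        rss3[sel] = yy[sel] - (vp_v * u[sel] + kt_v * wv)

    # keep whichever of {grid best, refined} is lower, never above model 2
    grid_better = rss_k[np.arange(nvox), k_best] < rss3
    vp3 = np.where(grid_better, vp_k[np.arange(nvox), k_best], vp3)
    kt3 = np.where(grid_better, kt_k[np.arange(nvox), k_best], kt3)
    kep3 = np.where(grid_better, kep_s[k_best], kep_ref)
    rss3 = np.minimum(rss_k[np.arange(nvox), k_best], rss3)

    m2_better = rss2 <= rss3
    vp3 = np.where(m2_better, beta2[:, 0], vp3)
    kt3 = np.where(m2_better, beta2[:, 1], kt3)
    kep3 = np.where(m2_better, 0.0, kep3)
    rss3 = np.minimum(rss3, rss2)
    rss3 = np.maximum(rss3, 0.0)

    return {
        1: dict(vp=vp1, ktrans=np.zeros_like(vp1), kep=np.zeros_like(vp1), rss=rss1),
        2: dict(vp=beta2[:, 0], ktrans=beta2[:, 1] * SEC_PER_MIN, kep=np.zeros_like(vp1), rss=rss2),
        3: dict(vp=vp3, ktrans=kt3 * SEC_PER_MIN, kep=kep3 * SEC_PER_MIN, rss=rss3),
    }


def map_pipeline(
    delta_r1: np.ndarray,
    cp: np.ndarray,
    mask: np.ndarray,
    times: np.ndarray,
    hct: float,
    alpha: float = 0.05,
    kep_grid: np.ndarray = DEFAULT_KEP_GRID,
    fit_offset: bool = True,
) -> ModelChoiceMap:
    """Per-voxel nested fits + selection over a masked DeltaR1 volume-series.

    Emits a label map {0 excluded, 1, 2, 3} and vp/Ktrans/kep/ve maps holding
    the selected model's parameters (clamped at 0 for reporting).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if delta_r1.shape[:-1] != mask.shape or delta_r1.shape[-1] != times.size:
        raise ValueError("inputs must be aligned on one grid")
    y = delta_r1[mask, :]
    n = times.size
    offs = 1 if fit_offset else 0

    fits = _fit_maps_arrays(y, cp, times, hct, np.asarray(kep_grid, dtype=float), fit_offset)
    rss1, rss2, rss3 = fits[1]["rss"], fits[2]["rss"], fits[3]["rss"]

    df = n - 3 - offs
    crit13 = stats.f.isf(alpha, 2, df)
    crit23 = stats.f.isf(alpha, 1, df)
    yy = np.einsum("ij,ij->i", y, y)
    floor = RSS_REL_FLOOR * yy
    with np.errstate(divide="ignore", invalid="ignore"):
        f13 = np.where(rss3 > 0, (rss1 - rss3) / 2 * df / rss3, np.inf)
        f23 = np.where(rss3 > 0, (rss2 - rss3) * df / rss3, np.inf)
        f13 = np.where(rss1 - rss3 <= floor, 0.0, f13)
        f23 = np.where(rss2 - rss3 <= floor, 0.0, f23)
    labels_flat = np.where(f13 > crit13, np.where(f23 > crit23, 3, 2), 1).astype(np.int8)

    def select(key):
        out = np.zeros(y.shape[0])
        for m in (1, 2, 3):
            sel = labels_flat == m
            out[sel] = fits[m][key][sel]
        return out

    vp = np.clip(select("vp"), 0.0, None)
    ktrans = np.clip(select("ktrans"), 0.0, None)
    kep = np.clip(select("kep"), 0.0, None)
    ve = np.where(kep > 0, ktrans / np.where(kep > 0, kep, 1.0), 0.0)

    def to_map(flat, dtype=float):
        out = np.zeros(mask.shape, dtype=dtype)
        out[mask] = flat
        return out

    return ModelChoiceMap(
        labels=to_map(labels_flat, dtype=np.int8),
        vp=to_map(vp),
        ktrans=to_map(ktrans),
        kep=to_map(kep),
        ve=to_map(ve),
        rss={m: to_map(fits[m]["rss"]) for m in (1, 2, 3)},
    )
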