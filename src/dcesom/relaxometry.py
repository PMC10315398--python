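"""Per-voxel flip-angle and DeltaR1(t) estimation from dual-echo series.

The estimator exploits the dual-echo structure: with mu = TE2/TE1, the
combination F^(mu/(mu-1)) / S^(1/(mu-1)) of the two echo intensities cancels
the T2* decay exactly and isolates the T1-weighted steady-state amplitude
A(T1) = M0 sin(theta) (1-E)/(1 - cos(theta) E), E = exp(-TR/T1).  Window sums
over a pre-injection baseline (m..n) and a late saturated window (o..p, same
length) give the amplitude ratio

    Q = [(sum S_pre)^(1/(mu-1)) / (sum F_pre)^(mu/(mu-1))]
        * [(sum F_sat)^(mu/(mu-1)) / (sum S_sat)^(1/(mu-1))]  = A_sat / A_pre

which, together with E_pre and E_post from the pre-/post-study T1 maps,
determines the actual per-voxel flip angle by exact inversion of the
steady-state equation:

    cos(theta) = [(1 - E_post) - Q (1 - E_pre)]
                 / [E_pre (1 - E_post) - Q E_post (1 - E_pre)]

DeltaR1(t) then follows from the per-timepoint amplitude ratio
rho(t) = A(t)/A_pre (same window-sum/power structure, carrying the
(n - m + 1) factor), inverted for E(t):

    E(t) = [(1 - c E_pre) - rho (1 - E_pre)]
           / [(1 - c E_pre) - c rho (1 - E_pre)],   c = cos(theta)

    DeltaR1(t) = -(1/TR) ln(E(t)/E_pre)

Note DeltaR1 is fully independent of E_post; only the flip angle uses the
post-study T1 map.  Degenerate voxels (invalid arccos argument, vanishing
denominators, non-positive signals) are flagged and excluded rather than
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dge import DualEchoSeries
from .protocol import BaselineWindows

logger = logging.getLogger(__name__)

_EPS = 1e-300


@dataclass
class RelaxFactors:
    """Per-voxel exp(-TR/T1) for the pre- and post-study T1 maps."""

    epre: np.ndarray
    epost: np.ndarray


@dataclass
class ConcentrationSeries:
    """Estimated DeltaR1(t) (1/s) with its per-voxel flip-angle map.

    ``valid`` marks voxels whose flip angle could be estimated; ``flagged``
    marks individual voxel-timepoints whose DeltaR1 was degenerate (stored as
    0 and excluded downstream).
    """

    delta_r1: np.ndarray  # (x, y, slice, time)
    theta_est: np.ndarray  # degrees, NaN-free inside `valid`
    valid: np.ndarray  # (x, y, slice) bool
    flagged: np.ndarray  # (x, y, slice, time) bool
    windows: BaselineWindows


def e_from_t1(t1_map: np.ndarray, tr: float, mask: np.ndarray | None = None) -> np.ndarray:
    """E = exp(-TR/T1) elementwise; T1 must be positive inside ``mask``."""
    t1_map = np.asarray(t1_map, dtype=float)
    if mask is None:
        mask = np.ones(t1_map.shape, dtype=bool)
    if (t1_map[mask] <= 0).any():
        raise ValueError("non-positive T1 inside mask")
    out = np.zeros_like(t1_map)
    out[mask] = np.exp(-tr / t1_map[mask])
    return out


def window_means(series: DualEchoSeries, windows: BaselineWindows):
    """Per-voxel arithmetic means of both echoes over the two windows."""
    n_acq = series.echo1.shape[-1]
    if windows.p > n_acq:
        raise ValueError("windows exceed the acquisition count")
    windows.validate_against(series.protocol)
    pre, sat = windows.pre_slice(), windows.sat_slice()
    fpre = series.echo1[..., pre].mean(axis=-1)
    spre = series.echo2[..., pre].mean(axis=-1)
    fsat = series.echo1[..., sat].mean(axis=-1)
    ssat = series.echo2[..., sat].mean(axis=-1)
    return fpre, spre, fsat, ssat


def _window_ratio(sum_f: np.ndarray, sum_s: np.ndarray, mu: float) -> np.ndarray:
    """(sum S)^(1/(mu-1)) / (sum F)^(mu/(mu-1)), the 1/A-proportional statistic."""
    a = 1.0 / (mu - 1.0)
    b = mu / (mu - 1.0)
    return np.power(sum_s, a) / np.maximum(np.power(sum_f, b), _EPS)


def estimate_flip_angle(
    series: DualEchoSeries,
    epre: np.ndarray,
    epost: np.ndarray,
    windows: BaselineWindows,
    mask: np.ndarray | None = None,
):
    """Per-voxel flip angle (degrees) and validity mask.

    Returns ``(theta_deg, valid)``; invalid voxels carry theta 0 and are
    excluded from every downstream stage.
    """
    if mask is None:
        mask = np.ones(series.echo1.shape[:-1], dtype=bool)
    mu = series.protocol.mu
    pre, sat = windows.pre_slice(), windows.sat_slice()
    sum_fpre = series.echo1[..., pre].sum(axis=-1)
    sum_spre = series.echo2[..., pre].sum(axis=-1)
    sum_fsat = series.echo1[..., sat].sum(axis=-1)
    sum_ssat = series.echo2[..., sat].sum(axis=-1)

    ok = mask & (sum_fpre > 0) & (sum_spre > 0) & (sum_fsat > 0) & (sum_ssat > 0)
    ok &= (epre > 0) & (epre < 1) & (epost > 0) & (epost < 1)

    with np.errstate(all="ignore"):
        q = _window_ratio(sum_fpre, sum_spre, mu) / np.maximum(
            _window_ratio(sum_fsat, sum_ssat, mu), _EPS
        )
        num = (1.0 - epost) - q * (1.0 - epre)
        den = epre * (1.0 - epost) - q * epost * (1.0 - epre)
        cos_theta = np.where(np.abs(den) > 0, num / np.where(den == 0, 1.0, den), np.nan)

    ok &= np.isfinite(cos_theta) & (cos_theta > 0.0) & (cos_theta < 1.0)
    theta = np.zeros_like(cos_theta)
    theta[ok] = np.degrees(np.arccos(cos_theta[ok]))
    n_bad = int(mask.sum() - ok.sum())
    if n_bad:
        logger.info("flip-angle estimation flagged %d voxel(s)", n_bad)
    return theta, ok


def estimate_delta_r1(
    series: DualEchoSeries,
    theta_est: np.ndarray,
    epre: np.ndarray,
    windows: BaselineWindows,
    valid: np.ndarray,
) -> ConcentrationSeries:
    """DeltaR1(t) per voxel-timepoint; independent of the post-study T1 map."""
    mu = series.protocol.mu
    tr = series.protocol.TR
    a = 1.0 / (mu - 1.0)
    b = mu / (mu - 1.0)
    pre = windows.pre_slice()
    n_pre = windows.length

    sum_fpre = series.echo1[..., pre].sum(axis=-1)
    sum_spre = series.echo2[..., pre].sum(axis=-1)

    shape = series.echo1.shape
    delta_r1 = np.zeros(shape)
    flagged = np.zeros(shape, dtype=bool)
    flagged[~valid, :] = False  # invalid voxels are excluded wholesale, not flagged per-t

    v = valid
    c = np.cos(np.deg2rad(theta_est[v]))[:, None]
    ep = epre[v][:, None]
    pre_ratio = (n_pre * _window_ratio(sum_fpre[v], sum_spre[v], mu))[:, None]

    f_t = series.echo1[v, :]
    s_t = series.echo2[v, :]
    pos = (f_t > 0) & (s_t > 0)
    with np.errstate(all="ignore"):
        rho = pre_ratio * np.power(f_t, b) / np.power(s_t, a)
        one_m_cep = 1.0 - c * ep
        num = one_m_cep - rho * (1.0 - ep)
        den = one_m_cep - c * rho * (1.0 - ep)
        e_t = num / den
        good = pos & np.isfinite(e_t) & (e_t > 0) & (num > 0) & (den > 0)
        dr1 = np.where(good, -np.log(np.where(good, e_t, 1.0) / ep) / tr, 0.0)

    delta_r1[v, :] = dr1
    flagged[v, :] = ~good
    n_flagged = int((~good).sum())
    if n_flagged:
        logger.info("DeltaR1 estimation flagged %d voxel-timepoint(s)", n_flagged)
    return ConcentrationSeries(
        delta_r1=delta_r1,
        theta_est=theta_est,
        valid=valid,
        flagged=flagged,
        windows=windows,
    )


def estimate_concentration(
    series: DualEchoSeries,
    t1pre_map: np.ndarray,
    t1post_map: np.ndarray,
    mask: np.ndarray | None = None,
    windows: BaselineWindows | None = None,
    theta_policy: str = "pooled",
) -> ConcentrationSeries:
    """Full relaxometry stage: T1 maps + dual-echo series -> DeltaR1 series.

    ``theta_policy`` controls what happens to voxels whose flip-angle arccos
    is degenerate (typically weakly enhancing tissue, where Epost ~ Epre):

    * ``"pooled"`` (default) — the flip angle is a property of the shared B1
      field, and the per-voxel estimate is well conditioned only where the
      T1 change between the windows is large.  The median flip angle over
      the most strongly enhancing quartile of estimable voxels is applied to
      the whole mask; each voxel's DeltaR1 still comes from its own signals.
    * ``"voxel"`` — strict per-voxel estimation; degenerate voxels are
      excluded from all downstream stages.
    """
    windows = windows or BaselineWindows.default_for(series.protocol)
    if mask is None:
        mask = np.ones(series.echo1.shape[:-1], dtype=bool)
    epre = e_from_t1(t1pre_map, series.protocol.TR, mask)
    epost = e_from_t1(t1post_map, series.protocol.TR, mask)
    theta, theta_valid = estimate_flip_angle(series, epre, epost, windows, mask)
    if theta_policy == "pooled":
        if not theta_valid.any():
            raise ValueError("no voxel yielded a valid flip angle to pool")
        enhancement = (epre - epost)[theta_valid]
        strong = enhancement >= np.quantile(enhancement, 0.75)
        pooled = float(np.median(theta[theta_valid][strong]))
        logger.info("pooled flip-angle policy: applying %.4f deg brain-wide", pooled)
        theta = np.where(mask, pooled, 0.0)
        valid = mask
    elif theta_policy == "voxel":
        valid = theta_valid
    else:
        raise ValueError("theta_policy must be 'pooled' or 'voxel'")
    return estimate_delta_r1(series, theta, epre, windows, valid)
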