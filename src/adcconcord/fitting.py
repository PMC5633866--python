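"""Voxel-wise monoexponential diffusion fitting in both algorithm families.

The signal model is S(b) = S0 * exp(-b * ADC).  Two families of estimators
are implemented, mirroring the split observed across analysis platforms:

``loglinear``
    Ordinary (unweighted) least squares of log(S) on b; ADC = -slope.
    With exactly two points this reduces algebraically to the explicit
    two-b-value solution ADC = [log(S1) - log(S2)] / (b2 - b1).
``nls``
    Nonlinear least squares on the untransformed signals (Levenberg-
    Marquardt), initialized from the log-linear estimate.  Because LM only
    accepts cost-decreasing steps, the NLS objective is never worse than at
    its log-linear initialization.

The perfusion-minimized analysis fits the slow (tissue) component on
b >= 100 s/mm^2 only and derives the perfusion fraction from the measured
unweighted signal: Pf = [S(0) - S0slow] / S(0).

Metrics (map names) follow the multisite study's nomenclature:

========== ==================================================================
ADC2       monoexponential ADC from a two-b-value study (explicit solution)
ADC4       monoexponential ADC from all four b-values
ADChi-low  two-point ADC from only the lowest and highest b-values
ADCslow    slow-component ADC from the b >= 100 s/mm^2 subset
PerfFrac   perfusion fraction Pf from the same slow fit
========== ==================================================================

All ADC maps are emitted in canonical units of 1e-6 mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .images import DWIStudy, ParametricMap

ADC_UNIT_SCALE = 1e6          # mm^2/s -> canonical 1e-6 mm^2/s map units
PERFUSION_B_MIN = 100.0       # s/mm^2; slow-component fit uses b >= this

FitMethod = Literal["two_point", "loglinear", "nls"]


@dataclass(frozen=True)
class FitConfig:
    """Fitting family and masking/solver options.

    ``signal_threshold`` masks voxels whose signal at any fitted b-value is
    at or below the threshold (default 0: any nonpositive signal masks the
    voxel).  Negative fitted ADCs are retained and flagged, not clipped,
    unless ``clip_negative`` is set.
    """

    method: FitMethod = "loglinear"
    b_subset: tuple[float, ...] | None = None
    signal_threshold: float = 0.0
    weighted_loglinear: bool = False
    clip_negative: bool = False
    nls_xtol: float = 1e-10
    nls_max_iter: int = 200


@dataclass
class VoxelFitResult:
    adc: float                  # mm^2/s
    s0_fit: float
    pf: float | None = None
    converged: bool = True
    masked: bool = False
    negative: bool = False


# ---------------------------------------------------------------------------
# elementary estimators

def adc_two_point(s1, s2, b1: float, b2: float):
    """Explicit two-b-value ADC: [log(s1) - log(s2)] / (b2 - b1).

    Vectorized; nonpositive signals yield NaN (a masked voxel, not an
    exception).  A negative ADC (s2 > s1) is returned as-is for flagging.
    """
    if b2 <= b1:
        raise ValueError("requires b2 > b1")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = (np.log(s1) - np.log(s2)) / (b2 - b1)
    bad = ~(np.isfinite(s1) & np.isfinite(s2) & (s1 > 0) & (s2 > 0))
    adc = np.where(bad, np.nan, adc)
    if adc.ndim == 0:
        return float(adc)
    return adc


def fit_loglinear(signals, bs, weighted: bool = False):
    """OLS of log(S) on b: returns (adc, s0_fit), vectorized over voxels.

    ``signals`` is (n_b,) or (n_b, n_vox); all signals must be positive
    (mask beforehand).  ``weighted=True`` weights each point by its signal,
    the first-order correction for log-transformed noise; the default is
    the plain unweighted regression used by the log-linear family.
    """
    s = np.atleast_2d(np.asarray(signals, dtype=float).T).T  # (n_b, n_vox)
    b = np.asarray(bs, dtype=float)
    if b.size != s.shape[0]:
        raise ValueError("one signal per b-value required")
    if b.size < 2:
        raise ValueError("need at least 2 b-values")
    y = np.log(s)
    if not weighted:
        X = np.column_stack([np.ones_like(b), b])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercept, slope = coef[0], coef[1]
    else:
        w = s                                           # sigma_logS ~ 1/S
        sw = w.sum(axis=0)
        bw = (w * b[:, None]).sum(axis=0) / sw
        yw = (w * y).sum(axis=0) / sw
        sxx = (w * (b[:, None] - bw) ** 2).sum(axis=0)
        sxy = (w * (b[:, None] - bw) * (y - yw)).sum(axis=0)
        slope = sxy / sxx
        intercept = yw - slope * bw
    adc = -slope
    s0 = np.exp(intercept)
    if np.ndim(signals) == 1:
        return float(adc[0]), float(s0[0])
    return adc, s0


def _exp_model_cost(s, b, s0, adc) -> float:
    return float(np.sum((s0 * np.exp(-b * adc) - s) ** 2))


def fit_nls(signals, bs, cfg: FitConfig | None = None):
    """Levenberg-Marquardt fit of S0*exp(-b*ADC) to one voxel's signals.

    Returns (adc, s0_fit, converged).  Initialization is the log-linear
    solution (falling back to a two-point estimate from the extreme
    b-values when the log-linear estimate is unusable); on solver failure
    the initialization is returned with ``converged=False``.
    """
    cfg = cfg or FitConfig(method="nls")
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bs, dtype=float)
    if s.size != b.size or s.size < 2:
        raise ValueError("need one signal per b-value, at least two")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        # positive initialization is still possible in principle, but a
        # nonpositive magnitude signal marks a masked voxel by convention
        return np.nan, np.nan, False
    adc0, s00 = fit_loglinear(s, b)
    if not (np.isfinite(adc0) and np.isfinite(s00) and s00 > 0):
        adc0 = adc_two_point(s[0], s[-1], b[0], b[-1])
        s00 = s[0]
    def resid(p):
        return p[0] * np.exp(-b * p[1]) - s
    def jac(p):
        e = np.exp(-b * p[1])
        return np.column_stack([e, -p[0] * b * e])
    try:
        res = least_squares(
            resid, x0=[s00, adc0], jac=jac, method="lm",
            xtol=cfg.nls_xtol, ftol=cfg.nls_xtol, gtol=cfg.nls_xtol,
            max_nfev=cfg.nls_max_iter * 3,
        )
    except Exception:
        return float(adc0), float(s00), False
    if not res.success:
        return float(adc0), float(s00), False
    s0_hat, adc_hat = res.x
    # LM is monotone from its initialization, but guard against pathologies
    if _exp_model_cost(s, b, s0_hat, adc_hat) > _exp_model_cost(s, b, s00, adc0):
        return float(adc0), float(s00), False
    return float(adc_hat), float(s0_hat), True


def adc_hi_low(signals, bs):
    """Two-point ADC from only the lowest and highest b-values (b=0 required)."""
    b = np.asarray(bs, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.min() != 0.0:
        raise ValueError("hi-low metric requires a b=0 acquisition")
    ilo, ihi = int(np.argmin(b)), int(np.argmax(b))
    return adc_two_point(s[ilo], s[ihi], b[ilo], b[ihi])


def fit_perfusion_minimized(signals, bs, method: Literal["loglinear", "nls"] = "loglinear",
                            cfg: FitConfig | None = None):
    """Slow-component fit on b >= 100 s/mm^2 plus perfusion fraction.

    Returns (adc_slow, s0_slow, pf) with Pf = [S(0) - S0slow] / S(0) from
    the *measured* b=0 signal.  Requires b=0 and at least two b >= 100.
    S(0) <= 0 marks the voxel masked (NaN result).
    """
    b = np.asarray(bs, dtype=float)
    s = np.asarray(signals, dtype=float)
    if 0.0 not in b:
        raise ValueError("perfusion-minimized analysis requires b=0")
    hi = b >= PERFUSION_B_MIN
    if hi.sum() < 2:
        raise ValueError("need at least two b-values >= 100 s/mm^2")
    s0_meas = float(s[b == 0.0][0])
    if not np.isfinite(s0_meas) or s0_meas <= 0:
        return np.nan, np.nan, np.nan
    sh, bh = s[hi], b[hi]
    if np.any(~np.isfinite(sh)) or np.any(sh <= 0):
        return np.nan, np.nan, np.nan
    if method == "loglinear":
        adc_slow, s0_slow = fit_loglinear(sh, bh)
    elif method == "nls":
        adc_slow, s0_slow, _ = fit_nls(sh, bh, cfg)
    else:
        raise ValueError(f"unknown method {method!r}")
    pf = (s0_meas - s0_slow) / s0_meas
    return float(adc_slow), float(s0_slow), float(pf)


# ---------------------------------------------------------------------------
# whole-volume fitting

#: b-values each metric needs, as (predicate, human description)
def _metric_b_values(metric: str, b_values: tuple[float, ...]) -> tuple[float, ...]:
    b = tuple(b_values)
    if metric == "ADC2":
        if len(b) != 2:
            raise ValueError(
                f"ADC2 needs exactly 2 b-values, study has {len(b)}: {b}")
        return b
    if metric == "ADC4":
        if len(b) < 3:
            raise ValueError(f"ADC4 needs a multi-b study (>=3 b-values), got {b}")
        return b
    if metric == "ADChi-low":
        if 0.0 not in b:
            raise ValueError("ADChi-low requires the missing b=0 image")
        return (min(b), max(b))
    if metric in ("ADCslow", "PerfFrac"):
        if 0.0 not in b:
            raise ValueError(f"{metric} requires the missing b=0 image")
        nhi = sum(1 for x in b if x >= PERFUSION_B_MIN)
        if nhi < 2:
            raise ValueError(
                f"{metric} requires >=2 b-values >= {PERFUSION_B_MIN:.0f} s/mm^2")
        return (0.0,) + tuple(x for x in b if x >= PERFUSION_B_MIN)
    raise ValueError(f"unknown metric {metric!r}")


def fit_volume(study: DWIStudy, cfg: FitConfig, metric: str) -> ParametricMap:
    """Fit one metric voxel-by-voxel over a study, emitting a parametric map.

    Directional studies are trace-reconstructed first.  Voxels failing the
    masking rule (non-finite or <= ``signal_threshold`` at any fitted
    b-value) are masked and reported as 0.  ADC maps are in 1e-6 mm^2/s.
    """
    from .synth import compute_trace  # local import avoids a cycle

    if not study.is_trace:
        study = compute_trace(study)
    bs = _metric_b_values(metric, study.b_values)
    sig = np.stack([study.signal(b) for b in bs])          # (n_b, nz, ny, nx)
    shape = sig.shape[1:]
    flat = sig.reshape(len(bs), -1)
    usable = np.all(np.isfinite(flat) & (flat > cfg.signal_threshold), axis=0)

    values = np.zeros(flat.shape[1])
    mask = usable.copy()
    b_arr = np.asarray(bs)
    idx = np.nonzero(usable)[0]
    n_nonconv = 0

    if metric in ("ADC2", "ADChi-low"):
        adc = adc_two_point(flat[0, idx], flat[-1, idx], bs[0], bs[-1])
        values[idx] = np.asarray(adc) * ADC_UNIT_SCALE
    elif metric == "ADC4":
        if cfg.method in ("loglinear", "two_point"):
            adc, _ = fit_loglinear(flat[:, idx], b_arr,
                                   weighted=cfg.weighted_loglinear)
            values[idx] = adc * ADC_UNIT_SCALE
        elif cfg.method == "nls":
            for j in idx:
                a, _, conv = fit_nls(flat[:, j], b_arr, cfg)
                values[j] = a * ADC_UNIT_SCALE
                n_nonconv += not conv
        else:
            raise ValueError(f"unknown fit method {cfg.method!r}")
    elif metric in ("ADCslow", "PerfFrac"):
        meth = "nls" if cfg.method == "nls" else "loglinear"
        hi = b_arr >= PERFUSION_B_MIN
        if meth == "loglinear":
            adc_slow, s0_slow = fit_loglinear(flat[hi][:, idx], b_arr[hi],
                                              weighted=cfg.weighted_loglinear)
        else:
            adc_slow = np.empty(idx.size)
            s0_slow = np.empty(idx.size)
            for k, j in enumerate(idx):
                a, s0f, conv = fit_nls(flat[hi, j], b_arr[hi], cfg)
                adc_slow[k], s0_slow[k] = a, s0f
                n_nonconv += not conv
        if metric == "ADCslow":
            values[idx] = adc_slow * ADC_UNIT_SCALE
        else:
            s0_meas = flat[0, idx]                         # b=0 comes first
            values[idx] = (s0_meas - s0_slow) / s0_meas
    else:  # pragma: no cover - guarded by _metric_b_values
        raise ValueError(f"unknown metric {metric!r}")

    bad = ~np.isfinite(values)
    values[bad] = 0.0
    mask &= ~bad
    negative = mask & (values < 0)
    if cfg.clip_negative:
        values[negative] = 0.0

    values = values.reshape(shape)
    mask = mask.reshape(shape)
    meta = {
        "source": study.metadata.get("label"),
        "fit_b_values": list(bs),
        "n_negative": int(negative.sum()),
        "n_nonconverged": int(n_nonconv),
    }
    if metric == "PerfFrac":
        flatv = values.reshape(-1)
        meta["n_pf_out_of_range"] = int(
            np.sum(mask.reshape(-1) & ((flatv < 0) | (flatv > 1))))
    return ParametricMap(
        values=values,
        mask=mask,
        metric=metric,
        method=cfg.method,
        rescale_factor=1.0,
        spacing=study.spacing,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# independent brute-force reference for the nonlinear fit

def grid_search_adc(signals, bs, adc_max: float = 4e-3, step: float = 1e-7):
    """Exhaustive profile-likelihood grid search over ADC in [0, adc_max].

    For each candidate ADC, the optimal S0 has the closed form
    S0*(ADC) = sum(S e^{-b ADC}) / sum(e^{-2 b ADC}); the returned ADC
    minimizes the profiled sum of squares on the grid.  This is the slow,
    assumption-free reference against which the LM solver is validated.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bs, dtype=float)
    grid = np.arange(0.0, adc_max + step / 2, step)
    # profile objective, chunked to bound memory
    best_sse = np.inf
    best_adc = 0.0
    chunk = 200_000
    for lo in range(0, grid.size, chunk):
        g = grid[lo:lo + chunk]
        E = np.exp(-np.outer(b, g))                 # (n_b, n_g)
        num = s @ E
        den = np.sum(E * E, axis=0)
        sse = np.sum(s * s) - num * num / den
        j = int(np.argmin(sse))
        if sse[j] < best_sse:
            best_sse = float(sse[j])
            best_adc = float(g[j])
    return best_adc
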