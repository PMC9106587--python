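"""Auto-/cross-correlation of photon streams and FCS/FCCS model fitting.

The correlation estimator convention is

    G(tau) = <dF1(t) dF2(t+tau)> / (<F1><F2>)

so for one freely diffusing species observed through a 3D Gaussian volume the
zero-lag amplitude is G(0) = 1 / (pi^{3/2} w0^2 z0 C) and the decay follows
1/((1 + 4 D tau / w0^2) sqrt(1 + 4 D tau / z0^2)).  The flow term of the
underlying model is fixed at zero velocity and never evaluated.

Two estimator schemes are provided: a multi-tau ladder (16 linear lags per
octave, coarsening by 2) and a brute-force direct estimator over the same
coarse binning, retained as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .errors import AmplitudeDegenerateError, EmptyInputError, FitFailureError
from .simulate import OpticalConfig
from .streams import PhotonStream

__all__ = [
    "CorrelationCurve",
    "FCSFit",
    "FCCSFit",
    "compute_correlation",
    "fcs_model",
    "fit_fcs",
    "calibrate_optics",
    "fit_fccs",
    "write_curve_tsv",
    "read_curve_tsv",
]

_LAGS_PER_OCTAVE = 16
_SE_FLOOR_FRAC = 1e-4
_N_BLOCKS = 10


@dataclass
class CorrelationCurve:
    """Lag/value/uncertainty triples for an auto- or cross-correlation."""

    lags: np.ndarray
    G: np.ndarray
    se: np.ndarray
    kind: str = "auto_D"

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=np.float64)
        self.G = np.asarray(self.G, dtype=np.float64)
        self.se = np.asarray(self.se, dtype=np.float64)
        if not (len(self.lags) == len(self.G) == len(self.se)):
            raise ValueError("lags/G/se must have equal length")
        if len(self.lags) and (np.any(np.diff(self.lags) <= 0) or self.lags[0] <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if np.any(self.se < 0):
            raise ValueError("se must be nonnegative")
        if not (np.all(np.isfinite(self.G)) and np.all(np.isfinite(self.se))):
            raise ValueError("curve values must be finite")

    def __len__(self):
        return len(self.lags)


def _parse_selector(sel):
    """A selector is 'D', ('D', 'Dex'), or ('A', None)."""
    if isinstance(sel, str):
        return sel, None
    channel, gate = sel
    return channel, gate


def _multitau_lags(n_base, base_dt, lag_max):
    """(level, k) pairs of the multi-tau ladder up to lag_max."""
    out = []
    level = 0
    n = n_base
    while True:
        width = base_dt * (1 << level)
        ks = range(1, _LAGS_PER_OCTAVE + 1) if level == 0 else \
            range(_LAGS_PER_OCTAVE // 2 + 1, _LAGS_PER_OCTAVE + 1)
        added = False
        for k in ks:
            lag = k * width
            if lag > lag_max or k >= n:
                continue
            out.append((level, k))
            added = True
        if not added and (1 << level) * base_dt > lag_max:
            break
        level += 1
        n //= 2
        if n < _LAGS_PER_OCTAVE // 2 + 2:
            break
    return out


def _corr_at_lag(f1, f2, k):
    n = len(f1) - k
    if n < 2:
        return np.nan
    num = np.dot(f1[:n], f2[k:]) / n
    m1 = f1[:n].mean()
    m2 = f2[k:].mean()
    if m1 == 0 or m2 == 0:
        return np.nan
    return num / (m1 * m2) - 1.0


def _correlate_binned(f1, f2, base_dt, lag_max, scheme):
    """Correlation of two equally-binned count arrays on the multi-tau ladder."""
    plan = _multitau_lags(len(f1), base_dt, lag_max)
    lags = np.array([k * base_dt * (1 << lvl) for lvl, k in plan])
    vals = np.empty(len(plan))
    if scheme == "multitau":
        c1, c2 = f1.astype(np.float64), f2.astype(np.float64)
        cur = 0
        for i, (lvl, k) in enumerate(plan):
            while lvl > cur:  # coarsen by pair-summing
                m = len(c1) // 2
                c1 = c1[: 2 * m].reshape(m, 2).sum(axis=1)
                c2 = c2[: 2 * m].reshape(m, 2).sum(axis=1)
                cur += 1
            vals[i] = _corr_at_lag(c1, c2, k)
    elif scheme == "direct":
        for i, (lvl, k) in enumerate(plan):
            fac = 1 << lvl
            m = len(f1) // fac
            c1 = f1[: m * fac].astype(np.float64).reshape(m, fac).sum(axis=1)
            c2 = f2[: m * fac].astype(np.float64).reshape(m, fac).sum(axis=1)
            vals[i] = _corr_at_lag(c1, c2, k)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return lags, vals


def compute_correlation(
    stream: PhotonStream,
    ch1,
    ch2=None,
    lag_range: tuple[float, float] = (1e-5, 1.0),
    scheme: str = "multitau",
) -> CorrelationCurve:
    """Correlate two channel/gate selections of a photon stream.

    ``ch1``/``ch2`` select photons by channel and (optionally) PIE gate,
    e.g. ``("D", "Dex")``; ``ch2=None`` means autocorrelation of ``ch1``.
    Per-lag standard errors come from block averaging over ``10`` contiguous
    segments of the record.
    """
    lag_min, lag_max = lag_range
    if lag_min <= 0 or lag_max <= lag_min:
        raise ValueError("lag_range must satisfy 0 < lag_min < lag_max")
    if lag_max > stream.duration / 2:
        raise ValueError("lag_range exceeds half the acquisition duration")
    auto = ch2 is None or ch2 == ch1
    c1, g1 = _parse_selector(ch1)
    c2, g2 = _parse_selector(ch1 if ch2 is None else ch2)
    f1 = stream.counts(lag_min, channel=c1, gate=g1)
    f2 = f1 if auto else stream.counts(lag_min, channel=c2, gate=g2)
    if f1.sum() == 0 or f2.sum() == 0:
        raise EmptyInputError("no photons in the requested channel/gate selection")

    lags, vals = _correlate_binned(f1, f2, lag_min, lag_max, scheme)
    keep = np.isfinite(vals)

    # block-averaged standard errors (always on the multitau path)
    block_len = len(f1) // _N_BLOCKS
    block_vals = []
    if block_len >= 4:
        for b in range(_N_BLOCKS):
            sl = slice(b * block_len, (b + 1) * block_len)
            bl, bv = _correlate_binned(f1[sl], f2[sl],
                                       lag_min, lag_max, "multitau")
            block_vals.append((bl, bv))
    se = np.full(len(lags), np.nan)
    if block_vals:
        common = min(len(bl) for bl, _ in block_vals)
        stack = np.vstack([bv[:common] for _, bv in block_vals])
        import warnings
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se_block = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(len(block_vals))
        se[:common] = se_block
    if np.any(np.isnan(se)):
        fill = np.nanmax(se) if np.any(np.isfinite(se)) else 0.0
        se = np.where(np.isnan(se), fill, se)

    if auto:
        kind = "auto_D" if c1 == "D" else "auto_A"
    else:
        kind = "cross"
    return CorrelationCurve(lags=lags[keep], G=vals[keep], se=se[keep], kind=kind)


def _diffusion_factor(tau, D, w0, z0):
    tau = np.asarray(tau, dtype=np.float64)
    return 1.0 / ((1.0 + 4.0 * D * tau / w0 ** 2)
                  * np.sqrt(1.0 + 4.0 * D * tau / z0 ** 2))


@dataclass
class FCSFit:
    """Single-species FCS fit: concentration (particles/µm³), diffusion
    coefficient (µm²/s), and the fixed optics. Flow velocity is fixed at 0."""

    C: float
    D: float
    w0: float
    z0: float
    V: float = 0.0
    se_C: float = np.nan
    se_D: float = np.nan
    residuals: np.ndarray | None = None
    redchi: float = np.nan

    def __post_init__(self):
        if self.C <= 0 or self.D <= 0:
            raise ValueError("C and D must be positive")
        if self.V != 0:
            raise ValueError("flow velocity is fixed at zero")


def fcs_model(tau, fit_or_C, D=None, w0=None, z0=None):
    """Evaluate the one-species 3D-Gaussian FCS model.

    Accepts either an :class:`FCSFit` or explicit (C, D, w0, z0).
    G(0) = 1/(pi^{3/2} w0^2 z0 C), monotone decreasing in tau.
    """
    if isinstance(fit_or_C, FCSFit):
        C, D, w0, z0 = fit_or_C.C, fit_or_C.D, fit_or_C.w0, fit_or_C.z0
    else:
        C = fit_or_C
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    amp = 1.0 / (np.pi ** 1.5 * w0 ** 2 * z0 * C)
    return amp * _diffusion_factor(tau, D, w0, z0)


def _fit_weights(curve: CorrelationCurve, g0_est: float) -> np.ndarray:
    floor = _SE_FLOOR_FRAC * abs(g0_est)
    se = np.maximum(curve.se, floor if floor > 0 else np.max(curve.se) * 1e-3)
    se = np.where(se > 0, se, np.max(se[se > 0]) if np.any(se > 0) else 1.0)
    return 1.0 / se


def _amplitude_estimate(curve: CorrelationCurve) -> float:
    k = max(min(3, len(curve)), 1)
    return float(np.mean(curve.G[:k]))


def fit_fcs(curve: CorrelationCurve, optics: OpticalConfig,
            init: FCSFit | None = None, n_restarts: int = 3,
            offset_free: bool = True) -> FCSFit:
    """Weighted least-squares fit of the one-species FCS model.

    w0 and z0 are fixed from calibration; C and D are free, plus (by
    default) an additive baseline: real correlators sit on small constant
    offsets from slow drifts, and a closed simulation box with a fixed
    particle count carries an exact -1/N baseline from suppressed number
    fluctuations, so the baseline is part of the measurement model rather
    than of the diffusion law.  Raises
    :class:`AmplitudeDegenerateError` when the curve carries no amplitude
    (pure background) and :class:`FitFailureError` on non-convergence after
    bounded restarts.
    """
    if len(curve) < 10:
        raise ValueError("need >= 10 lags to fit")
    if curve.lags[-1] / curve.lags[0] < 100:
        raise ValueError("curve must span >= 2 decades of lag")
    w0, z0 = optics.w0, optics.z0
    g0 = _amplitude_estimate(curve)
    se_ref = np.median(curve.se[curve.se > 0]) if np.any(curve.se > 0) else 0.0
    if g0 <= 0 or (se_ref > 0 and g0 < 3 * se_ref):
        raise AmplitudeDegenerateError(
            "correlation amplitude indistinguishable from zero")

    if init is not None:
        c0, d0 = init.C, init.D
    else:
        c0 = 1.0 / (np.pi ** 1.5 * w0 ** 2 * z0 * g0)
        # crude half-decay lag -> D
        half = np.argmin(np.abs(curve.G - g0 / 2))
        tau_half = curve.lags[max(half, 1)]
        d0 = max(w0 ** 2 / (4 * tau_half), 1e-3)
    weights = _fit_weights(curve, g0)

    params = lmfit.Parameters()
    params.add("C", value=c0, min=c0 * 1e-3, max=c0 * 1e3)
    params.add("D", value=d0, min=d0 * 1e-3, max=d0 * 1e3)
    params.add("G_inf", value=0.0, vary=offset_free)

    def resid(p):
        return (fcs_model(curve.lags, p["C"].value, p["D"].value, w0, z0)
                + p["G_inf"].value - curve.G) * weights

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(n_restarts):
        if attempt:
            params["C"].value = c0 * np.exp(rng.normal(0, 0.3))
            params["D"].value = d0 * np.exp(rng.normal(0, 0.3))
        res = lmfit.minimize(resid, params, method="least_squares")
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and attempt == 0:
            break
    if best is None or not best.success:
        raise FitFailureError("FCS fit failed to converge", diagnostics=best)
    p = best.params
    return FCSFit(C=p["C"].value, D=p["D"].value, w0=w0, z0=z0,
                  se_C=p["C"].stderr or np.nan, se_D=p["D"].stderr or np.nan,
                  residuals=np.asarray(best.residual), redchi=best.redchi)


def calibrate_optics(curve: CorrelationCurve, D_ref: float = 430.0,
                     shape_ratio: float | None = None,
                     optics_template: OpticalConfig | None = None) -> OpticalConfig:
    """Infer w0 (and z0) from a calibration dye of known diffusion coefficient.

    Fits the one-species model with D fixed at ``D_ref`` (rhodamine-type
    calibration standard); the structure parameter z0/w0 is either fitted or
    fixed at ``shape_ratio``.
    """
    if D_ref <= 0:
        raise ValueError("D_ref must be positive")
    g0 = _amplitude_estimate(curve)
    if g0 <= 0:
        raise AmplitudeDegenerateError("calibration curve has no amplitude")
    half = np.argmin(np.abs(curve.G - g0 / 2))
    tau_half = curve.lags[max(half, 1)]
    w0_0 = max(np.sqrt(4 * D_ref * tau_half), 1e-3)
    weights = _fit_weights(curve, g0)

    params = lmfit.Parameters()
    params.add("w0", value=w0_0, min=w0_0 / 30, max=w0_0 * 30)
    if shape_ratio is None:
        params.add("ratio", value=5.0, min=1.0, max=50.0)
    else:
        params.add("ratio", value=shape_ratio, vary=False)
    params.add("C", value=1.0, min=1e-6, max=1e6)
    params.add("G_inf", value=0.0)

    def resid(p):
        w0 = p["w0"].value
        z0 = w0 * p["ratio"].value
        return (fcs_model(curve.lags, p["C"].value, D_ref, w0, z0)
                + p["G_inf"].value - curve.G) * weights

    res = lmfit.minimize(resid, params, method="least_squares")
    if not res.success:
        raise FitFailureError("optics calibration failed", diagnostics=res)
    w0 = res.params["w0"].value
    z0 = w0 * res.params["ratio"].value
    base = optics_template or OpticalConfig()
    return OpticalConfig(w0=w0, z0=z0, pie_period=base.pie_period,
                         leak_frac=base.leak_frac, direct_frac=base.direct_frac,
                         bg_rate=base.bg_rate)


@dataclass
class FCCSFit:
    """Simultaneous dual-colour fit: free acceptor/donor and double-labelled
    particle densities (particles/µm³) with their diffusion coefficients.

    ``n_ad`` is the printed number of cross-correlated particles,
    Gx(0) / (2 sqrt(2) Ga(0) Gd(0)); ``n_ad_unscaled`` is C_ad * V_eff =
    Gx(0)/(Ga(0) Gd(0)), the value the printed C_ad and N_ad definitions give
    when combined algebraically (the two printed formulas differ by the
    2 sqrt 2).  ``significant`` is False when the cross-amplitude is
    consistent with zero."""

    Ca: float
    Cd: float
    Cad: float
    Da: float
    Dd: float
    Dad: float
    w0: float
    z0: float
    n_ad: float
    veff: float
    n_ad_unscaled: float = np.nan
    se_n_ad: float = np.nan
    se_Cad: float = np.nan
    significant: bool = True
    redchi: float = np.nan

    def __post_init__(self):
        if min(self.Ca, self.Cd, self.Cad) < 0:
            raise ValueError("densities must be nonnegative")
        if min(self.Da, self.Dd, self.Dad) <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.veff <= 0:
            raise ValueError("Veff must be positive")


def effective_volume(optics: OpticalConfig) -> float:
    """V_eff = pi^{3/2} w0^2 z0 / (2 sqrt 2), in µm³ (printed convention)."""
    return np.pi ** 1.5 * optics.w0 ** 2 * optics.z0 / (2.0 * np.sqrt(2.0))


def n_ad_from_amplitudes(gx0: float, ga0: float, gd0: float) -> float:
    """Printed cross-correlated particle number Gx(0)/(2 sqrt 2 Ga(0) Gd(0))."""
    return gx0 / (2.0 * np.sqrt(2.0) * ga0 * gd0)


def _fccs_models(p, lags, w0, z0):
    pref = np.pi ** 1.5 * w0 ** 2 * z0
    ca, cd, cad = p["Ca"], p["Cd"], p["Cad"]
    ga = (ca * _diffusion_factor(lags, p["Da"], w0, z0)
          + cad * _diffusion_factor(lags, p["Dad"], w0, z0)) / (pref * (ca + cad) ** 2)
    gd = (cd * _diffusion_factor(lags, p["Dd"], w0, z0)
          + cad * _diffusion_factor(lags, p["Dad"], w0, z0)) / (pref * (cd + cad) ** 2)
    gx = (cad * _diffusion_factor(lags, p["Dad"], w0, z0)
          / (pref * (ca + cad) * (cd + cad)))
    return ga, gd, gx


def fit_fccs(Ga: CorrelationCurve, Gd: CorrelationCurve, Gx: CorrelationCurve,
             optics: OpticalConfig) -> FCCSFit:
    """Simultaneous two-component fit of the two autocorrelations and the
    cross-correlation, sharing the calibrated w0/z0.

    Each autocorrelation is the two-component (free + double-labelled) sum;
    the cross-correlation carries only the double-labelled term.  When the
    cross amplitude is consistent with zero the fit returns ``n_ad ≈ 0``
    with ``significant=False`` rather than raising.
    """
    if not (len(Ga) == len(Gd) == len(Gx)) or \
            not np.allclose(Ga.lags, Gd.lags) or not np.allclose(Ga.lags, Gx.lags):
        raise ValueError("the three curves must share one lag grid")
    w0, z0 = optics.w0, optics.z0
    pref = np.pi ** 1.5 * w0 ** 2 * z0
    ga0 = _amplitude_estimate(Ga)
    gd0 = _amplitude_estimate(Gd)
    gx0 = _amplitude_estimate(Gx)
    if ga0 <= 0 or gd0 <= 0:
        raise AmplitudeDegenerateError("autocorrelation amplitude missing")
    gx_se = np.median(Gx.se[Gx.se > 0]) if np.any(Gx.se > 0) else 0.0
    cross_present = gx0 > 3 * gx_se and gx0 > 0

    ctot_a = 1.0 / (pref * ga0)
    ctot_d = 1.0 / (pref * gd0)
    cad0 = max(gx0, 1e-6 * min(ctot_a, ctot_d)) * ctot_a * ctot_d * pref
    cad0 = min(cad0, 0.95 * min(ctot_a, ctot_d))

    def tau_half_D(curve, g0):
        half = np.argmin(np.abs(curve.G - g0 / 2))
        return max(w0 ** 2 / (4 * curve.lags[max(half, 1)]), 1e-3)

    params = lmfit.Parameters()
    params.add("Cad", value=cad0, min=0.0, max=2 * min(ctot_a, ctot_d))
    params.add("Ca", value=max(ctot_a - cad0, 1e-6), min=0.0, max=10 * ctot_a)
    params.add("Cd", value=max(ctot_d - cad0, 1e-6), min=0.0, max=10 * ctot_d)
    da0 = tau_half_D(Ga, ga0)
    dd0 = tau_half_D(Gd, gd0)
    params.add("Da", value=da0, min=da0 / 100, max=da0 * 100)
    params.add("Dd", value=dd0, min=dd0 / 100, max=dd0 * 100)
    params.add("Dad", value=min(da0, dd0) / 2, min=min(da0, dd0) / 300,
               max=max(da0, dd0) * 100)
    for name in ("offa", "offd", "offx"):  # per-curve baselines
        params.add(name, value=0.0)

    wa = _fit_weights(Ga, ga0)
    wd = _fit_weights(Gd, gd0)
    wx = _fit_weights(Gx, max(gx0, 0.05 * min(ga0, gd0)))

    def resid(p):
        v = {k: p[k].value for k in p}
        ma, md, mx = _fccs_models(v, Ga.lags, w0, z0)
        return np.concatenate([(ma + v["offa"] - Ga.G) * wa,
                               (md + v["offd"] - Gd.G) * wd,
                               (mx + v["offx"] - Gx.G) * wx])

    res = lmfit.minimize(resid, params, method="least_squares")
    if not res.success:
        raise FitFailureError("FCCS fit failed to converge", diagnostics=res)
    p = res.params
    ca, cd, cad = p["Ca"].value, p["Cd"].value, p["Cad"].value
    ga0_fit = (ca + cad) / (pref * (ca + cad) ** 2)
    gd0_fit = (cd + cad) / (pref * (cd + cad) ** 2)
    gx0_fit = cad / (pref * (ca + cad) * (cd + cad))
    veff = effective_volume(optics)
    n_ad = n_ad_from_amplitudes(gx0_fit, ga0_fit, gd0_fit)
    n_ad_unscaled = gx0_fit / (ga0_fit * gd0_fit)

    se_cad = p["Cad"].stderr or np.nan
    # delta-method propagation Cad -> N_ad at fixed totals
    if np.isfinite(se_cad) and cad > 0:
        se_n_ad = n_ad * se_cad / cad
    else:
        se_n_ad = np.nan
    significant = cross_present and (not np.isfinite(se_cad) or cad > 3 * se_cad)
    if not cross_present:
        n_ad = 0.0 if cad == 0 else n_ad
    return FCCSFit(Ca=ca, Cd=cd, Cad=cad, Da=p["Da"].value, Dd=p["Dd"].value,
                   Dad=p["Dad"].value, w0=w0, z0=z0, n_ad=n_ad, veff=veff,
                   n_ad_unscaled=n_ad_unscaled, se_n_ad=se_n_ad, se_Cad=se_cad,
                   significant=significant, redchi=res.redchi)


def write_curve_tsv(curve: CorrelationCurve, path) -> None:
    pd.DataFrame({"lag_s": curve.lags, "G": curve.G, "se": curve.se}).to_csv(
        path, sep="\t", index=False, float_format="%.10e")


def read_curve_tsv(path, kind: str = "auto_D") -> CorrelationCurve:
    df = pd.read_csv(path, sep="\t")
    return CorrelationCurve(df["lag_s"].to_numpy(), df["G"].to_numpy(),
                            df["se"].to_numpy(), kind=kind)
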