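"""Exponential kinetics, FRAP normalization, solubility fractions, linear
calibrations, and nuclear-concentration estimates.

Aggregation (ThT) traces follow the single exponential y = A e^{R t} with
time constant 1/|R|; FRAP recovery is fitted as the decaying deficit
y = F_inf - B e^{R t} with R < 0.  The reported ``time_constant`` is -1/R
(the convention under which recovery "half-times" are quoted alongside these
fits); the true half-time ln2 * (-1/R) is reported separately as
``half_time``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

from .errors import FitFailureError

__all__ = [
    "KineticTrace",
    "ExpFit",
    "CalibrationLine",
    "fit_exponential",
    "normalize_frap",
    "solubility_fraction",
    "fit_calibration",
    "nuclear_concentration",
]


@dataclass
class KineticTrace:
    """Time/value series, optionally with a reference-ROI channel."""

    t: np.ndarray
    y: np.ndarray
    y_ref: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("t must be sorted ascending")
        if self.y_ref is not None:
            self.y_ref = np.asarray(self.y_ref, dtype=np.float64)
            if len(self.y_ref) != len(self.t):
                raise ValueError("y_ref must match t in length")


@dataclass
class ExpFit:
    """Exponential fit result.  ``time_constant`` is 1/|R| for growth mode
    and -1/R for recovery mode (the printed convention); ``half_time`` is
    the ln2-corrected recovery half-time."""

    A: float
    R: float
    time_constant: float
    se_A: float = np.nan
    se_R: float = np.nan
    offset: float = 0.0
    f_inf: float = np.nan
    se_f_inf: float = np.nan
    half_time: float = np.nan
    mode: str = "growth"
    wrong_sign: bool = False
    redchi: float = np.nan


def _multistart_minimize(resid, params, n_starts: int = 3, seed: int = 0):
    rng = np.random.default_rng(seed)
    best = None
    base = {k: params[k].value for k in params}
    for attempt in range(n_starts):
        for k in params:
            if params[k].vary:
                jitter = 1.0 if attempt == 0 else np.exp(rng.normal(0, 0.2))
                v = base[k] * jitter
                lo, hi = params[k].min, params[k].max
                params[k].value = np.clip(v, lo, hi) if np.isfinite(lo) else v
        res = lmfit.minimize(resid, params, method="least_squares")
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitFailureError("exponential fit failed to converge",
                              diagnostics=best)
    return best


def fit_exponential(trace: KineticTrace, mode: str = "growth",
                    offset_free: bool = False) -> ExpFit:
    """Fit y = A e^{R t} (+offset) or the FRAP form y = F_inf - B e^{R t}.

    ``frap_recovery`` expects an already-normalized trace and reports
    ``time_constant = -1/R`` (labelled tau_recovery in the field's
    convention) plus the ln2-corrected ``half_time``.  A fitted rate of the
    wrong sign for the requested mode sets ``wrong_sign=True`` rather than
    raising.
    """
    t, y = trace.t, trace.y
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    if mode not in ("growth", "frap_recovery"):
        raise ValueError(f"unknown mode {mode!r}")

    params = lmfit.Parameters()
    if mode == "growth":
        y_pos = np.maximum(np.abs(y), 1e-12)
        slope, intercept, *_ = stats.linregress(t, np.log(y_pos))
        params.add("A", value=float(np.exp(intercept)))
        params.add("R", value=float(slope))
        params.add("offset", value=0.0, vary=offset_free)

        def resid(p):
            return p["A"].value * np.exp(p["R"].value * t) + p["offset"].value - y
    else:
        f_inf0 = float(y[-1])
        b0 = max(float(f_inf0 - y[0]), 1e-6)
        span = max(t[-1] - t[0], 1e-12)
        params.add("f_inf", value=f_inf0)
        params.add("B", value=b0)
        params.add("R", value=-2.0 / span, max=0.0)

        def resid(p):
            return (p["f_inf"].value - p["B"].value * np.exp(p["R"].value * t)) - y

    res = _multistart_minimize(resid, params)
    p = res.params
    R = p["R"].value
    se_R = p["R"].stderr or np.nan
    if mode == "growth":
        A = p["A"].value
        tc = 1.0 / abs(R) if R != 0 else np.inf
        return ExpFit(A=A, R=R, time_constant=tc,
                      se_A=p["A"].stderr or np.nan, se_R=se_R,
                      offset=p["offset"].value, mode=mode,
                      wrong_sign=False, redchi=res.redchi)
    B = p["B"].value
    tc = -1.0 / R if R < 0 else np.inf
    return ExpFit(A=B, R=R, time_constant=tc, se_A=p["B"].stderr or np.nan,
                  se_R=se_R, f_inf=p["f_inf"].value,
                  se_f_inf=p["f_inf"].stderr or np.nan,
                  half_time=np.log(2.0) * tc, mode=mode,
                  wrong_sign=R >= 0, redchi=res.redchi)


def normalize_frap(roi: KineticTrace, ref: KineticTrace,
                   n_prebleach: int) -> KineticTrace:
    """Correct a FRAP ROI for acquisition photobleaching and normalize to the
    pre-bleach level: F(t) = (roi/ref) / mean_prebleach(roi/ref).

    The first ``n_prebleach`` frames must precede the bleach; the output's
    pre-bleach mean is exactly 1.
    """
    if n_prebleach < 1:
        raise ValueError("n_prebleach must be >= 1")
    if len(roi.t) != len(ref.t) or not np.allclose(roi.t, ref.t):
        raise ValueError("roi and ref must share one time grid")
    if np.any(ref.y == 0):
        raise ValueError("reference trace contains zeros")
    ratio = roi.y / ref.y
    pre = ratio[:n_prebleach].mean()
    if pre == 0:
        raise ValueError("pre-bleach mean is zero")
    return KineticTrace(t=roi.t, y=ratio / pre, units="normalized")


def solubility_fraction(a_supernatant: float, a_pellet: float,
                        denominator: str = "total") -> float:
    """Percent of protein remaining soluble after centrifugation.

    ``total`` (default) reads the fraction of the total,
    100 * sup / (sup + pellet); ``pellet`` returns the plain sup/pellet
    ratio as a percentage for comparison with ratio-style readings.
    """
    if a_supernatant < 0 or a_pellet < 0:
        raise ValueError("absorbances must be nonnegative")
    if a_supernatant == 0 and a_pellet == 0:
        raise ZeroDivisionError("supernatant and pellet both zero: undefined ratio")
    if denominator == "total":
        return 100.0 * a_supernatant / (a_supernatant + a_pellet)
    if denominator == "pellet":
        if a_pellet == 0:
            return np.inf
        return 100.0 * a_supernatant / a_pellet
    raise ValueError(f"unknown denominator {denominator!r}")


@dataclass
class CalibrationLine:
    """OLS line through calibration points, optionally on log10(response)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    transform: str = "identity"
    n_points: int = 0

    def predict(self, x):
        """Response expected at x (back-transformed for log10_response)."""
        val = self.slope * np.asarray(x, dtype=float) + self.intercept
        return 10.0 ** val if self.transform == "log10_response" else val

    def invert(self, response):
        """x that would produce the observed response."""
        r = np.asarray(response, dtype=float)
        val = np.log10(r) if self.transform == "log10_response" else r
        return (val - self.intercept) / self.slope


def fit_calibration(x, response, transform: str = "identity") -> CalibrationLine:
    """Ordinary least squares on (x, response) or (x, log10 response).

    Used for fluorescence standard curves (band intensity vs amount) and
    size-exclusion Mw calibrations (log Mw vs retention time).
    """
    x = np.asarray(x, dtype=np.float64)
    resp = np.asarray(response, dtype=np.float64)
    if len(x) != len(resp) or len(x) < 2:
        raise ValueError("need >= 2 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("calibration x values are degenerate (all equal)")
    if transform == "log10_response":
        if np.any(resp <= 0):
            raise ValueError("responses must be positive for log10 transform")
        yv = np.log10(resp)
    elif transform == "identity":
        yv = resp
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if len(x) == 2:
        slope = (yv[1] - yv[0]) / (x[1] - x[0])
        intercept = yv[0] - slope * x[0]
        se_slope = se_intercept = 0.0
    else:
        fit = stats.linregress(x, yv)
        slope, intercept = fit.slope, fit.intercept
        se_slope, se_intercept = fit.stderr, fit.intercept_stderr
    return CalibrationLine(slope=slope, intercept=intercept, se_slope=se_slope,
                           se_intercept=se_intercept, transform=transform,
                           n_points=len(x))


def nuclear_concentration(amount_mol: float, n_cells: float,
                          transfection_eff: float = 0.8,
                          nuclear_volume_l: float = 2.2e-13) -> float:
    """Average nuclear concentration (mol/L) of an expressed protein.

    Divides the total amount by the number of expressing nuclei
    (``n_cells * transfection_eff``) times the nuclear volume (220 fl
    default)."""
    if amount_mol <= 0 or n_cells <= 0 or nuclear_volume_l <= 0:
        raise ValueError("amount, cell count and volume must be positive")
    if not (0 < transfection_eff <= 1):
        raise ValueError("transfection_eff must be in (0, 1]")
    return amount_mol / (n_cells * transfection_eff * nuclear_volume_l)


def read_trace_tsv(path) -> KineticTrace:
    df = pd.read_csv(path, sep="\t")
    y_ref = df["y_ref"].to_numpy() if "y_ref" in df.columns else None
    return KineticTrace(t=df["t"].to_numpy(), y=df["y"].to_numpy(), y_ref=y_ref)


def write_trace_tsv(trace: KineticTrace, path) -> None:
    data = {"t": trace.t, "y": trace.y}
    if trace.y_ref is not None:
        data["y_ref"] = trace.y_ref
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
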