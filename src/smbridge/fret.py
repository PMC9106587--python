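"""PIE-gated single-molecule FRET: binning, intensity corrections, histogram
Gaussian fits, and denaturant titration profiles.

FRET efficiency per selected bin is

    E = I_A / (I_A + gamma * I_D),     gamma = 1 by default,

where the acceptor intensity has been corrected for donor bleed-through
(fraction ``l`` of I_D) and acceptor direct excitation (fraction ``d`` of the
acceptor-gate intensity I_AA):  I_A = I_A_raw - l*I_D - d*I_AA.  Negative
corrected intensities are retained (the histogram domain extends to -0.2) so
the shot-noise shape of the zero peak survives.  Peaks are fitted
phenomenologically with Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .errors import EmptyInputError
from .streams import PhotonStream

__all__ = [
    "FretBinSeries",
    "FretHistogram",
    "DenaturationProfile",
    "gate_and_bin",
    "fret_histogram",
    "denaturation_profile",
]

E_DOMAIN = (-0.2, 1.2)
DEFAULT_N_EDGES = 71


@dataclass
class FretBinSeries:
    """Per-bin donor/acceptor counts by PIE gate, with a selection mask.

    I_D: donor channel under donor excitation; I_A_raw: acceptor channel under
    donor excitation (uncorrected); I_AA: acceptor channel under acceptor
    excitation (used as the direct-excitation reference).
    """

    bin_time: float
    I_D: np.ndarray
    I_A_raw: np.ndarray
    I_AA: np.ndarray
    selected: np.ndarray

    def __post_init__(self):
        for name in ("I_D", "I_A_raw", "I_AA"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, arr)
        self.selected = np.asarray(self.selected, dtype=bool)
        n = len(self.I_D)
        if not (len(self.I_A_raw) == len(self.I_AA) == len(self.selected) == n):
            raise ValueError("per-bin arrays must have equal length")


def gate_and_bin(stream: PhotonStream, bin_time: float = 5e-4,
                 threshold: float | None = None) -> FretBinSeries:
    """Bin a PIE-tagged stream (500 µs default) and mark signal-rich bins.

    Bins with total donor-excitation counts (I_D + I_A_raw) at or above the
    threshold are selected; the default threshold is mean + 3 sd of the
    per-bin totals, standing in for an instrument's "optimal signal" gate.
    """
    if len(stream) == 0:
        raise EmptyInputError("photon stream is empty")
    I_D = stream.counts(bin_time, channel="D", gate="Dex")
    I_A_raw = stream.counts(bin_time, channel="A", gate="Dex")
    I_AA = stream.counts(bin_time, channel="A", gate="Aex")
    total = I_D + I_A_raw
    if threshold is None:
        threshold = total.mean() + 3.0 * total.std()
    selected = total >= threshold
    return FretBinSeries(bin_time=bin_time, I_D=I_D, I_A_raw=I_A_raw,
                         I_AA=I_AA, selected=selected)


@dataclass
class FretHistogram:
    """FRET-efficiency histogram with optional Gaussian peak decomposition.

    ``gaussians`` holds (mean, sd, amplitude) per fitted component, sorted by
    mean; ``gaussian_se`` the matching standard errors.
    """

    efret_edges: np.ndarray
    counts: np.ndarray
    n_events: int
    gaussians: list = field(default_factory=list)
    gaussian_se: list = field(default_factory=list)
    fit_ok: bool = True
    fit_message: str = ""

    def __post_init__(self):
        self.efret_edges = np.asarray(self.efret_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.n_events:
            raise ValueError("histogram counts must sum to n_events")
        for (_, sd, _) in self.gaussians:
            if sd <= 0:
                raise ValueError("Gaussian components need positive sd")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.efret_edges[:-1] + self.efret_edges[1:])

    def peak_areas(self) -> list[float]:
        """Area (event count) under each fitted Gaussian component."""
        return [amp * sd * np.sqrt(2 * np.pi) for (_, sd, amp) in self.gaussians]

    def main_peak(self, min_mean: float = 0.05):
        """Largest-area component with mean above ``min_mean`` (the FRET
        peak, as opposed to the donor-only zero peak); falls back to the
        largest component."""
        if not self.gaussians:
            return None
        areas = self.peak_areas()
        cands = [i for i, (m, _, _) in enumerate(self.gaussians) if m > min_mean]
        if not cands:
            cands = range(len(self.gaussians))
        return self.gaussians[max(cands, key=lambda i: areas[i])]


def efret_values(bins: FretBinSeries, l: float = 0.03, d: float = 0.01,
                 gamma: float = 1.0) -> np.ndarray:
    """Corrected per-selected-bin FRET efficiencies."""
    sel = bins.selected
    if not np.any(sel):
        raise EmptyInputError("no selected bins")
    I_D = bins.I_D[sel].astype(float)
    I_A = bins.I_A_raw[sel] - l * bins.I_D[sel] - d * bins.I_AA[sel]
    denom = I_A + gamma * I_D
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom != 0, I_A / denom, 0.0)
    return e


def _find_modes(centers, counts, n_modes):
    """Initial Gaussian means: the n_modes highest well-separated histogram
    bins (ties broken lowest-E first)."""
    smooth = np.convolve(counts.astype(float), np.ones(3) / 3, mode="same")
    order = np.argsort(-smooth, kind="stable")
    means = []
    for idx in order:
        c = centers[idx]
        if all(abs(c - m) > 0.08 for m in means):
            means.append(c)
        if len(means) == n_modes:
            break
    while len(means) < n_modes:
        means.append(centers[len(centers) // (n_modes + 1) * (len(means) + 1)])
    return sorted(means)


def fret_histogram(bins: FretBinSeries, l: float = 0.03, d: float = 0.01,
                   gamma: float = 1.0, n_gauss: int = 1,
                   edges: np.ndarray | None = None,
                   init_means: list[float] | None = None) -> FretHistogram:
    """Histogram corrected FRET efficiencies and fit Gaussian peaks.

    Efficiencies outside the [-0.2, 1.2] domain are clipped into the edge
    bins so every selected bin contributes one event.  ``n_gauss`` Gaussians
    (1-3) are fitted by nonlinear least squares with mode-found initial
    means; on non-convergence the raw histogram is returned with
    ``fit_ok=False``.
    """
    if not (1 <= n_gauss <= 3):
        raise ValueError("n_gauss must be between 1 and 3")
    e = efret_values(bins, l=l, d=d, gamma=gamma)
    if edges is None:
        edges = np.linspace(E_DOMAIN[0], E_DOMAIN[1], DEFAULT_N_EDGES)
    eps = 1e-9
    e_clip = np.clip(e, edges[0] + eps, edges[-1] - eps)
    counts, _ = np.histogram(e_clip, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    params = lmfit.Parameters()
    if init_means is not None:
        if len(init_means) != n_gauss:
            raise ValueError("init_means must supply one mean per component")
        means0 = sorted(init_means)
    else:
        means0 = _find_modes(centers, counts, n_gauss)
    width0 = 0.05
    for i, m0 in enumerate(means0):
        amp0 = max(counts[np.argmin(np.abs(centers - m0))], 1)
        params.add(f"amp{i}", value=float(amp0), min=0)
        params.add(f"mu{i}", value=m0, min=edges[0], max=edges[-1])
        params.add(f"sd{i}", value=width0, min=1e-3, max=1.0)

    def model(p):
        out = np.zeros_like(centers)
        for i in range(n_gauss):
            out += p[f"amp{i}"] * np.exp(-0.5 * ((centers - p[f"mu{i}"])
                                                 / p[f"sd{i}"]) ** 2)
        return out

    def resid(p):
        v = {k: p[k].value for k in p}
        return model(v) - counts

    hist = FretHistogram(efret_edges=edges, counts=counts, n_events=int(counts.sum()))
    try:
        res = lmfit.minimize(resid, params, method="least_squares",
                             max_nfev=100_000)
        if not res.success:
            raise RuntimeError(res.message)
    except Exception as exc:  # raw histogram survives a failed peak fit
        hist.fit_ok = False
        hist.fit_message = str(exc)
        return hist
    comps = []
    ses = []
    for i in range(n_gauss):
        p = res.params
        comps.append((p[f"mu{i}"].value, p[f"sd{i}"].value, p[f"amp{i}"].value))
        ses.append((p[f"mu{i}"].stderr or np.nan, p[f"sd{i}"].stderr or np.nan,
                    p[f"amp{i}"].stderr or np.nan))
    order = np.argsort([c[0] for c in comps])
    hist.gaussians = [comps[i] for i in order]
    hist.gaussian_se = [ses[i] for i in order]
    return hist


@dataclass
class DenaturationProfile:
    """Fitted FRET-peak position versus denaturant concentration.

    ``cooperativity_metric`` is the fitted sigmoid transition slope with a
    95% CI; a non-cooperative transition corresponds to a slope CI that
    includes 0, or to the linear drift model being preferred by AIC.
    """

    denaturant_conc: np.ndarray
    efret: np.ndarray
    efret_se: np.ndarray
    cooperativity_metric: float
    cooperativity_ci: tuple[float, float]
    midpoint: float = np.nan
    midpoint_se: float = np.nan
    preferred_model: str = "linear"
    aic_linear: float = np.nan
    aic_sigmoid: float = np.nan

    @property
    def non_cooperative(self) -> bool:
        lo, hi = self.cooperativity_ci
        return self.preferred_model == "linear" or (lo <= 0 <= hi)


def denaturation_profile(histograms: list[FretHistogram],
                         concs) -> DenaturationProfile:
    """Track the FRET peak across a chemical denaturant series.

    Extracts the main FRET-peak mean from each histogram, then fits both a
    linear drift and a two-state sigmoid
    ``E(c) = E_f + (E_u - E_f) / (1 + exp(-k (c - c_mid)))`` and compares
    them by AIC.
    """
    concs = np.asarray(concs, dtype=np.float64)
    if len(histograms) != len(concs):
        raise ValueError("one histogram per concentration required")
    if len(concs) < 4:
        raise ValueError("need at least 4 denaturant concentrations")
    if np.any(concs < 0) or np.any(np.diff(concs) < 0):
        raise ValueError("concentrations must be nonnegative and sorted")
    efret = np.empty(len(concs))
    ese = np.empty(len(concs))
    for i, h in enumerate(histograms):
        peak = h.main_peak()
        if peak is None:
            raise ValueError(f"histogram {i} has no fitted peak")
        efret[i] = peak[0]
        idx = h.gaussians.index(peak)
        ese[i] = h.gaussian_se[idx][0] if h.gaussian_se else np.nan
    ese = np.where(np.isfinite(ese) & (ese > 0), ese, 0.01)

    # linear drift model
    X = np.vstack([np.ones_like(concs), concs]).T
    coef, res_lin, *_ = np.linalg.lstsq(X, efret, rcond=None)
    rss_lin = float(((X @ coef - efret) ** 2).sum())
    n = len(concs)
    aic_lin = n * np.log(max(rss_lin, 1e-300) / n) + 2 * 2

    if np.ptp(efret) < 1e-12:  # degenerate flat profile
        return DenaturationProfile(concs, efret, ese, 0.0, (0.0, 0.0),
                                   preferred_model="linear",
                                   aic_linear=aic_lin, aic_sigmoid=np.inf)

    params = lmfit.Parameters()
    params.add("e_f", value=float(efret[0]))
    params.add("e_u", value=float(efret[-1]))
    params.add("k", value=1.0)
    params.add("c_mid", value=float(np.median(concs)),
               min=float(concs[0]) - 1.0, max=float(concs[-1]) + 1.0)

    def sigmoid(p):
        return p["e_f"] + (p["e_u"] - p["e_f"]) / (
            1.0 + np.exp(-p["k"] * (concs - p["c_mid"])))

    def resid(p):
        v = {k: p[k].value for k in p}
        return sigmoid(v) - efret

    res = lmfit.minimize(resid, params, method="least_squares")
    rss_sig = float((np.asarray(res.residual) ** 2).sum())
    aic_sig = n * np.log(max(rss_sig, 1e-300) / n) + 2 * 4
    k = res.params["k"].value
    k_se = res.params["k"].stderr
    if k_se is None or not np.isfinite(k_se):
        k_se = abs(k)  # unconstrained slope: CI spans zero
    ci = (k - 1.96 * k_se, k + 1.96 * k_se)
    preferred = "linear" if aic_lin <= aic_sig else "sigmoid"
    return DenaturationProfile(
        concs, efret, ese, cooperativity_metric=k, cooperativity_ci=ci,
        midpoint=res.params["c_mid"].value,
        midpoint_se=res.params["c_mid"].stderr or np.nan,
        preferred_model=preferred, aic_linear=aic_lin, aic_sigmoid=aic_sig)


def write_profile_tsv(profile: DenaturationProfile, path) -> None:
    pd.DataFrame({"conc_M": profile.denaturant_conc, "Efret": profile.efret,
                  "se": profile.efret_se}).to_csv(path, sep="\t", index=False)
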