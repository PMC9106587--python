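"""Photon-counting histograms and burst analysis.

The PCH of a spatially uniform detection profile is a compound double
Poisson: the number of molecules in the volume is Poisson with mean N̄, and
given N molecules the photon count in a bin is Poisson with mean N·ε, where
ε is the molecular brightness in counts per bin.  The histogram shape (in
particular its tail) encodes brightness and therefore oligomer size; a
mixture of brightnesses shows up as a long tail that a one-species fit
cannot reproduce, and is handled by segmental fitting.

Burst analysis rebins the stream coarsely (50 Hz by default) and histograms
each bin's count as an integer multiple of the record average, so rare
bright assemblies appear as mass at high multiples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EmptyInputError, FitFailureError
from .streams import PhotonStream

__all__ = [
    "PCHData",
    "PCHFit",
    "BurstHistogram",
    "pch_pmf",
    "build_and_fit_pch",
    "fit_pch",
    "burst_histogram",
]


def _truncation_n(n_bar: float) -> int:
    # tail mass beyond N_bar + 10 sqrt(N_bar) + 20 is < 1e-12
    return int(np.ceil(n_bar + 10.0 * np.sqrt(n_bar) + 20.0))


def pch_pmf(k, n_bar: float, eps: float) -> np.ndarray:
    """Compound double-Poisson photon-counting probability.

    P(k) = sum_N Poisson(N; N̄) Poisson(k; N ε), truncated where the
    occupancy tail mass is below 1e-12.  Normalizes to 1 within 1e-9, with
    mean N̄ε and variance N̄ε(1+ε).
    """
    k = np.atleast_1d(np.asarray(k))
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("k must be nonnegative integers")
    if n_bar <= 0:
        raise ValueError("n_bar must be positive")
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    if eps == 0:
        return np.where(k == 0, 1.0, 0.0)
    n_max = _truncation_n(n_bar)
    N = np.arange(n_max + 1)
    pN = stats.poisson.pmf(N, n_bar)
    pkN = stats.poisson.pmf(k[None, :], (N * eps)[:, None])  # N=0 row handles k=0
    return pN @ pkN


@dataclass
class PCHData:
    """Observed photon-count histogram at one bin time."""

    bin_time: float
    counts_hist: np.ndarray  # frequency of k = index
    total_bins: int

    def __post_init__(self):
        self.counts_hist = np.asarray(self.counts_hist, dtype=np.int64)
        if np.any(self.counts_hist < 0):
            raise ValueError("histogram frequencies must be nonnegative")
        if self.counts_hist.sum() != self.total_bins:
            raise ValueError("frequencies must sum to total_bins")


@dataclass
class PCHFit:
    """Maximum-likelihood PCH parameters: mean occupancy and brightness/bin."""

    n_bar: float
    eps_counts: float
    chi2_dof: float = np.nan
    segments: list = field(default_factory=list)  # (k_lo, k_hi, n_bar, eps)

    def __post_init__(self):
        if self.n_bar <= 0 or self.eps_counts <= 0:
            raise ValueError("n_bar and eps_counts must be positive")


def _ml_fit(hist: np.ndarray, k_lo: int = 0, k_hi: int | None = None):
    """Poisson/multinomial ML over histogram bins restricted to [k_lo, k_hi]."""
    k = np.arange(len(hist))
    if k_hi is None:
        k_hi = len(hist) - 1
    sel = (k >= k_lo) & (k <= k_hi) & (hist > 0)
    kk = k[sel]
    hh = hist[sel].astype(float)
    ntot = hh.sum()
    mean = (kk * hh).sum() / ntot
    var = ((kk - mean) ** 2 * hh).sum() / ntot
    eps0 = max(var / max(mean, 1e-12) - 1.0, 0.05)
    nbar0 = max(mean / eps0, 1e-3)

    krange = np.arange(k_lo, k_hi + 1)

    def nll(logp):
        n_bar, eps = np.exp(logp)
        pmf = pch_pmf(krange, n_bar, eps)
        norm = pmf.sum()
        if norm <= 0:
            return 1e30
        p = np.maximum(pmf[kk - k_lo] / norm, 1e-300)
        return -(hh * np.log(p)).sum()

    res = optimize.minimize(nll, np.log([nbar0, eps0]), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 2000})
    if not res.success:
        raise FitFailureError("PCH maximum-likelihood fit did not converge",
                              diagnostics=res)
    n_bar, eps = np.exp(res.x)
    return n_bar, eps


def _pearson_chi2(hist: np.ndarray, n_bar: float, eps: float) -> float:
    """Pearson chi^2/dof with expected-count pooling below 5."""
    total = hist.sum()
    kmax = len(hist) - 1
    pmf = pch_pmf(np.arange(kmax + 1), n_bar, eps)
    exp = total * pmf
    exp_tail = total * max(1.0 - pmf.sum(), 0.0)
    obs, expd = [], []
    acc_o = acc_e = 0.0
    for k in range(kmax + 1):
        acc_o += hist[k]
        acc_e += exp[k]
        if acc_e >= 5:
            obs.append(acc_o)
            expd.append(acc_e)
            acc_o = acc_e = 0.0
    obs.append(acc_o)
    expd.append(acc_e + exp_tail)
    obs = np.array(obs)
    expd = np.maximum(np.array(expd), 1e-12)
    chi2 = ((obs - expd) ** 2 / expd).sum()
    dof = max(len(obs) - 1 - 2, 1)
    return chi2 / dof


def default_breakpoint(hist: np.ndarray, n_bar: float, eps: float,
                       tail_prob: float = 1e-4) -> int | None:
    """k above which the head fit predicts cumulative tail mass < tail_prob."""
    kmax = len(hist) - 1
    pmf = pch_pmf(np.arange(kmax + 1), n_bar, eps)
    tail = 1.0 - np.cumsum(pmf)
    below = np.nonzero(tail < tail_prob)[0]
    if below.size == 0 or below[0] >= kmax:
        return None
    return int(below[0])


def fit_pch(data: PCHData, model: str = "single",
            breakpoints: list[int] | None = None) -> PCHFit:
    """Fit the uniform-brightness compound-Poisson model to a histogram.

    ``single`` fits one (N̄, ε) pair by Poisson maximum likelihood.
    ``segmental`` additionally partitions the k-range (at user breakpoints,
    or at the point where the head fit's predicted tail mass drops below
    1e-4) and refits each segment, reporting per-segment brightness as an
    oligomer-size proxy.
    """
    hist = data.counts_hist
    if hist.sum() == 0 or (len(hist) > 0 and hist[1:].sum() == 0):
        raise EmptyInputError("histogram has no nonzero photon counts")
    n_bar, eps = _ml_fit(hist)
    chi2 = _pearson_chi2(hist, n_bar, eps)
    fit = PCHFit(n_bar=n_bar, eps_counts=eps, chi2_dof=chi2)
    if model == "single":
        return fit
    if model != "segmental":
        raise ValueError(f"unknown model {model!r}")
    if breakpoints is None:
        bp = default_breakpoint(hist, n_bar, eps)
        breakpoints = [bp] if bp is not None else []
    edges = [0] + sorted(breakpoints) + [len(hist) - 1]
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hist[lo:hi + 1].sum() == 0 or (hist[lo:hi + 1] > 0).sum() < 3:
            continue
        try:
            nb, ep = _ml_fit(hist, k_lo=lo, k_hi=hi)
        except FitFailureError:
            continue
        segments.append((lo, hi, nb, ep))
    fit.segments = segments
    return fit


def build_and_fit_pch(stream: PhotonStream, bin_time: float = 5e-4,
                      model: str = "single",
                      breakpoints: list[int] | None = None,
                      min_bins: int = 10_000) -> tuple[PCHData, PCHFit]:
    """Bin a photon stream (2 kHz default), histogram the counts and fit."""
    counts = stream.counts(bin_time)
    if len(counts) < min_bins:
        raise ValueError(f"need >= {min_bins} bins; got {len(counts)}")
    hist = np.bincount(counts)
    data = PCHData(bin_time=bin_time, counts_hist=hist, total_bins=len(counts))
    return data, fit_pch(data, model=model, breakpoints=breakpoints)


@dataclass
class BurstHistogram:
    """Histogram of bin counts expressed as multiples of the record average."""

    bin_time: float
    mean_rate: float
    multiples_hist: np.ndarray

    def __post_init__(self):
        self.multiples_hist = np.asarray(self.multiples_hist, dtype=np.int64)
        if np.any(self.multiples_hist < 0):
            raise ValueError("frequencies must be nonnegative")


def burst_histogram(stream: PhotonStream, bin_time: float = 0.02) -> BurstHistogram:
    """Bin at 50 Hz (default) and histogram round(count / mean count).

    Ties round half up.  Raises :class:`EmptyInputError` on an empty stream.
    """
    if len(stream) == 0:
        raise EmptyInputError("photon stream is empty")
    counts = stream.counts(bin_time)
    mean = counts.mean()
    if mean == 0:
        raise EmptyInputError("no photons after binning")
    multiples = np.floor(counts / mean + 0.5).astype(np.int64)
    hist = np.bincount(multiples)
    return BurstHistogram(bin_time=bin_time,
                          mean_rate=float(counts.sum() / stream.duration),
                          multiples_hist=hist)


def write_histogram_tsv(hist: np.ndarray, path, label: str = "k") -> None:
    pd.DataFrame({label: np.arange(len(hist)), "frequency": hist}).to_csv(
        path, sep="\t", index=False)
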