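"""Contact-matrix analytics: balancing, distance decay, compartments, domain
insulation, binding-site classification and pairwise binding-site contact
aggregation.

The aggregation operation is the centrepiece: for every intra-chromosomal
pair of transcription-factor binding-site bins (a, b) it extracts the
contact submatrix around (a, b), normalizes it by the mean of the 400
(20 x 20 at defaults) background bin-bin contacts formed by sliding 25-kb
windows +/-250 kb along each side of both anchors, and averages the result
over all pairs — the paired-site analogue of aggregate peak analysis, with
the sliding-window background acting as an internal normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import EmptyInputError, FitFailureError
from .genome import ContactMatrix, IntervalSet

__all__ = [
    "Track",
    "AggregateGrid",
    "SiteClasses",
    "ice_normalize",
    "ps_curve",
    "fit_ps_slope",
    "compartment_e1",
    "insulation_tads",
    "classify_sites",
    "cluster_filter",
    "pairwise_aggregate",
    "pair_fold_change",
    "paired_center_score_test",
]


@dataclass
class Track:
    """Per-bin scalar values aligned to a matrix binning; NaN marks masked bins."""

    chrom: str
    resolution: int
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


# ---------------------------------------------------------------------------
# balancing

def ice_normalize(m: ContactMatrix, max_iter: int = 200,
                  tol: float = 1e-4) -> ContactMatrix:
    """Iterative correction: equalize unmasked row sums.

    Iterates until the coefficient of variation of unmasked marginals drops
    below ``tol`` or ``max_iter`` is reached (then the result carries
    ``meta['converged']=False`` instead of raising).  Returns a new balanced
    matrix with bias vector satisfying balanced = raw / outer(bias, bias),
    scaled so unmasked marginals average 1.
    """
    raw = m.matrix
    mask = raw.sum(axis=0) > 0
    if not mask.any():
        raise EmptyInputError("contact matrix is all zero")
    work = raw[np.ix_(mask, mask)].astype(float)
    bias_m = np.ones(work.shape[0])
    converged = False
    for _ in range(max_iter):
        s = work.sum(axis=0)
        cv = s.std() / s.mean()
        if cv < tol:
            converged = True
            break
        s_norm = s / s.mean()
        work /= np.outer(s_norm, s_norm)
        bias_m *= s_norm
    # rescale so the balanced matrix has unit mean marginal
    total = work.sum(axis=0).mean()
    work /= total
    bias_m *= np.sqrt(total)
    balanced = np.full_like(raw, np.nan, dtype=float)
    balanced[np.ix_(mask, mask)] = work
    bias = np.full(raw.shape[0], np.nan)
    bias[mask] = bias_m
    out = ContactMatrix(chrom=m.chrom, resolution=m.resolution,
                        matrix=np.nan_to_num(balanced), balanced=True,
                        bias=bias)
    out.meta["converged"] = converged
    out.meta["mask"] = mask
    return out


def _usable_mask(m: ContactMatrix) -> np.ndarray:
    if "mask" in m.meta:
        return m.meta["mask"]
    return m.matrix.sum(axis=0) > 0


# ---------------------------------------------------------------------------
# distance decay

def ps_curve(m: ContactMatrix, bins_per_decade: int = 8):
    """Contact probability versus genomic distance on log-spaced bands.

    Returns (band centre distances in bp, P values) with P normalized so
    that the band-width-weighted sum equals 1.
    """
    n = m.n_bins
    if n < 2:
        raise ValueError("matrix must have at least 2 bins")
    mask = _usable_mask(m)
    mat = m.matrix
    # per-distance mean over unmasked bin pairs
    means = np.full(n, np.nan)
    mm = np.outer(mask, mask)
    for s in range(1, n):
        d = np.diagonal(mat, offset=s)
        v = np.diagonal(mm, offset=s)
        if v.any():
            means[s] = d[v].mean()
    res = m.resolution
    edges = [res]
    while edges[-1] < n * res:
        edges.append(edges[-1] * 10 ** (1.0 / bins_per_decade))
    edges = np.array(edges)
    centers, P, widths = [], [], []
    dist = np.arange(1, n) * res
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi) & np.isfinite(means[1:])
        if not sel.any():
            continue
        centers.append(np.sqrt(lo * hi))
        P.append(means[1:][sel].mean())
        widths.append(hi - lo)
    centers = np.array(centers)
    P = np.array(P)
    widths = np.array(widths)
    norm = (P * widths).sum()
    return centers, P / norm


def fit_ps_slope(s: np.ndarray, P: np.ndarray,
                 s_range: tuple[float, float] | None = None) -> float:
    """Log–log slope of a P(s) curve, optionally over one distance range."""
    sel = (P > 0) & (s > 0)
    if s_range is not None:
        sel &= (s >= s_range[0]) & (s <= s_range[1])
    slope, *_ = sps.linregress(np.log10(s[sel]), np.log10(P[sel]))
    return float(slope)


# ---------------------------------------------------------------------------
# compartments

def _expected_by_distance(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    exp = np.ones(n)
    mm = np.outer(mask, mask)
    for s in range(n):
        d = np.diagonal(mat, offset=s)
        v = np.diagonal(mm, offset=s)
        exp[s] = d[v].mean() if v.any() else np.nan
    return exp


def oe_matrix(m: ContactMatrix) -> np.ndarray:
    """Observed/expected with per-distance means as the expected model;
    masked bins are NaN."""
    mask = _usable_mask(m)
    mat = m.matrix
    exp = _expected_by_distance(mat, mask)
    n = m.n_bins
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = mat / exp[idx]
    oe[~np.outer(mask, mask)] = np.nan
    return oe


def _boxcar_smooth(oe: np.ndarray, half: int) -> np.ndarray:
    """NaN-aware 2D boxcar of full width 2*half+1 (sliding-window O/E)."""
    if half == 0:
        return oe
    n = oe.shape[0]
    filled = np.nan_to_num(oe)
    valid = np.isfinite(oe).astype(float)
    # separable box filter via cumulative sums
    def box1d(a):
        c = np.cumsum(a, axis=0)
        c = np.vstack([np.zeros((1, a.shape[1])), c])
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        return c[hi] - c[lo]
    num = box1d(box1d(filled).T).T
    den = box1d(box1d(valid).T).T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~np.isfinite(oe)] = np.nan
    return out


def compartment_e1(m: ContactMatrix, window: int = 100_000, step: int = 20_000,
                   orient_track: Track | np.ndarray | None = None,
                   n_quantiles: int = 10):
    """First principal component of the O/E correlation matrix plus a saddle.

    The observed/expected matrix is smoothed with a sliding window of
    ``window`` bp advanced by ``step`` bp (at a 20-kb binning the defaults
    reproduce a 100-kb window, 20-kb step scan), converted to a Pearson
    correlation matrix, and decomposed; E1 is sign-oriented to correlate
    positively with ``orient_track`` (planted labels for synthetic maps, a
    GC-like reference for real ones).  The saddle averages O/E over E1
    quantile pairs.  Returns (Track, saddle grid, variance_explained).
    """
    mask = _usable_mask(m)
    if mask.sum() < 50:
        raise ValueError("need >= 50 usable bins for compartment analysis")
    oe = oe_matrix(m)
    half = max(int(round(window / m.resolution)) // 2, 0)
    if step != m.resolution:
        # the scan step equals the binning here; other steps would resample
        half = max(int(round(window / (2 * step))), 0)
    oe_s = _boxcar_smooth(oe, half)
    sub = oe_s[np.ix_(mask, mask)]
    sub = np.nan_to_num(sub, nan=1.0)
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)  # constant rows correlate with nothing
    if not np.all(np.isfinite(corr)):
        raise FitFailureError("degenerate correlation matrix")
    vals, vecs = np.linalg.eigh(corr)
    e1 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    var_explained = float(vals[-1] / vals.sum())
    full = np.full(m.n_bins, np.nan)
    full[mask] = e1
    if orient_track is not None:
        ref = orient_track.values if isinstance(orient_track, Track) else \
            np.asarray(orient_track, dtype=float)
        sel = np.isfinite(full) & np.isfinite(ref)
        if sel.any() and np.corrcoef(full[sel], ref[sel])[0, 1] < 0:
            full = -full
    # saddle over E1 quantiles of the (unsmoothed) O/E
    finite = np.isfinite(full)
    ranks = sps.rankdata(full[finite])
    q = np.minimum(((ranks - 1) / len(ranks) * n_quantiles).astype(int),
                   n_quantiles - 1)
    qfull = np.full(m.n_bins, -1)
    qfull[finite] = q
    saddle = np.full((n_quantiles, n_quantiles), np.nan)
    for i in range(n_quantiles):
        bi = qfull == i
        for j in range(n_quantiles):
            bj = qfull == j
            block = oe[np.ix_(bi, bj)]
            if np.isfinite(block).any():
                saddle[i, j] = np.nanmean(block)
    track = Track(chrom=m.chrom, resolution=m.resolution, values=full, name="E1")
    return track, saddle, var_explained


# ---------------------------------------------------------------------------
# insulation / domains

def insulation_tads(m: ContactMatrix, square: int = 1_000_000,
                    delta_window: int = 200_000,
                    boundary_strength: float = 0.1):
    """Diagonal-square insulation score, boundary calls, and aggregate
    domain strength.

    The insulation of bin i is the mean contact in the square spanning the
    ``square``-bp windows immediately upstream and downstream of i,
    log2-normalized to the chromosome mean.  Boundaries sit where the delta
    (mean insulation over ``delta_window`` to the left minus to the right)
    crosses from positive to negative with prominence above
    ``boundary_strength``.  Aggregate strength is mean within-domain O/E
    divided by mean between-adjacent-domain O/E over the called domains.
    Returns (insulation Track, boundary IntervalSet, aggregate_tad_strength).
    """
    n = m.n_bins
    w = max(int(round(square / m.resolution)), 1)
    d = max(int(round(delta_window / m.resolution)), 1)
    if n <= 2 * w:
        raise ValueError("matrix span must exceed twice the insulation square")
    mat = m.matrix.astype(float)
    mask = _usable_mask(m)
    mat[~np.outer(mask, mask)] = np.nan
    # prefix sums for O(1) square means
    filled = np.nan_to_num(mat)
    valid = np.isfinite(mat).astype(float)
    cs = np.zeros((n + 1, n + 1))
    cs[1:, 1:] = filled.cumsum(0).cumsum(1)
    cv = np.zeros((n + 1, n + 1))
    cv[1:, 1:] = valid.cumsum(0).cumsum(1)

    def square_mean(r0, r1, c0, c1):
        s = cs[r1, c1] - cs[r0, c1] - cs[r1, c0] + cs[r0, c0]
        v = cv[r1, c1] - cv[r0, c1] - cv[r1, c0] + cv[r0, c0]
        return s / v if v > 0 else np.nan

    ins_raw = np.full(n, np.nan)
    for i in range(w, n - w):
        ins_raw[i] = square_mean(i - w, i, i + 1, i + w + 1)
    finite = np.isfinite(ins_raw) & (ins_raw > 0)
    if not finite.any():
        raise ValueError("no usable insulation scores")
    chrom_mean = ins_raw[finite].mean()
    ins = np.full(n, np.nan)
    ins[finite] = np.log2(ins_raw[finite] / chrom_mean)

    delta = np.full(n, np.nan)
    for i in range(d, n - d):
        left = ins[i - d:i]
        right = ins[i + 1:i + 1 + d]
        if np.isfinite(left).any() and np.isfinite(right).any():
            delta[i] = np.nanmean(left) - np.nanmean(right)

    boundaries = []
    for i in range(1, n - 1):
        if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
            continue
        if delta[i] > 0 >= delta[i + 1]:
            lo = max(i - d, 0)
            hi = min(i + 1 + d, n)
            strength = np.nanmax(delta[lo:i + 1]) - np.nanmin(delta[i + 1:hi])
            if strength >= boundary_strength:
                cand = [j for j in (i, i + 1) if np.isfinite(ins[j])]
                if cand:
                    boundaries.append(min(cand, key=lambda j: ins[j]))
    boundaries = sorted(set(boundaries))
    res = m.resolution
    bset = IntervalSet(
        np.array([m.chrom] * len(boundaries), dtype=object),
        np.array([b * res for b in boundaries], dtype=np.int64),
        np.array([(b + 1) * res for b in boundaries], dtype=np.int64),
    ) if boundaries else IntervalSet.from_records([])

    strength = np.nan
    edges = [0] + boundaries + [n]
    tads = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b - a >= 2]
    if len(tads) >= 2:
        oe = oe_matrix(m)
        within, between = [], []
        for a, b in tads:
            block = oe[a:b, a:b]
            iu = np.triu_indices(b - a, k=1)
            within.extend(block[iu][np.isfinite(block[iu])])
        for (a1, b1), (a2, b2) in zip(tads[:-1], tads[1:]):
            block = oe[a1:b1, a2:b2]
            between.extend(block[np.isfinite(block)])
        if within and between:
            strength = float(np.mean(within) / np.mean(between))
    track = Track(chrom=m.chrom, resolution=res, values=ins, name="insulation")
    return track, bset, strength


# ---------------------------------------------------------------------------
# binding-site classification

@dataclass
class SiteClasses:
    """Partition of two peak sets by the >=1-bp overlap rule.

    ``shared`` holds the a-peaks that overlap any b-peak (so
    |a_only| + |shared| = |peaks_a|); ``shared_b`` is the b-side mirror.
    """

    a_only: IntervalSet
    shared: IntervalSet
    b_only: IntervalSet
    shared_b: IntervalSet


def _overlaps_any(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query boolean: overlaps (half-open, >=1 bp) any subject interval."""
    out = np.zeros(len(query), dtype=bool)
    for chrom in np.unique(query.chroms.astype(str)):
        qsel = np.nonzero(query.chroms.astype(str) == chrom)[0]
        ssel = subject.chroms.astype(str) == chrom
        if not ssel.any():
            continue
        s_starts = subject.starts[ssel]
        s_ends = subject.ends[ssel]
        # sweep: for each query, any subject with start < q.end and end > q.start
        order = np.argsort(s_starts)
        s_starts = s_starts[order]
        s_ends = s_ends[order]
        cummax_end = np.maximum.accumulate(s_ends)
        for qi in qsel:
            qs, qe = query.starts[qi], query.ends[qi]
            k = np.searchsorted(s_starts, qe, side="left")  # starts < qe
            if k > 0 and cummax_end[k - 1] > qs:
                out[qi] = True
    return out


def classify_sites(peaks_a: IntervalSet, peaks_b: IntervalSet) -> SiteClasses:
    """Split two peak sets into a-only / shared / b-only by 1-bp overlap.

    Overlap means a nonempty intersection of half-open intervals; adjacent
    intervals ([100,200) vs [200,300)) do not overlap.
    """
    a_hits = _overlaps_any(peaks_a, peaks_b)
    b_hits = _overlaps_any(peaks_b, peaks_a)
    return SiteClasses(
        a_only=peaks_a.subset(~a_hits),
        shared=peaks_a.subset(a_hits),
        b_only=peaks_b.subset(~b_hits),
        shared_b=peaks_b.subset(b_hits),
    )


def cluster_filter(peaks: IntervalSet, resolution: int = 25_000,
                   min_peaks: int = 2) -> IntervalSet:
    """Genome bins containing at least ``min_peaks`` peak midpoints
    (high-density binding clusters)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    records = []
    mid = (peaks.starts + peaks.ends) // 2
    bins = mid // resolution
    for chrom in np.unique(peaks.chroms.astype(str)):
        sel = peaks.chroms.astype(str) == chrom
        uniq, counts = np.unique(bins[sel], return_counts=True)
        for b, c in zip(uniq, counts):
            if c >= min_peaks:
                records.append((chrom, int(b) * resolution,
                                (int(b) + 1) * resolution))
    return IntervalSet.from_records(records)


# ---------------------------------------------------------------------------
# pairwise aggregation

@dataclass
class AggregateGrid:
    """Mean observed/background grid over anchor pairs.

    ``grid`` is (2F+1) x (2F+1) centred on the anchor-anchor contact;
    ``center_scores`` holds each pair's centre contact divided by its own
    mean background; ``background_pair_count`` the number of valid
    background cells per kept pair ((2F)^2 = 400 at defaults when no bin is
    masked).
    """

    grid: np.ndarray
    n_pairs: int
    center_scores: np.ndarray
    background_pair_count: np.ndarray
    n_dropped: int = 0
    pairs: list = field(default_factory=list)


def _anchor_bins(anchors: IntervalSet, chrom: str, resolution: int) -> np.ndarray:
    sel = anchors.chroms.astype(str) == chrom
    starts = anchors.starts[sel]
    if np.any(starts % resolution != 0):
        raise ValueError("anchors are not aligned to the matrix binning")
    return np.unique(starts // resolution)


def pairwise_aggregate(m: ContactMatrix, anchors: IntervalSet,
                       flank: int = 250_000, window: int = 25_000,
                       min_sep: int | None = None) -> AggregateGrid:
    """Aggregate contacts between all eligible intra-chromosomal anchor pairs.

    For each pair (a, b) with separation >= ``min_sep`` (default
    2*flank + 3*window, keeping the background windows clear of both
    anchors), the (2F+1)^2 submatrix around (a, b) is extracted
    (F = flank/window) and divided by the pair's mean background — the
    (2F)^2 contacts formed by the non-centre sliding windows on each side of
    a crossed with those of b.  Pairs with under 50% valid background cells
    are dropped and counted.
    """
    if flank % window != 0:
        raise ValueError("flank must be a multiple of window")
    if m.resolution != window:
        raise ValueError("matrix resolution must equal the scan window")
    F = flank // window
    if min_sep is None:
        min_sep = 2 * flank + 3 * window
    if min_sep <= 2 * flank + window:
        raise ValueError("min_sep must exceed 2*flank + window to keep "
                         "background windows off the anchors")
    bins = _anchor_bins(anchors, m.chrom, m.resolution)
    n = m.n_bins
    mask = _usable_mask(m)
    mat = m.matrix.astype(float)
    mat[~np.outer(mask, mask)] = np.nan
    off = np.arange(-F, F + 1)
    bg_sel = np.ones((2 * F + 1, 2 * F + 1), dtype=bool)
    bg_sel[F, :] = False
    bg_sel[:, F] = False

    grids, scores, bgcounts, kept_pairs = [], [], [], []
    dropped = 0
    min_sep_bins = min_sep // m.resolution
    for ii in range(len(bins)):
        for jj in range(ii + 1, len(bins)):
            a, b = bins[ii], bins[jj]
            if b - a < min_sep_bins:
                continue
            if a - F < 0 or b + F >= n:
                continue
            sub = mat[np.ix_(a + off, b + off)]
            bg = sub[bg_sel]
            n_valid = int(np.isfinite(bg).sum())
            if n_valid < bg_sel.sum() / 2:
                dropped += 1
                continue
            bg_mean = np.nanmean(bg)
            if not np.isfinite(bg_mean) or bg_mean <= 0:
                dropped += 1
                continue
            grids.append(sub / bg_mean)
            scores.append(sub[F, F] / bg_mean)
            bgcounts.append(n_valid)
            kept_pairs.append((int(a), int(b)))
    if not grids:
        raise EmptyInputError(
            "no eligible anchor pairs (separation/edge constraints)")
    grid = np.nanmean(np.stack(grids), axis=0)
    return AggregateGrid(grid=grid, n_pairs=len(grids),
                         center_scores=np.array(scores),
                         background_pair_count=np.array(bgcounts),
                         n_dropped=dropped, pairs=kept_pairs)


# ---------------------------------------------------------------------------
# condition comparison

def pair_fold_change(m1: ContactMatrix, m2: ContactMatrix,
                     pairs: list[tuple[int, int]]) -> np.ndarray:
    """Per-pair log2 ratio of balanced contacts with a pseudocount.

    The pseudocount is half the smallest positive value in either matrix,
    so equal matrices give exactly 0 and doubling gives ~1 wherever the
    contacts dominate the pseudocount.
    """
    if m1.resolution != m2.resolution or m1.n_bins != m2.n_bins:
        raise ValueError("matrices must share binning")
    pos = np.concatenate([m1.matrix[m1.matrix > 0], m2.matrix[m2.matrix > 0]])
    if pos.size == 0:
        raise EmptyInputError("both matrices are empty")
    pc = pos.min() / 2.0
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        out[k] = np.log2((m1.matrix[i, j] + pc) / (m2.matrix[i, j] + pc))
    return out


def write_bedgraph(track: Track, path) -> None:
    """Export a per-bin track (E1, insulation, log2 FC) as bedGraph."""
    n = len(track.values)
    starts = np.arange(n) * track.resolution
    sel = np.isfinite(track.values)
    import pandas as pd
    pd.DataFrame({
        "chrom": track.chrom, "start": starts[sel],
        "end": starts[sel] + track.resolution, "value": track.values[sel],
    }).to_csv(path, sep="\t", header=False, index=False,
              float_format="%.6g")


def write_aggregate_grid(grid: AggregateGrid, grid_path,
                         scores_path=None) -> None:
    """Write the aggregation grid as a square matrix and, optionally, the
    per-pair centre scores as a two-column table."""
    np.savetxt(grid_path, grid.grid, delimiter="\t", fmt="%.6g")
    if scores_path is not None:
        import pandas as pd
        pd.DataFrame({
            "pair": [f"{a}-{b}" for a, b in grid.pairs],
            "center_score": grid.center_scores,
        }).to_csv(scores_path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PairedTestResult:
    statistic: float
    dof: int
    pvalue: float
    degenerate: bool = False


def paired_center_score_test(scores1, scores2) -> PairedTestResult:
    """Two-sided paired Student's t-test on per-pair centre scores.

    Constant differences (zero variance) are flagged as degenerate instead
    of reporting an infinite statistic.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.size < 2:
        raise ValueError("need two equal-length score lists of size >= 2")
    diff = s1 - s2
    if np.allclose(diff, diff[0]):
        if np.allclose(diff, 0):
            return PairedTestResult(0.0, s1.size - 1, 1.0, degenerate=False)
        return PairedTestResult(np.nan, s1.size - 1, np.nan, degenerate=True)
    t, p = sps.ttest_rel(s1, s2)
    return PairedTestResult(float(t), s1.size - 1, float(p))
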