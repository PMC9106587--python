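"""Synthetic-data generators with known ground truth.

Three generators cover every input the analysis stages consume:

* :func:`simulate_photon_stream` — Brownian point emitters in a periodic box,
  detected through a 3D Gaussian observation volume under interleaved
  two-laser excitation, with donor bleed-through, acceptor direct excitation
  and uniform background.  Produces a tagged photon stream suitable for FCS,
  FCCS, PCH, burst and smFRET analysis.
* :func:`simulate_contact_map` — binned chromosome contact matrices with
  power-law distance decay, checkerboard compartments, block domains and
  planted anchor–anchor enrichment, Poisson-sampled to a target depth.
* :func:`simulate_kinetic_trace` — noisy single-exponential traces of the
  kind produced by amyloid-reporter (ThT) plate-reader assays and FRAP
  recovery measurements.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._rng import rand_poisson, rand_u01, seed_state
from .genome import ContactMatrix, IntervalSet
from .streams import PhotonStream

__all__ = [
    "OpticalConfig",
    "SpeciesSpec",
    "ContactMapSpec",
    "simulate_photon_stream",
    "simulate_contact_map",
    "simulate_kinetic_trace",
    "simulate_pch_stream",
    "observation_volume",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Confocal detection geometry and PIE bookkeeping.

    Parameters
    ----------
    w0, z0:
        Lateral beam waist and axial beam extent of the 3D Gaussian
        observation volume, in µm.  ``z0 >= w0``.
    pie_period:
        Excitation alternation period in ns (the two lasers are pulsed this
        far apart).  Kept for bookkeeping; the simulator assigns each photon
        the gate of the laser that produced it and omits ns lifetime
        structure.
    leak_frac:
        Donor fluorescence bleed-through fraction into the acceptor channel.
    direct_frac:
        Fraction of the donor-laser power that directly excites the acceptor.
    bg_rate:
        Uncorrelated background count rate per channel, counts/s.
    """

    w0: float = 0.3
    z0: float = 1.5
    pie_period: float = 25.0
    leak_frac: float = 0.03
    direct_frac: float = 0.01
    bg_rate: float = 0.0

    def __post_init__(self):
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.z0 < self.w0:
            raise ValueError("z0 must be >= w0")
        if not (0 <= self.leak_frac < 1):
            raise ValueError("leak_frac must be in [0, 1)")
        if not (0 <= self.direct_frac < 1):
            raise ValueError("direct_frac must be in [0, 1)")
        if self.bg_rate < 0:
            raise ValueError("bg_rate must be nonnegative")

    def default_box(self) -> tuple[float, float, float]:
        """Periodic box (8 w0, 8 w0, 4 z0): edge detection weight < 1e-13."""
        return (8 * self.w0, 8 * self.w0, 4 * self.z0)


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing emitter species.

    ``label_class`` is ``donor_only``, ``acceptor_only`` or ``dual`` (a
    double-labelled particle such as two bridged DNA duplexes).
    ``stoichiometry`` multiplies the per-fluorophore brightness ``eps``
    (counts/s at beam centre), so oligomers are brighter, not more numerous.
    ``efret`` sets the donor→acceptor transfer efficiency of dual species.
    """

    label_class: str
    conc: float
    D: float
    eps: float
    stoichiometry: int = 1
    efret: float = 0.0

    def __post_init__(self):
        if self.label_class not in ("donor_only", "acceptor_only", "dual"):
            raise ValueError(f"unknown label_class {self.label_class!r}")
        if self.stoichiometry < 1:
            raise ValueError("stoichiometry must be >= 1")
        if self.conc < 0:
            raise ValueError("conc must be nonnegative")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")
        if not (0 <= self.efret <= 1):
            raise ValueError("efret must be in [0, 1]")


def observation_volume(optics: OpticalConfig) -> float:
    """Integral of the detection weight over space, (π/2)^{3/2} w0² z0 (µm³)."""
    return (np.pi / 2.0) ** 1.5 * optics.w0 ** 2 * optics.z0


# photon categories: (channel, gate) codes; channel 0=D 1=A, gate 0=Dex 1=Aex
_CAT_D_DEX = (0, 0)
_CAT_A_DEX = (1, 0)
_CAT_A_AEX = (1, 1)


def _species_categories(s: SpeciesSpec, optics: OpticalConfig):
    """Per-category peak rates (counts/s at beam centre) for one species."""
    eps_tot = s.stoichiometry * s.eps
    leak, direct = optics.leak_frac, optics.direct_frac
    if s.label_class == "donor_only":
        cats = [(_CAT_D_DEX, (1 - leak) * eps_tot), (_CAT_A_DEX, leak * eps_tot)]
    elif s.label_class == "acceptor_only":
        cats = [(_CAT_A_AEX, eps_tot), (_CAT_A_DEX, direct * eps_tot)]
    else:  # dual: donor arm split by efret under Dex; acceptor arm under Aex
        e = s.efret
        cats = [
            (_CAT_D_DEX, (1 - e) * (1 - leak) * eps_tot),
            (_CAT_A_DEX, ((1 - e) * leak + e + direct) * eps_tot),
            (_CAT_A_AEX, eps_tot),
        ]
    return [(cg, rate) for cg, rate in cats if rate > 0]


@njit(cache=True, fastmath=True)
def _diffuse_and_count(n_steps, dt, sigma, bx, by, bz, iw2, iz2,
                       cat_rate_dt, pos0, state, counts):
    """Advance particles one Brownian step at a time and Poisson-draw photons.

    ``counts`` is an (n_cats, n_steps) int16 array filled in place with the
    photon count of each category in each step.  The detection weight is
    W = exp(-2(x²+y²)/w0² - 2z²/z0²); contributions with exponent > 25 are
    dropped (W < 2e-11).
    """
    n_part = pos0.shape[0]
    n_cats = cat_rate_dt.shape[0]
    x = pos0[:, 0].copy()
    y = pos0[:, 1].copy()
    z = pos0[:, 2].copy()
    # polar-method Gaussian with the spare kept in registers: the draw
    # sequence is identical to rand_gauss but avoids a scratch array in
    # the innermost loop
    have = False
    spare = 0.0
    g3 = np.empty(3)
    for t in range(n_steps):
        wsum = 0.0
        for i in range(n_part):
            for j in range(3):
                if have:
                    g3[j] = spare
                    have = False
                else:
                    while True:
                        u = 2.0 * rand_u01(state) - 1.0
                        v = 2.0 * rand_u01(state) - 1.0
                        r2 = u * u + v * v
                        if 0.0 < r2 < 1.0:
                            f = np.sqrt(-2.0 * np.log(r2) / r2)
                            spare = v * f
                            have = True
                            g3[j] = u * f
                            break
            xi = x[i] + sigma * g3[0]
            yi = y[i] + sigma * g3[1]
            zi = z[i] + sigma * g3[2]
            if xi > 0.5 * bx:
                xi -= bx
            elif xi < -0.5 * bx:
                xi += bx
            if yi > 0.5 * by:
                yi -= by
            elif yi < -0.5 * by:
                yi += by
            if zi > 0.5 * bz:
                zi -= bz
            elif zi < -0.5 * bz:
                zi += bz
            x[i] = xi
            y[i] = yi
            z[i] = zi
            arg = iw2 * (xi * xi + yi * yi) + iz2 * zi * zi
            if arg < 25.0:
                wsum += np.exp(-arg)
        if wsum > 0.0:
            for c in range(n_cats):
                counts[c, t] = rand_poisson(state, cat_rate_dt[c] * wsum)


@njit(cache=True)
def _uniform_positions(n_part, bx, by, bz, state):
    pos = np.empty((n_part, 3))
    for i in range(n_part):
        pos[i, 0] = (rand_u01(state) - 0.5) * bx
        pos[i, 1] = (rand_u01(state) - 0.5) * by
        pos[i, 2] = (rand_u01(state) - 0.5) * bz
    return pos


def simulate_photon_stream(
    species: list[SpeciesSpec],
    optics: OpticalConfig,
    duration: float,
    dt: float = 1e-5,
    box: tuple[float, float, float] | None = None,
    seed: int = 0,
    init_positions: dict[int, np.ndarray] | None = None,
) -> PhotonStream:
    """Simulate a tagged photon stream from diffusing emitters.

    Each species contributes ``round(conc * box volume)`` particles taking
    Brownian steps of s.d. sqrt(2 D dt) per axis in a periodic box.  Photons
    are drawn per step from a Poisson law with rate (category peak rate) ×
    W(position), then jittered uniformly within their step so the stream is
    usable at correlator lags finer than ``dt``.  Background counts arrive
    uniformly at ``optics.bg_rate`` per channel with random gates.

    ``init_positions`` optionally pins the starting positions of a species
    (mapping species index -> (n,3) array), e.g. a single particle at the
    beam centre for closed-form checks.
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    if duration == 0:
        return PhotonStream(np.empty(0), np.empty(0, np.uint8),
                            np.empty(0, np.uint8), 0.0)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if box is None:
        box = optics.default_box()
    bx, by, bz = box
    if bx < 4 * optics.w0 or by < 4 * optics.w0 or bz < 2 * optics.z0:
        raise ValueError(
            "box must be >= 4*w0 laterally and >= 2*z0 axially; smaller boxes "
            "bias the correlation amplitude")
    if not species and optics.bg_rate == 0:
        raise ValueError("need at least one species or a nonzero bg_rate")

    n_steps = int(np.round(duration / dt))
    volume = bx * by * bz
    ss = np.random.SeedSequence(seed)
    kernel_seeds = ss.generate_state(max(len(species), 1), np.uint64)
    rng = np.random.default_rng(ss.spawn(1)[0])
    iw2 = 2.0 / optics.w0 ** 2
    iz2 = 2.0 / optics.z0 ** 2

    all_times, all_chan, all_gate = [], [], []
    for k, s in enumerate(species):
        n_part = int(np.round(s.conc * volume))
        if n_part == 0:
            continue
        state = seed_state(int(kernel_seeds[k]))
        if init_positions is not None and k in init_positions:
            pos0 = np.array(init_positions[k], dtype=np.float64).reshape(-1, 3)
            if pos0.shape[0] != n_part:
                raise ValueError("init_positions must supply one row per particle")
        else:
            pos0 = _uniform_positions(n_part, bx, by, bz, state)
        cats = _species_categories(s, optics)
        cat_rate_dt = np.array([rate * dt for _, rate in cats])
        counts = np.zeros((len(cats), n_steps), dtype=np.int16)
        sigma = np.sqrt(2.0 * s.D * dt)
        _diffuse_and_count(n_steps, dt, sigma, bx, by, bz, iw2, iz2,
                           cat_rate_dt, pos0, state, counts)
        for c, ((chan, gate), _) in enumerate(cats):
            row = counts[c]
            nz = np.nonzero(row)[0]
            if nz.size == 0:
                continue
            reps = row[nz].astype(np.int64)
            steps = np.repeat(nz, reps)
            t = (steps + rng.random(steps.size)) * dt
            all_times.append(t)
            all_chan.append(np.full(t.size, chan, np.uint8))
            all_gate.append(np.full(t.size, gate, np.uint8))

    if optics.bg_rate > 0:
        for chan in (0, 1):
            n_bg = rng.poisson(optics.bg_rate * duration)
            t = rng.random(n_bg) * duration
            all_times.append(t)
            all_chan.append(np.full(n_bg, chan, np.uint8))
            all_gate.append(rng.integers(0, 2, size=n_bg).astype(np.uint8))

    if not all_times:
        return PhotonStream(np.empty(0), np.empty(0, np.uint8),
                            np.empty(0, np.uint8), duration)
    times = np.concatenate(all_times)
    chan = np.concatenate(all_chan)
    gate = np.concatenate(all_gate)
    order = np.argsort(times, kind="stable")
    times = np.minimum(times[order], duration)
    return PhotonStream(times, chan[order], gate[order], duration)


def simulate_pch_stream(n_bar: float, eps_per_bin: float, bin_time: float,
                        n_bins: int, seed: int = 0) -> PhotonStream:
    """Sample a stream whose per-bin counts follow the compound-Poisson
    photon-counting-histogram law: N ~ Poisson(n_bar) molecules per bin,
    k | N ~ Poisson(N * eps_per_bin) photons.  Occupancies are independent
    between bins (no diffusion memory); photons land uniformly in their bin,
    donor channel, Dex gate."""
    if n_bins <= 0 or bin_time <= 0:
        raise ValueError("n_bins and bin_time must be positive")
    rng = np.random.default_rng(seed)
    occupancy = rng.poisson(n_bar, size=n_bins)
    counts = rng.poisson(occupancy * eps_per_bin)
    nz = np.nonzero(counts)[0]
    steps = np.repeat(nz, counts[nz])
    times = (steps + rng.random(steps.size)) * bin_time
    times.sort()
    duration = n_bins * bin_time
    return PhotonStream(times, np.zeros(times.size, np.uint8),
                        np.zeros(times.size, np.uint8), duration)


@dataclass
class ContactMapSpec:
    """Recipe for a synthetic binned contact matrix on one chromosome.

    The expected (unbalanced) contact between bins i, j is proportional to
    ``max(|i-j|, 1) ** ps_exponent`` times a compartment factor
    (``compartment_fold`` when both bins carry the same ±1 label), a domain
    factor (``tad_fold`` when both bins lie in the same block between
    consecutive ``tad_boundaries``) and ``anchor_fold`` when both bins are
    planted anchors.  Counts are Poisson-sampled so the total is ``depth``
    in expectation.
    """

    chrom: str
    chrom_size: int
    resolution: int
    ps_exponent: float = -1.0
    compartment_track: np.ndarray | None = None
    tad_boundaries: list[int] = field(default_factory=list)
    anchor_bins: list[int] = field(default_factory=list)
    anchor_fold: float = 1.0
    compartment_fold: float = 1.5
    tad_fold: float = 2.0
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.anchor_fold < 1:
            raise ValueError("anchor_fold must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        n_bins = self.n_bins
        if any(b < 0 or b >= n_bins for b in self.anchor_bins):
            raise ValueError("anchor bins must lie within the chromosome extent")
        if self.compartment_track is not None:
            self.compartment_track = np.asarray(self.compartment_track)
            if self.compartment_track.shape != (n_bins,):
                raise ValueError("compartment_track must have one ±1 label per bin")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_size // self.resolution)


def simulate_contact_map(spec: ContactMapSpec) -> tuple[ContactMatrix, IntervalSet]:
    """Build the expected contact surface from the recipe and Poisson-sample it.

    Returns the symmetric integer contact matrix and the planted anchor bins
    as a BED-convention interval set.
    """
    n = spec.n_bins
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :])
    w = np.maximum(s, 1).astype(float) ** spec.ps_exponent
    if spec.compartment_track is not None:
        same = spec.compartment_track[:, None] == spec.compartment_track[None, :]
        w *= np.where(same, spec.compartment_fold, 1.0)
    if spec.tad_boundaries:
        edges = np.concatenate([[0], np.sort(spec.tad_boundaries), [n]])
        block = np.searchsorted(edges, idx, side="right")
        w *= np.where(block[:, None] == block[None, :], spec.tad_fold, 1.0)
    if spec.anchor_bins and spec.anchor_fold != 1.0:
        amask = np.zeros(n, dtype=bool)
        amask[list(spec.anchor_bins)] = True
        w *= np.where(amask[:, None] & amask[None, :], spec.anchor_fold, 1.0)
    lam_up = np.triu(w)
    lam_up *= spec.depth / lam_up.sum()  # depth = expected sampled pairs
    rng = np.random.default_rng(spec.seed)
    upper = rng.poisson(lam_up).astype(float)
    mat = np.triu(upper) + np.triu(upper, 1).T
    cm = ContactMatrix(chrom=spec.chrom, resolution=spec.resolution, matrix=mat)
    anchors = sorted(spec.anchor_bins)
    intervals = IntervalSet(
        np.array([spec.chrom] * len(anchors), dtype=object),
        np.array([b * spec.resolution for b in anchors], dtype=np.int64),
        np.array([min((b + 1) * spec.resolution, spec.chrom_size)
                  for b in anchors], dtype=np.int64),
    )
    return cm, intervals


def simulate_kinetic_trace(A: float, R: float, times, noise_sd: float = 0.0,
                           seed: int = 0):
    """Noisy single-exponential trace y = A·exp(R·t) + N(0, noise_sd²)."""
    from .kinetics import KineticTrace

    times = np.asarray(times, dtype=np.float64)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    y = A * np.exp(R * times)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=times.size)
    return KineticTrace(t=times, y=y)
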