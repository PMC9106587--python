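# Methods

This note documents the models implemented in `smbridge`, the synthetic-data
generators used to exercise them, the numerical choices that matter, and the
limits of what the tests demonstrate.

## Photon-stream simulator

`simulate_photon_stream` models point emitters undergoing free Brownian
motion in a periodic box, detected through a 3D Gaussian observation volume

    W(x, y, z) = exp(-2 (x² + y²) / w0² - 2 z² / z0²),

with lateral waist `w0` and axial extent `z0`.  Each species contributes
`round(conc × box volume)` particles; per time step `dt` every particle takes
an isotropic Gaussian step of per-axis s.d. `sqrt(2 D dt)` and the photon
count in each detection category is Poisson with mean
(category peak rate) × Σᵢ W(xᵢ).  Photon times are jittered uniformly within
their generating step so correlator lags finer than `dt` carry no comb
artifacts.  Brownian increments are exact for any `dt`; the only
discretization effect is that the intensity is piecewise constant over a
step, so analyses should use lags ≥ `dt`.  The default step, `1e-5` s, keeps
`dt` below the lateral diffusion time `w0²/4D` for everything up to
dye-like diffusion (430 µm²/s) at the default waist.

Pulsed interleaved excitation is represented by per-photon gate tags: Dex
for photons driven by the donor laser, Aex for the acceptor laser; both
lasers are treated as continuously interrogating (time-averaged rates), and
nanosecond lifetime structure is deliberately omitted.  Category rates per
species, with bleed-through `l` and direct excitation `d`:

| species       | D channel, Dex        | A channel, Dex                | A channel, Aex |
|---------------|-----------------------|-------------------------------|----------------|
| donor_only    | (1−l)·ε               | l·ε                           | —              |
| acceptor_only | —                     | d·ε                           | ε              |
| dual (E)      | (1−E)(1−l)·ε          | [(1−E)l + E + d]·ε            | ε              |

with ε = stoichiometry × per-fluorophore brightness.  Note a dual-labelled
particle emits under both lasers, so its total detected rate is ~2ε·W.
Background arrives uniformly at `bg_rate` per channel with random gates.

**Finite-box physics.**  Two departures from the infinite-dilution ideal are
inherent to a closed box and are *properties of the generator, not bugs in
the estimators*:

1. *Canonical baseline.*  With a fixed particle count N, occupancy
   fluctuations in the focal volume are sub-Poissonian and the intensity
   autocorrelation carries an exact additive baseline of −1/N at all lags.
   The correlation estimator's self-normalization absorbs most of it; the
   FCS/FCCS fitters include a free constant-baseline term (as instrument
   software does, for slow drifts) which absorbs the rest.
2. *Mode truncation.*  Diffusion relaxation modes with wavelength longer
   than the box are absent, so the measured decay falls below the
   infinite-medium model beyond lags of order (L/2π)²/D.  Recovery
   workflows therefore fit the lag window where the diffusion factor
   retains ≥ 3% of its amplitude (with a two-decade floor), selected
   self-consistently from a first full-range fit.

The default box is (8·w0, 8·w0, 4·z0).  Recovery tests and the acceptance
script use (2.4, 2.4, 6.0) µm at w0 = 0.3 µm — the same default — which
keeps the canonical baseline at 1/230 ≈ 0.4% of a typical amplitude; the
burst/smFRET runs use smaller or larger boxes chosen so that particle counts
are large enough to resolve the planted composition while occupancy stays in
the single-molecule regime (edge detection weight ≤ e⁻⁸ ≈ 3×10⁻⁴ in every
configuration, so wraparound bias is negligible).

Randomness comes from one xoshiro256** generator per simulation call,
seeded via splitmix64 from the user seed — numba-compiled draws several
times faster than the library generators, and exactly reproducible.

## Correlation and FCS/FCCS

The estimator convention is G(τ) = ⟨δF₁(t) δF₂(t+τ)⟩ / (⟨F₁⟩⟨F₂⟩) with
truncated-window empirical means (symmetric normalization).  The multi-tau
ladder uses 16 linear lags per octave with pair-sum coarsening by 2; a
brute-force direct estimator over the identical coarse binning is retained
as the test oracle (agreement to 1e-6 relative).  Per-lag standard errors
come from block averaging over 10 contiguous record segments, with a floor
of 1e-4·G(0) in the fit weights.

The one-species model is

    G(τ) = 1/(π^{3/2} w0² z0 C) · 1/[(1 + 4Dτ/w0²) √(1 + 4Dτ/z0²)],

flow velocity fixed at zero.  Dual-colour data are fitted simultaneously:
each autocorrelation is the two-component (free + double-labelled) sum with
a (C_free + C_ad)² amplitude denominator, and the cross-correlation carries
only the double-labelled term; w0, z0 are shared and fixed from
calibration.  The effective volume is V_eff = π^{3/2} w0² z0/(2√2), and the
number of cross-correlated particles is reported in the printed convention

    N_ad = G_x(0) / (2√2 · G_a(0) · G_d(0)).

Combining the definitions C_ad = G_x(0)/(G_a(0) G_d(0) V_eff) and
N_ad = C_ad·V_eff algebraically instead gives G_x(0)/(G_a(0) G_d(0)) — a
2√2 discrepancy inherent to the printed conventions.  Both values are
reported (`n_ad` and `n_ad_unscaled`).  A cross-amplitude within 3 s.e. of
zero yields `significant=False` with N_ad ≈ 0 rather than an error.

Optics calibration fits the model with D fixed at a reference dye value
(430 µm²/s) and w0 (optionally the shape ratio z0/w0) free; the fitted
waist scales as √D_ref, which the tests verify.

## Photon-counting histogram and bursts

For a spatially uniform profile the count distribution is the compound
double Poisson Π(k; N̄, ε) = Σ_N Pois(N; N̄)·Pois(k; Nε), with mean N̄ε and
variance N̄ε(1+ε) (Fano factor 1+ε).  The occupancy sum is truncated at
N̄ + 10√N̄ + 20 (tail mass < 1e-12).  Fitting is Poisson maximum likelihood
over histogram bins — correct at small counts, unlike least squares.
Heterogeneous-brightness samples defeat the one-species fit (χ²/dof ≫ 1);
segmental mode splits the k-range at the point where the head fit's
predicted tail mass drops below 1e-4 (a rule exposed as a parameter, since
no canonical segmentation exists) and refits each segment, with per-segment
brightness as an oligomer-size proxy.  Bin time defaults: 500 µs (2 kHz)
for PCH, 20 ms (50 Hz) for bursts; burst multiples are
round(bin count / mean bin count) with ties rounding half up.

## smFRET

Streams are binned at 500 µs; bins with donor-excitation total
(I_D + I_A_raw) at or above a threshold are selected (default mean + 3 s.d.
of the per-bin totals, standing in for an instrument's unspecified "optimal
signal" gate).  Corrected acceptor intensity is
I_A = I_A_raw − l·I_D − d·I_AA, with the Aex-gated acceptor signal I_AA as
the direct-excitation reference (the natural PIE choice; both coefficients
configurable, defaults 3% and 1%), and E = I_A/(I_A + γ·I_D) with γ = 1.
Negative corrected intensities are kept — the histogram domain spans
[−0.2, 1.2] — preserving the shot-noise shape of the donor-only zero peak;
out-of-domain values are clipped into the edge bins so every selected bin
contributes one event.  Peaks are fitted phenomenologically with 1–3
Gaussians (caller's choice), means initialized by mode finding or supplied
explicitly; on non-convergence the raw histogram is still returned.

Denaturant titrations fit both a linear drift and a two-state sigmoid to
the peak position versus concentration and compare them by AIC; "non-
cooperative" means the linear model is preferred or the sigmoid slope's 95%
CI includes zero.

## Hydrodynamics

Rh = k_B·T/(6π·η·D); defaults T = 295.15 K (21.5 °C room temperature) and
η = 9.55×10⁻⁴ Pa·s (water at that temperature), both configurable since
buffers differ.  Chain-length back-calculation uses the empirical power
laws Rh = 4.75·N^0.29 Å (folded) and Rh = 2.21·N^0.57 Å (denatured); the
coefficients are the standard literature values and are fully
configurable.  Note the two default laws cross near N ≈ 15, so the
"denatured > folded" ordering holds for chains longer than that.  The
monomer boundary for an N-residue protein is [Rh_folded(N),
Rh_denatured(N)]; a measured radius above the denatured bound flags an
assembly, and dividing the back-calculated chain lengths under both laws by
N brackets its size in monomer equivalents.

## Kinetics and calibrations

Aggregation traces fit y = A·e^{Rt} (optional baseline, default off) with
time constant 1/|R|.  FRAP recoveries are normalized as
(roi/ref)/mean_prebleach(roi/ref) — exact cancellation of acquisition
bleaching — and fitted as the decaying deficit y = F∞ − B·e^{Rt} with
R < 0.  The reported `time_constant` is −1/R, matching the convention under
which recovery half-times are quoted alongside such fits; since that
conflates time constant with half-time, the ln2-corrected `half_time` is
reported as well.  Nonlinear fits use bounded least squares with three
jittered starts (fixed seed).  Solubility reads the fraction of total,
100·A_sup/(A_sup+A_pellet), with the plain sup/pellet ratio exposed as an
option since both readings appear in practice.  Calibrations are OLS on the
response or its log10 (fluorescence standards; size-exclusion log Mw versus
retention time), with predict/invert inverses.  Nuclear concentration
divides the quantified amount by (cell count × transfection efficiency ×
220 fl).

## Contact-matrix analytics

Coordinates are 0-based half-open (BED) throughout; bins are labelled by
start coordinate, which makes the ≥1-bp peak-overlap rule unambiguous.

* **ICE balancing** iterates marginal equalization until the unmasked
  marginal CV < 1e-4 (default), returning bias vectors and a flag instead
  of an exception on non-convergence.  Balancing is idempotent.
* **P(s)** averages contacts per log-spaced distance band (8/decade),
  normalized so the band-width-weighted sum is 1; a log–log regression
  recovers the decay exponent.
* **Compartments**: observed/expected with per-distance means (no
  smoothing beyond the stated sliding window — 100 kb window, 20 kb step,
  implemented as a NaN-aware boxcar at the working binning), Pearson
  correlation matrix, first principal component sign-oriented to an
  orientation track; saddle plots average O/E over E1 decile pairs.  A
  first component explaining < 10% of variance flags a compartment-free
  map.
* **Insulation/domains**: mean contact in a 1 Mb × 1 Mb square sliding
  along the diagonal, log2-normalized to the chromosome mean; boundaries
  where the 200-kb left-minus-right delta crosses zero with prominence
  ≥ 0.1; aggregate domain strength is mean within-domain O/E over mean
  between-adjacent-domain O/E.
* **Pairwise binding-site aggregation**: for every intra-chromosomal
  anchor-bin pair separated by at least 2·flank + 3·window (default — the
  smallest separation keeping every background window off both anchors;
  exposed as a flag), extract the (2F+1)² submatrix (F = flank/window = 10
  at the 250-kb/25-kb defaults), divide by the pair's mean background over
  the (2F)² = 400 window-window contacts excluding the anchor row and
  column, and average over pairs.  Pairs with under 50% valid background
  cells are dropped and counted.  The per-pair centre scores feed paired
  two-sided t-tests between conditions (constant differences are flagged
  degenerate rather than reported as infinite statistics); per-pair log2
  fold changes use a pseudocount of half the smallest positive balanced
  value.

### Synthetic contact maps

Expected contact between bins i, j is max(|i−j|,1)^ps_exponent, multiplied
by a compartment factor (same ±1 label), a domain factor (same block
between boundaries) and the anchor fold when both bins are planted anchors,
then Poisson-sampled so the expected upper-triangle total equals `depth`.
Maps for enrichment-recovery checks use a flat decay (ps_exponent = 0):
with a realistic decaying background the 21×21 aggregation grid acquires a
deterministic tilt of order flank/separation from the P(s) curvature itself
— a property of distance decay, not of the planted enrichment being
measured — while decay-exponent recovery is checked on ps_exponent = −1
maps where it is the signal.

## Problem sizes

Recovery runs are desk-scale: 30–60-s photon streams (10⁵–10⁶ photons) at
nanomolar-equivalent concentrations, 10⁵-bin count histograms, and single
chromosomes of 200–600 bins at 20–25-kb resolution with 2×10⁶–3×10⁷
sampled contacts.  These sizes give planted-parameter recovery well inside
the stated tolerances (10–15%) while a full test run stays in the minutes
range.

## What the synthetic data do not emulate

No triplet/blinking photophysics, detector afterpulsing or dead time, no
nanosecond lifetime structure (PIE gating is ideal), no photobleaching
during acquisition, and emitters never interact or exchange between
species.  Contact maps contain no read-level artifacts (no mappability
structure, no trans contacts, no replicate variability).  Passing tests
therefore demonstrate the correctness of the estimators and fits under the
stated generative models, not robustness to every instrument or library
artifact of real data.
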