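"""smFRET: PIE gating, intensity corrections and efficiency histograms.

A double-labelled species with intramolecular transfer efficiency 0.75
diffuses through the confocal spot; 500-µs bins with burst-level signal are
selected, corrected for 3% donor bleed-through and 1% acceptor direct
excitation, and histogrammed.  A Gaussian fit recovers the planted peak.
"""

import smbridge as sb

optics = sb.OpticalConfig(w0=0.3, z0=1.5)
species = sb.SpeciesSpec("dual", conc=0.25, D=20.0, eps=2.5e5, efret=0.75)
stream = sb.simulate_photon_stream([species], optics, duration=20.0,
                                   dt=1e-4, box=(1.2, 1.2, 6.0), seed=1)

bins = sb.gate_and_bin(stream, bin_time=5e-4)  # threshold: mean + 3 sd
print(f"{bins.selected.sum()} burst bins selected out of {len(bins.I_D):,}")

hist = sb.fret_histogram(bins, l=0.03, d=0.01, gamma=1.0, n_gauss=1)
mean, sd, amp = hist.gaussians[0]
print(f"fitted FRET peak: E = {mean:.3f} ± {sd:.3f} (planted 0.75)")
print(f"histogram holds {hist.n_events} events on [-0.2, 1.2]")

# the worked correction arithmetic on one bin
one = sb.FretBinSeries(bin_time=5e-4, I_D=[200], I_A_raw=[100], I_AA=[300],
                       selected=[True])
e = sb.efret_values(one)[0]
print(f"single-bin example: I_A = 100 - 0.03*200 - 0.01*300 = 91, "
      f"E = 91/291 = {e:.4f}")
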