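"""FCCS: detect co-diffusing double-labelled complexes (DNA bridging).

Two DNA populations carry a green or a red label; a bridging protein joins
some of them into slow double-labelled complexes.  Cross-correlation between
the PIE-separated channels reports only the double-labelled species; the
fitted N_ad (number of cross-correlated particles) and the complex's slower
diffusion are the bridging readout.
"""

import smbridge as sb

optics = sb.OpticalConfig(w0=0.3, z0=1.5)
species = [
    sb.SpeciesSpec("donor_only", conc=1.4, D=60.0, eps=2e4),     # free green DNA
    sb.SpeciesSpec("acceptor_only", conc=1.4, D=60.0, eps=2e4),  # free red DNA
    sb.SpeciesSpec("dual", conc=0.6, D=20.0, eps=2e4),           # bridged pair
]
stream = sb.simulate_photon_stream(species, optics, duration=40.0,
                                   dt=3.75e-5, box=(2.4, 2.4, 6.0), seed=3)

kw = dict(lag_range=(3.75e-5, 2.0))
ga = sb.compute_correlation(stream, ("A", "Aex"), **kw)
gd = sb.compute_correlation(stream, ("D", "Dex"), **kw)
gx = sb.compute_correlation(stream, ("D", "Dex"), ("A", "Aex"), **kw)
fit = sb.fit_fccs(ga, gd, gx, optics)

frac = fit.Cad / (fit.Cd + fit.Cad)
print(f"double-labelled density C_ad = {fit.Cad:.2f} /µm³ (truth 0.6)")
print(f"bridged fraction             = {frac:.1%} (truth 30%)")
print(f"complex D_ad = {fit.Dad:.0f} µm²/s vs free D_d = {fit.Dd:.0f} µm²/s")
print(f"N_ad (printed convention)    = {fit.n_ad:.3f}")
print(f"C_ad * V_eff (algebraic)     = {fit.n_ad_unscaled:.3f}  "
      f"[differs by 2*sqrt(2)]")
print(f"cross-correlation significant: {fit.significant}")
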