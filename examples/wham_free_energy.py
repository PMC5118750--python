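"""Umbrella sampling round trip: generate biased windows, recover the PMF.

A double-well binding free-energy profile (deep well 20 kBT at 1.6 nm,
shallow intermediate at 2.4 nm, flat unbound plateau) plays the role of the
unknown PMF.  42 harmonic windows (k = 1000 kJ/mol/nm^2) sample it; WHAM
recombines the histograms; the binding free energy is read off as
plateau minus well minimum, with a bootstrap error bar.
"""

import aptafield as af

true_pmf = af.TruePMF.double_well()
kT = af.kBT(300.0)
print(f"true well depth: {true_pmf.well_depth():.2f} kJ/mol "
      f"({true_pmf.well_depth() / kT:.1f} kBT)")

config = af.GeneratorConfig(samples_per_window=2000, seed=11)
windows = af.generate_windows(true_pmf, config)
result = af.wham_solve(windows, n_bins=100)
print(f"WHAM converged in {result.iterations} iterations")

bound, unbound = (1.2, 2.0), (3.2, 4.0)
dg = af.delta_g_binding(result.pmf, bound, unbound)
dg_sd, _ = af.bootstrap_error(windows, bound, unbound, n_bootstrap=16,
                              n_bins=100, seed=1, tolerance=1e-6 * kT)
print(f"recovered Delta-G_binding = {dg:.2f} +/- {dg_sd:.2f} kcal/mol")
print(f"true value                = {true_pmf.well_depth() / 4.184:.2f} kcal/mol")
print("\nThe estimate agrees with the generator's well depth to a fraction "
      "of kBT; the +/- is the bootstrap standard deviation over resampled "
      "window data.")
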