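"""WHAM free-energy recovery from umbrella-sampling windows.

Draws exact Boltzmann samples from a double-well potential with a known
5 kJ/mol barrier under 17 harmonic bias windows, then reconstructs the
profile with WHAM and reports the recovered barrier, histogram overlaps,
per-window autocorrelation times and Bayesian bootstrap errors.
"""

import numpy as np

from avidkit import (
    PotentialSpec,
    autocorrelation_time,
    bootstrap_error,
    generate_umbrella_series,
    histogram_overlap,
    wham_solve,
)

truth = PotentialSpec("double_well", {"barrier": 5.0, "half_separation": 1.0})
centers = np.arange(-2.0, 2.01, 0.25)
windows = generate_umbrella_series(truth, centers, force_constant=200.0,
                                   n_samples=5000, seed=3)

profile = wham_solve(windows)
i_mid = np.argmin(np.abs(profile.bin_centers))
print(f"WHAM converged after {profile.n_iterations} iterations")
print(f"recovered barrier : {profile.free_energy[i_mid]:.2f} kJ/mol (truth: 5.00)")

overlaps, low = histogram_overlap(windows)
print(f"adjacent-histogram overlap: min {overlaps.min():.2f}, "
      f"{len(low)} pair(s) below the 0.05 floor")

taus = [autocorrelation_time(w.samples) for w in windows[:3]]
print("autocorrelation times (first 3 windows):", np.round(taus, 2),
      "(exact i.i.d. samples -> ~1)")

errors = bootstrap_error(windows, n_bootstrap=50, seed=9)
m = profile.finite_mask & np.isfinite(errors)
print(f"Bayesian bootstrap error: median {np.median(errors[m]):.2f} kJ/mol per bin")

# The min-shifted profile puts the two wells at 0; the value at the midpoint
# is the barrier. Overlap and autocorrelation are the standard checks that
# the window layout and sampling support a reliable profile.
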