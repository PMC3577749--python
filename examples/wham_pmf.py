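"""Reconstruct a potential of mean force from umbrella-sampling windows.

Biased Metropolis samples are drawn from the double well
U(x) = 2(x² − 1)² kcal/mol under the study's window geometry — 26 windows
0.5 Å apart with k = 20 kcal/mol/Å² harmonic restraints at 300 K — and
recombined by self-consistent WHAM.  A second dataset with a planted
3 kcal/mol binding well demonstrates the dissociation-ΔG extraction.
"""

import numpy as np

from pepdimer import synthetic as syn
from pepdimer.wham import (
    binned_reference_pmf,
    dissociation_delta_g,
    pmf_rms_error,
    wham_solve,
)

potential = syn.double_well()
windows, _ = syn.generate_umbrella_dataset(potential, n_per_window=5000, seed=1)
result = wham_solve(windows, bin_width=0.05, temperature=300.0)
rms = pmf_rms_error(result, binned_reference_pmf(potential))
print(f"windows: {len(windows)}, converged in {result.n_iter} iterations")
print(f"double-well recovery RMS: {rms:.3f} kcal/mol")
# The recovered profile deviates from the analytic potential by well under
# 0.1 kcal/mol over the thermally accessible range.

well = syn.well_plus_plateau(depth=3.0, width=2.0, x0=2.0)
dwin, _ = syn.generate_umbrella_dataset(
    well, centers=np.arange(0.0, 13.0, 0.5), n_per_window=5000, seed=1, thin=10
)
dres = wham_solve(dwin)
est = dissociation_delta_g(dres, slope_tol=0.1)
print(f"dissociation free energy: {est.delta_g:.2f} kcal/mol (planted 3.0)")
print(f"plateau: {est.plateau_range[0]:.1f}-{est.plateau_range[1]:.1f} A, "
      f"minimum at {est.min_location:.2f} A")
# delta G is read as the plateau height of the min-normalized PMF, the free
# energy to take the bound pair to full separation.
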