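"""Flexibility analysis of a synthetic multi-frame trajectory: RMSF with
block-averaged errors, dynamic cross-correlation, and a pocket-width
distance series.
"""

import numpy as np

from brr2allo.flexibility import (
    ca_selection,
    cross_correlation,
    pocket_width,
    rmsf,
    superpose,
)
from brr2allo.synthetic import NetworkDesign, generate_synthetic_trajectory

traj, _ = generate_synthetic_trajectory(NetworkDesign(seed=1, n_frames=200,
                                                      jitter=0.15))
sel = ca_selection(traj)
aligned = superpose(traj, sel)

prof = rmsf(aligned, sel, n_blocks=5)
print(f"mean RMSF over {len(prof.residues)} residues: "
      f"{prof.rmsf_mean.mean():.3f} +/- {prof.rmsf_sem.mean():.3f} A")
print(f"(isotropic jitter sigma=0.15 A -> expected RMSF ~ {0.15 * np.sqrt(3):.3f} A)")

corr = cross_correlation(aligned, sel)
off = corr.matrix[~np.eye(len(sel), dtype=bool)]
print(f"cross-correlation: diagonal = {corr.matrix[0, 0]:.1f}, "
      f"max |off-diagonal| = {np.abs(off).max():.2f}")

pw = pocket_width(traj, (("A", 401), ("A", 410)), n_blocks=5)
print(f"pocket width A:401-A:410: {pw.mean:.2f} +/- {pw.sem:.3f} A")
print("\nIndependent thermal jitter yields near-zero correlations and an RMSF")
print("at the analytic isotropic-noise limit; block SEMs quantify sampling error.")
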