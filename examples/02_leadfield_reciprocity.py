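"""Lead fields by reciprocity versus brute-force dipole excitation.

The reciprocity construction needs one forward solve per electrode (M - 1
solves); the direct construction needs one per dipole component (3N).  On a
small two-layer phantom both are computed and compared entry-by-entry.
"""

import numpy as np

from sepmap.forward import SolverConfig, assemble_spfd
from sepmap.leadfield import build_leadfield_direct, build_leadfield_reciprocity
from sepmap.phantom import PhantomSpec, build_layered_sphere, place_electrodes

spec = PhantomSpec(
    layer_radii=(10.0, 13.0),
    layer_conductivities=(0.33, 0.1),
    grid_shape=(16, 16, 16),
    spacing_mm=2.0,
    gm_shell_frac=(0.2, 0.85),
)
vol = build_layered_sphere(spec)
electrodes = place_electrodes(vol, "fibonacci", n_electrodes=8)
system = assemble_spfd(vol)

rng = np.random.default_rng(0)
mask = np.argwhere(vol.gray_matter_mask)
subset = mask[rng.choice(len(mask), size=20, replace=False)]

config = SolverConfig(tolerance=1e-8)
L_recip = build_leadfield_reciprocity(vol, electrodes, subset, config, system=system)
L_direct = build_leadfield_direct(vol, electrodes, subset, config, system=system)

rel = np.linalg.norm(L_recip.gain - L_direct.gain) / np.linalg.norm(L_direct.gain)
print(f"reciprocity solves: {len(L_recip.solve_log)} (electrodes minus reference)")
print(f"direct solves:      {len(L_direct.solve_log)} (20 voxels x 3 components)")
print(f"relative Frobenius discrepancy: {rel:.2e}")
print("The two constructions agree to solver tolerance; reciprocity is the")
print("one that scales to full gray-matter source spaces.")
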