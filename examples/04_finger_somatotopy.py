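"""Recover finger somatotopy from a synthetic 16-subject SEP cohort.

Five finger sources are planted 4 mm apart along a lateral-medial arc of
the gray-matter shell.  Each virtual subject gets jittered source
positions and independent sensor noise at 10 dB evoked SNR; every
subject x finger topography is localized with OMP, per-finger mean
coordinates are computed across subjects, and the somatotopic ordering is
tested by linear regression against the finger index (1 = thumb ...
5 = little).
"""

from sepmap.evaluate import FINGER_ORDER, summarize_by_target
from sepmap.pipeline import build_study, plant_finger_sources, run_cohort_replicate

study = build_study()
sources = plant_finger_sources(study)
print("planted finger voxels:", [(s.target_label, s.voxel) for s in sources])

rep = run_cohort_replicate(study, sources, seed=42, n_subjects=16, snr_db=10.0)

print("\nper-finger mean localized coordinates (mm):")
for label, c in zip(FINGER_ORDER, rep.mean_coords_mm):
    print(f"  {label:<7s} x={c[0]:6.1f}  y={c[1]:6.1f}  z={c[2]:6.1f}")

for ax, fit in rep.fits.items():
    print(
        f"axis {ax}: slope {fit.slope:+.2f} mm/finger, R = {fit.r:+.3f}, "
        f"p = {fit.p:.2e} ({'significant' if fit.significant else 'n.s.'})"
    )

print("\nlocalization accuracy vs planted positions:")
print(summarize_by_target(rep.results).to_string(index=False))
print("\nA monotone lateral (x) progression with |R| near 1 reproduces the")
print("thumb-to-little-finger somatotopic gradient from EEG alone.")
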