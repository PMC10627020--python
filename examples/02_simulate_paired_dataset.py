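"""Generate one synthetic subject with paired ECoG + BOLD recordings.

A gray-matter slab with an 8x8 electrode grid at 10 mm pitch; two Gaussian
activation foci; the BOLD activation equals the ECoG-truth field blurred by
a known ground-truth point-spread width (4 mm here).  The subject is
written in the pipeline's BIDS-like layout.
"""

from pathlib import Path

from boldkernel import make_design, make_scene, make_truth, simulate_bold, simulate_ecog
from boldkernel.synth import write_subject

scene = make_scene(seed=1)
truth = make_truth(scene, sigma_true=4.0, seed=1)
print(f"scene: {scene.gm_mask.sum()} gray-matter voxels, "
      f"{len(scene.electrode_names)} electrodes")
print(f"truth: sigma_true={truth.sigma_true} mm, band effects={truth.band_effects}")

ecog_design = make_design(5, 5, 30.0)
bold_design = make_design(4, 5, 30.0)
rec = simulate_ecog(scene, truth, ecog_design)
bold = simulate_bold(scene, truth, bold_design)
print(f"ECoG: {rec.n_channels} channels x {rec.n_samples} samples at {rec.fs:.0f} Hz")
print(f"BOLD: {bold.data.shape} at TR {bold.tr} s")

out = Path("scratch/example_dataset")
write_subject(out, "sub-01", scene, truth, ecog_design, bold_design, rec, bold)
print(f"subject written under {out}/sub-01 "
      "(electrodes/channels/events TSVs, ECoG matrix, BOLD + GM mask NIfTI)")
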