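"""The core analysis: ECoG-fMRI correlation as a function of kernel width.

For each kernel width sigma (1-20 mm), the fMRI z at every significant
electrode is the Gaussian-weighted average of surrounding gray-matter voxel
z-scores; correlating these with the ECoG z-scores across electrodes gives
the explained-variance curve r^2(sigma).  Its maximum is the peak kernel
width (best ECoG-fMRI agreement); the most negative second derivative is
the maximum-downwards-concavity width (where further smoothing stops
helping — the spatial-specificity estimate of the BOLD point spread).
"""

import pandas as pd

from boldkernel import (
    band_responses,
    bold_zmap,
    kernel_curve,
    make_design,
    make_scene,
    make_truth,
    simulate_bold,
    simulate_ecog,
)

scene = make_scene(seed=1)
truth = make_truth(scene, sigma_true=4.0, seed=1)
rec = simulate_ecog(scene, truth, make_design(5, 5, 30.0))
bold = simulate_bold(scene, truth, make_design(4, 5, 30.0))

electrodes = pd.DataFrame(
    {
        "name": scene.electrode_names,
        "x": scene.electrode_xyz[:, 0],
        "y": scene.electrode_xyz[:, 1],
        "z": scene.electrode_xyz[:, 2],
    }
)
resp = band_responses(rec, make_design(5, 5, 30.0), electrodes)
zmap = bold_zmap(bold, make_design(4, 5, 30.0), scene.gm_mask)

for band in ("hfb", "alpha", "beta"):
    curve = kernel_curve(zmap, resp[resp.band == band])
    s = curve.summary()
    print(
        f"{band:>5s}: n={s['n_electrodes']:2d} electrodes | "
        f"peak r^2={s['peak_r2']:.2f} at sigma={s['peak_sigma']:.2f} mm | "
        f"concavity at {s['concavity_sigma']} mm | "
        f"slope at peak {s['slope_at_peak']:+.2f}"
    )
print(
    "\nGround truth sigma_true = 4 mm: the concavity width tracks it, while"
    "\nthe peak width is larger (averaging noisy voxels keeps helping past"
    "\nthe point spread).  The slope is positive for broadband power and"
    "\nnegative for alpha/beta, mirroring their opposite coupling to BOLD."
)
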