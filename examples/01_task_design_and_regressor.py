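"""Build the block-design motor task and its BOLD movement regressor.

The scanner task is 4 movement + 5 rest blocks of 30 s (4.5 min); the
regressor is the movement boxcar convolved with a canonical double-gamma
HRF, sampled once per 0.608 s volume.
"""

import numpy as np

from boldkernel import make_design
from boldkernel.fmri import build_regressor, canonical_hrf

design = make_design(n_movement_blocks=4, n_rest_blocks=5, block_s=30.0)
print(f"blocks: {design.conditions}")
print(f"total duration: {design.total_duration:.0f} s")

h = canonical_hrf(dt=0.1)
print(f"HRF: sum={h.sum():.3f}, peak at {np.argmax(h) * 0.1:.1f} s after onset")

tr = 0.608
n_vols = int(design.total_duration / tr)
reg = build_regressor(design, tr, n_vols)
print(
    f"regressor: {n_vols} volumes, range [{reg.raw.min():.2f}, {reg.raw.max():.2f}], "
    f"first rise crosses 0.5 at t={np.argmax(reg.raw > 0.5) * tr:.1f} s"
)
# The rise begins ~5 s after the first movement block starts at 30 s: the
# hemodynamic response lags the neuronal activity by the HRF peak delay.
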