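import numpy as np
import pandas as pd
import pytest

import boldkernel as bk
from boldkernel.fmri import ZMap


@pytest.fixture(scope="session")
def plain_scene():
    """Small deterministic scene: no rotation, no jitter."""
    return bk.make_scene(
        grid_shape=(4, 4), margin_mm=12.0, seed=0, jitter_mm=0.0, rotation_deg=0.0
    )


@pytest.fixture()
def electrode_table():
    def _table(scene):
        return pd.DataFrame(
            {
                "name": scene.electrode_names,
                "x": scene.electrode_xyz[:, 0],
                "y": scene.electrode_xyz[:, 1],
                "z": scene.electrode_xyz[:, 2],
            }
        )

    return _table


def random_zmap(scene, seed=0, sd=4.0):
    rng = np.random.default_rng(seed)
    z = np.full(scene.gm_mask.shape, np.nan)
    z[scene.gm_mask] = rng.normal(0.0, sd, int(scene.gm_mask.sum()))
    return ZMap(z, scene.gm_mask, scene.affine)
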