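import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boldkernel as bk
from boldkernel.fmri import ZMap
from boldkernel.kernel import (
    DEFAULT_SIGMA_GRID,
    concavity_point,
    correlation_at_sigma,
    gaussian_weights,
    kernel_curve,
    weighted_zscores,
)
from conftest import random_zmap


def _zmap_from_voxels(voxels, zvals, shape=(10, 10, 10), voxel_mm=1.0):
    """Build a ZMap whose gray matter is exactly the listed voxel indices."""
    mask = np.zeros(shape, dtype=bool)
    z = np.full(shape, np.nan)
    for ijk, v in zip(voxels, zvals):
        mask[tuple(ijk)] = True
        z[tuple(ijk)] = v
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return ZMap(z, mask, affine)


class TestGaussianWeights:
    def test_two_voxel_closed_form(self):
        # voxels at 2 mm (z=1) and 4 mm (z=0) from the electrode, sigma 2 mm
        zmap = _zmap_from_voxels([(2, 0, 0), (4, 0, 0)], [1.0, 0.0])
        kw = gaussian_weights(np.array([0.0, 0.0, 0.0]), zmap, sigma=2.0)
        w = np.exp([-0.5, -2.0])
        expected = w[0] / w.sum()
        got = float(kw.weights @ zmap.z[tuple(kw.voxel_indices.T)])
        assert got == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8176, abs=1e-4)

    def test_single_voxel_in_radius_takes_all_weight(self):
        zmap = _zmap_from_voxels([(1, 0, 0)], [2.5])
        for sigma in (0.5, 2.0, 50.0):
            kw = gaussian_weights(np.zeros(3), zmap, sigma)
            assert kw.weights == pytest.approx([1.0])

    def test_uniform_zmap_gives_constant(self, plain_scene):
        z = np.where(plain_scene.gm_mask, 3.14, np.nan)
        zmap = ZMap(z, plain_scene.gm_mask, plain_scene.affine)
        for sigma in (1.0, 4.0, 12.0):
            vals = weighted_zscores(
                zmap,
                pd.DataFrame(
                    {
                        "electrode": plain_scene.electrode_names,
                        "x": plain_scene.electrode_xyz[:, 0],
                        "y": plain_scene.electrode_xyz[:, 1],
                        "z": plain_scene.electrode_xyz[:, 2],
                    }
                ),
                sigma,
            )
            assert vals.to_numpy() == pytest.approx(3.14)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 4),
        electrode=st.integers(0, 8),
        sigma=st.floats(1.0, 30.0),  # the sweep's smallest width upward
    )
    def test_weights_normalised_over_random_scenes(self, seed, electrode, sigma):
        scene = bk.make_scene(grid_shape=(3, 3), margin_mm=10.0, seed=seed)
        zmap = random_zmap(scene, seed)
        kw = gaussian_weights(scene.electrode_xyz[electrode], zmap, sigma)
        assert kw.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (kw.weights >= 0).all()

    def test_no_gray_matter_in_radius_is_an_error(self):
        zmap = _zmap_from_voxels([(9, 9, 9)], [1.0])
        with pytest.raises(ValueError, match="no gray-matter voxel"):
            gaussian_weights(np.zeros(3), zmap, sigma=0.5)

    def test_truncated_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            scene = bk.make_scene(grid_shape=(3, 3), margin_mm=10.0, seed=seed)
            zmap = random_zmap(scene, seed)
            coords = scene.gm_coords()
            zvals = zmap.z[zmap.gm_mask]
            e = scene.electrode_xyz[rng.integers(9)]
            sigma = float(rng.uniform(1.0, 20.0))
            d2 = ((coords - e) ** 2).sum(axis=1)
            w = np.exp(-(d2 - d2.min()) / (2 * sigma**2))
            exact = float((w / w.sum()) @ zvals)
            kw = gaussian_weights(e, zmap, sigma)
            got = float(kw.weights @ zmap.z[tuple(kw.voxel_indices.T)])
            assert got == pytest.approx(exact, abs=1e-6)


class TestWeightedZscores:
    def test_large_sigma_limit_is_gm_mean(self, plain_scene, electrode_table):
        zmap = random_zmap(plain_scene, 1)
        tab = electrode_table(plain_scene).rename(columns={"name": "electrode"})
        vals = weighted_zscores(zmap, tab, sigma=1e6)
        gm_mean = np.nanmean(zmap.z)
        assert vals.to_numpy() == pytest.approx(gm_mean, abs=1e-9)

    def test_small_sigma_limit_is_nearest_voxel(self, plain_scene):
        zmap = random_zmap(plain_scene, 2)
        coords = plain_scene.gm_coords()
        zvals = zmap.z[zmap.gm_mask]
        # electrodes placed exactly at gray-matter voxel centers
        idx = [0, 10, 100]
        tab = pd.DataFrame(
            {
                "electrode": [f"e{i}" for i in idx],
                "x": coords[idx, 0],
                "y": coords[idx, 1],
                "z": coords[idx, 2],
            }
        )
        vals = weighted_zscores(zmap, tab, sigma=0.01 * plain_scene.voxel_size)
        assert vals.to_numpy() == pytest.approx(zvals[idx], abs=1e-12)

    def test_translation_equivariance(self, plain_scene, electrode_table):
        zmap = random_zmap(plain_scene, 3)
        offset = np.array([13.0, -7.0, 5.0])
        affine2 = zmap.affine.copy()
        affine2[:3, 3] += offset
        zmap2 = ZMap(zmap.z, zmap.gm_mask, affine2)
        tab = electrode_table(plain_scene).rename(columns={"name": "electrode"})
        tab2 = tab.copy()
        tab2[["x", "y", "z"]] += offset
        a = weighted_zscores(zmap, tab, 3.0)
        b = weighted_zscores(zmap2, tab2, 3.0)
        assert a.to_numpy() == pytest.approx(b.to_numpy(), abs=1e-12)

    def test_missing_gm_electrodes_dropped_with_warning(self, plain_scene):
        zmap = random_zmap(plain_scene, 4)
        tab = pd.DataFrame(
            {
                "electrode": ["ok", "far"],
                "x": [0.0, 500.0],
                "y": [0.0, 500.0],
                "z": [1.0, 500.0],
            }
        )
        with pytest.warns(RuntimeWarning, match="dropped"):
            vals = weighted_zscores(zmap, tab, 2.0)
        assert list(vals.index) == ["ok"]
        with pytest.raises(ValueError, match="all electrodes dropped"):
            weighted_zscores(zmap, tab.iloc[[1]], 2.0)

    def test_smoothing_shrinks_across_electrode_variance(
        self, plain_scene, electrode_table
    ):
        tab = electrode_table(plain_scene).rename(columns={"name": "electrode"})
        for seed in range(3):
            zmap = random_zmap(plain_scene, seed)
            variances = [
                weighted_zscores(zmap, tab, s).to_numpy().var()
                for s in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
            ]
            assert all(
                b <= a + 1e-9 for a, b in zip(variances, variances[1:])
            )


class TestCorrelation:
    def test_exact_linear_relationship(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = correlation_at_sigma(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)
        res = correlation_at_sigma(x, -x)
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        res = correlation_at_sigma(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert res["r"] == pytest.approx(r_hand, abs=1e-12)
        assert res["r2"] == pytest.approx(r_hand**2, abs=1e-12)

    def test_affine_rescaling_leaves_r2(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        base = correlation_at_sigma(x, y)
        scaled = correlation_at_sigma(3 * x + 2, 0.5 * y - 7)
        assert scaled["r2"] == pytest.approx(base["r2"], abs=1e-12)
        assert scaled["slope"] == pytest.approx(base["slope"] * 0.5 / 3, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlation_at_sigma([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            correlation_at_sigma([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_flag(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 4.0, 9.0, 100.0])  # monotone, nonlinear
        assert correlation_at_sigma(x, y, spearman=True)["r"] == pytest.approx(1.0)


class TestConcavity:
    def test_analytic_exponential_curve_unit_grid(self):
        # r2 = 1 - exp(-s/3): second derivative -(1/9)exp(-s/3) is most
        # negative at the left end -> first interior point of the stencil
        grid = np.arange(1.0, 21.0)
        sigma, r2_at, missing = concavity_point(grid, 1 - np.exp(-grid / 3.0))
        assert not missing
        assert sigma == 2.0

    def test_analytic_exponential_curve_default_grid(self):
        grid = DEFAULT_SIGMA_GRID
        sigma, _, missing = concavity_point(grid, 1 - np.exp(-grid / 3.0))
        assert not missing
        assert sigma == 2.0  # first interior point of the 1 mm stencil

    def test_linear_curve_reports_missing(self):
        grid = np.arange(1.0, 21.0)
        sigma, r2_at, missing = concavity_point(grid, 0.01 * grid + 0.1)
        assert missing and sigma is None and r2_at is None

    def test_constant_curvature_tie_breaks_to_smallest(self):
        grid = np.arange(1.0, 21.0)
        r2 = -((grid - 10.0) ** 2)
        r2 = (r2 - r2.min()) / (r2.max() - r2.min())
        sigma, _, missing = concavity_point(grid, r2)
        assert not missing
        assert sigma == 2.0

    def test_interior_trough_is_found(self):
        grid = DEFAULT_SIGMA_GRID
        # logistic-style rise centred at 8 mm: steepest deceleration after 8
        r2 = 1.0 / (1.0 + np.exp(-(grid - 8.0) / 1.5))
        sigma, _, missing = concavity_point(grid, r2)
        assert not missing
        assert 8.0 < sigma < 12.0

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            concavity_point(np.array([1.0, 2.0, 4.0, 8.0, 16.0]), np.zeros(5))
        with pytest.raises(ValueError, match="5 grid points"):
            concavity_point(np.array([1.0, 2.0, 3.0]), np.zeros(3))


class TestKernelCurve:
    def _setup(self, seed=0):
        scene = bk.make_scene(seed=seed)
        zmap = random_zmap(scene, seed)
        rng = np.random.default_rng(seed)
        tab = pd.DataFrame(
            {
                "electrode": scene.electrode_names,
                "z_score": rng.normal(0, 5, 64),
                "significant": rng.random(64) < 0.6,
                "x": scene.electrode_xyz[:, 0],
                "y": scene.electrode_xyz[:, 1],
                "z": scene.electrode_xyz[:, 2],
            }
        )
        return zmap, tab

    def test_curve_invariants(self):
        zmap, tab = self._setup(1)
        curve = kernel_curve(zmap, tab)
        assert np.all((curve.r2 >= 0) & (curve.r2 <= 1))
        assert curve.r2 == pytest.approx(curve.r**2)
        assert curve.peak_sigma in curve.sigma_grid
        assert curve.peak_r2 == curve.r2.max()
        i = int(np.argmax(curve.r2))
        assert curve.peak_sigma == curve.sigma_grid[i]
        assert curve.peak_on_boundary == (i in (0, len(curve.sigma_grid) - 1))
        if not curve.concavity_missing:
            assert curve.concavity_sigma in curve.sigma_grid
        assert curve.n_electrodes == int(tab.significant.sum())

    def test_significant_only_filter(self):
        zmap, tab = self._setup(2)
        all_curve = kernel_curve(zmap, tab, significant_only=False)
        sig_curve = kernel_curve(zmap, tab)
        assert all_curve.n_electrodes == 64
        assert sig_curve.n_electrodes < 64

    def test_too_few_significant_electrodes(self):
        zmap, tab = self._setup(3)
        tab["significant"] = False
        tab.loc[:1, "significant"] = True
        with pytest.raises(ValueError, match="at least 3"):
            kernel_curve(zmap, tab)

    def test_grid_validation(self):
        zmap, tab = self._setup(4)
        with pytest.raises(ValueError):
            kernel_curve(zmap, tab, sigma_grid=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            kernel_curve(zmap, tab, sigma_grid=np.array([-1.0, 1.0, 2.0, 3.0, 4.0]))

    def test_matches_per_electrode_weighted_path(self):
        """The vectorised sweep equals the per-electrode reference path."""
        zmap, tab = self._setup(5)
        sig = tab[tab.significant]
        curve = kernel_curve(zmap, tab, sigma_grid=np.array([1.0, 2.0, 4.0, 8.0, 16.0]))
        for i, sigma in enumerate([1.0, 2.0, 4.0, 8.0, 16.0]):
            vals = weighted_zscores(zmap, sig, sigma)
            res = correlation_at_sigma(
                sig.set_index("electrode").loc[vals.index, "z_score"], vals
            )
            assert curve.r2[i] == pytest.approx(res["r2"], abs=1e-12)
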