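"""Gray-matter-restricted voxelwise z-maps from a block-design BOLD series.

The temporal model is deliberately minimal: a Gaussian-weighted running-line
high-pass filter (sigma 45 s), a single movement regressor (30 s boxcar
convolved with a canonical double-gamma HRF, mean-centred), and per-voxel
ordinary least squares with df = n_vols - 2.  No prewhitening, motion
regressors or slice timing — inputs are assumed motion-corrected and
registered upstream.

The per-voxel OLS t is computed in closed form; scipy supplies the reference
distributions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import TaskDesign
from .ecog import Z_CAP, _t_to_z

__all__ = [
    "BoldSeries",
    "HrfParams",
    "Regressor",
    "ZMap",
    "highpass_gaussian_line",
    "canonical_hrf",
    "build_regressor",
    "glm_zmap",
    "bold_zmap",
]


@dataclass(frozen=True)
class BoldSeries:
    """A 4D BOLD array (x, y, z, t) with its affine and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        if data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if data.shape[-1] < 20:
            raise ValueError("BOLD series must have at least 20 volumes")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_vols(self) -> int:
        return self.data.shape[-1]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF shape parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0


@dataclass(frozen=True)
class Regressor:
    """Movement regressor sampled at volume times.

    ``values`` is mean-centred; ``raw`` holds the uncentred convolved boxcar.
    """

    values: np.ndarray
    raw: np.ndarray
    hrf_params: HrfParams
    dt: float

    def __post_init__(self) -> None:
        if len(self.values) != len(self.raw):
            raise ValueError("values and raw must have equal length")


@dataclass(frozen=True)
class ZMap:
    """3D z-score volume defined (finite) exactly on the gray-matter mask."""

    z: np.ndarray
    gm_mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        mask = np.asarray(self.gm_mask, dtype=bool)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "gm_mask", mask)
        if z.shape != mask.shape:
            raise ValueError("z and gm_mask must share a shape")
        if not np.all(np.isfinite(z[mask])):
            raise ValueError("z must be finite on the gray-matter mask")

    def summary(self) -> dict:
        zin = self.z[self.gm_mask]
        return {
            "n_gm_voxels": int(self.gm_mask.sum()),
            "max_z": float(zin.max()),
            "min_z": float(zin.min()),
            "pct_significant": float(100.0 * np.mean(np.abs(zin) > 1.96)),
        }


def _running_line_smoother(n: int, tr: float, sigma_s: float) -> np.ndarray:
    """n x n linear operator giving the Gaussian-weighted local-line fit.

    Row ``i`` produces the value at time ``t_i`` of a straight line fitted by
    weighted least squares with Gaussian weights of width ``sigma_s`` centred
    at ``t_i``.  Weights are truncated at the series bounds and renormalised
    implicitly (only in-range samples enter the fit).
    """
    t = np.arange(n) * tr
    w = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2.0 * sigma_s**2))
    m0 = w.sum(axis=1)
    m1 = w @ t
    m2 = w @ (t * t)
    denom = m0 * m2 - m1**2
    # fitted(t_i) = a_i + b_i t_i from the 2x2 normal equations; linear in y
    s = ((m2 - m1 * t)[:, None] * w + (m0 * t - m1)[:, None] * (w * t[None, :])) / denom[
        :, None
    ]
    return s


def highpass_gaussian_line(
    series: np.ndarray, tr: float, sigma_s: float = 45.0
) -> np.ndarray:
    """Remove slow trends by Gaussian-weighted least-squares line fitting.

    At every time point a straight line is fitted to the series with Gaussian
    weights of width ``sigma_s`` centred there; the fitted value is
    subtracted and the series mean added back.  ``series`` may be ``(t,)`` or
    ``(..., t)`` (time last).
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 3:
        raise ValueError("series must have at least 3 samples")
    s = _running_line_smoother(n, tr, sigma_s)
    fitted = series @ s.T
    return series - fitted + series.mean(axis=-1, keepdims=True)


def canonical_hrf(dt: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sampled double-gamma HRF kernel, normalised to unit sum.

    A gamma density peaking near ``peak_delay`` minus a later gamma density
    (the undershoot) scaled by ``undershoot_ratio``, sampled every ``dt``
    seconds over ``duration`` seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.duration, dt)
    h = stats.gamma.pdf(t, params.peak_delay) - params.undershoot_ratio * stats.gamma.pdf(
        t, params.undershoot_delay
    )
    return h / h.sum()


def build_regressor(
    design: TaskDesign,
    tr: float,
    n_vols: int,
    dt: float = 0.01,
    hrf_params: HrfParams = HrfParams(),
    center: bool = True,
) -> Regressor:
    """Movement boxcar convolved with the canonical HRF, sampled per volume.

    The boxcar (1 during movement, 0 otherwise) is built on a fine ``dt``
    grid, convolved with :func:`canonical_hrf`, sampled at volume times
    ``t = i * tr`` and mean-centred.
    """
    if n_vols < 1:
        raise ValueError("n_vols must be >= 1")
    span = (n_vols - 1) * tr - design.total_duration
    if abs(span) > max(np.max(design.durations), tr):
        raise ValueError(
            "volume coverage differs from the design duration by more than one block"
        )
    t_hi = np.arange(0.0, design.total_duration + hrf_params.duration, dt)
    box = design.movement_indicator(t_hi)
    h = canonical_hrf(dt, hrf_params)
    conv = np.convolve(box, h)[: len(t_hi)]
    t_vol = np.arange(n_vols) * tr
    raw = np.interp(t_vol, t_hi, conv)
    values = raw - raw.mean() if center else raw.copy()
    return Regressor(values, raw, hrf_params, dt)


def glm_zmap(
    bold: BoldSeries,
    reg: Regressor,
    gm_mask: np.ndarray,
    z_cap: float = Z_CAP,
) -> ZMap:
    """Voxelwise OLS of the (filtered) series on [intercept, regressor].

    For every gray-matter voxel, ``t = beta / SE`` with ``df = n_vols - 2``
    and z the signed normal quantile of the two-sided p, capped at
    ``+/- z_cap``.  Zero-variance voxels get z = 0; an exact fit gets the
    capped z.  Non-GM voxels are NaN.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if gm_mask.shape != bold.data.shape[:3]:
        raise ValueError("gray-matter mask does not match the BOLD volume shape")
    x = np.asarray(reg.values, dtype=float)
    if len(x) != bold.n_vols:
        raise ValueError("regressor length must equal the number of volumes")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("regressor is constant")
    y = bold.data[gm_mask]  # (v, t)
    n = bold.n_vols
    df = n - 2
    yc = y - y.mean(axis=1, keepdims=True)
    syy = np.einsum("vt,vt->v", yc, yc)
    sxy = yc @ xc
    beta = sxy / sxx
    sse = np.maximum(syy - beta**2 * sxx, 0.0)
    scale = np.maximum(syy, 1e-300)
    z = np.zeros(len(y))
    zero_var = syy <= 1e-30 * n
    exact = (~zero_var) & (sse <= 1e-24 * scale)
    ok = (~zero_var) & (~exact)
    se = np.sqrt(sse[ok] / df / sxx)
    t = beta[ok] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    z[ok] = [_t_to_z(ti, pi, z_cap) for ti, pi in zip(t, p)]
    z[exact] = np.sign(beta[exact]) * z_cap
    vol = np.full(gm_mask.shape, np.nan)
    vol[gm_mask] = z
    return ZMap(vol, gm_mask, bold.affine)


def bold_zmap(
    bold: BoldSeries,
    design: TaskDesign,
    gm_mask: np.ndarray,
    highpass_sigma_s: float = 45.0,
    hrf_params: HrfParams = HrfParams(),
    z_cap: float = Z_CAP,
) -> ZMap:
    """High-pass filter the GM voxels, build the regressor, and run the GLM."""
    gm = np.asarray(gm_mask, dtype=bool)
    data = bold.data.copy()
    data[gm] = highpass_gaussian_line(bold.data[gm], bold.tr, highpass_sigma_s)
    filtered = BoldSeries(data, bold.affine, bold.tr)
    reg = build_regressor(design, bold.tr, bold.n_vols, hrf_params=hrf_params)
    return glm_zmap(filtered, reg, gm, z_cap=z_cap)
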