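"""Seeded synthetic paired ECoG + BOLD datasets with known spatial ground truth.

The generator emulates the study conditions of a block-design motor
experiment: a planar electrode grid at 10 mm pitch resting just above a flat
gray-matter sheet, band-specific ECoG power modulation (broadband high-gamma
increase, alpha/beta decrease during movement), and a BOLD activation field
equal to the ECoG-truth field blurred by a known spatial width
``sigma_true`` plus drift and white temporal noise.  Everything is
deterministic given the seed.

What it does *not* emulate: cortical folding, explicit vasculature, motion,
epileptiform activity — the gray matter is a slab and the noise families are
simple: 1/f Gaussian ECoG noise; BOLD nuisances split into a PSF-smoothed
hemodynamic component plus linear/slow-cosine drift with PSF-smooth
coefficient fields, and a small spatially white thermal component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from nibabel.affines import apply_affine
from scipy import ndimage

from .design import MOVEMENT, TaskDesign, make_design
from .ecog import DEFAULT_BANDS, BandSpec, EcogRecording
from .fmri import BoldSeries, HrfParams, build_regressor

__all__ = [
    "SyntheticScene",
    "SyntheticTruth",
    "NoiseParams",
    "DEFAULT_BAND_EFFECTS",
    "make_scene",
    "make_truth",
    "simulate_ecog",
    "simulate_bold",
    "gm_blur",
    "write_subject",
]

#: Signed fractional band-power change during movement (at field value 1).
#: Magnitudes chosen so the simulated per-electrode z-scores span the ranges
#: reported for motor tasks (broadband increases around +100%, strong
#: alpha/beta desynchronisation); signs are the defining contract.
DEFAULT_BAND_EFFECTS = {"hfb": 1.0, "alpha": -0.7, "beta": -0.6}


@dataclass(frozen=True)
class NoiseParams:
    """Noise and nuisance amplitudes for the simulated measurements.

    ecog_noise_sd      broadband ECoG noise SD, microvolts
    bold_noise_sd      hemodynamic noise SD per voxel, signal units; this
                       component is spatially smoothed by the ground-truth
                       point-spread width, like the signal it rides on
    bold_thermal_sd    spatially white (thermal) noise SD per voxel
    drift_amplitude    scale of the linear + slow-cosine drift, signal units
    ecog_slope         1/f spectral slope of the ECoG background noise
    drift_period_s     period of the slow cosine drift component
    """

    ecog_noise_sd: float = 40.0
    bold_noise_sd: float = 3.0
    bold_thermal_sd: float = 0.5
    drift_amplitude: float = 2.0
    ecog_slope: float = 1.0
    drift_period_s: float = 120.0


@dataclass(frozen=True)
class SyntheticScene:
    """A gray-matter slab with a planar electrode grid just above it."""

    gm_mask: np.ndarray
    affine: np.ndarray
    voxel_size: float
    electrode_names: tuple[str, ...]
    electrode_xyz: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.gm_mask, dtype=bool)
        object.__setattr__(self, "gm_mask", mask)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        object.__setattr__(
            self, "electrode_xyz", np.asarray(self.electrode_xyz, dtype=float)
        )
        if not mask.any():
            raise ValueError("gray-matter mask is empty")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if len(set(self.electrode_names)) != len(self.electrode_names):
            raise ValueError("electrode names must be unique")
        if self.electrode_xyz.shape != (len(self.electrode_names), 3):
            raise ValueError("electrode_xyz must be (n_electrodes, 3)")

    def gm_coords(self) -> np.ndarray:
        """World-mm coordinates of gray-matter voxel centers."""
        return apply_affine(self.affine, np.argwhere(self.gm_mask))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth activation field and generative parameters."""

    activation_field: np.ndarray  # 3D, zero outside GM, max 1
    sigma_true: float
    band_effects: dict
    noise: NoiseParams
    seed: int
    foci_xyz: np.ndarray
    focus_width_mm: float
    electrode_field: np.ndarray  # field sampled at the nearest GM voxel
    bold_amplitude: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")


def make_scene(
    grid_shape: tuple[int, int] = (8, 8),
    pitch_mm: float = 10.0,
    voxel_mm: float = 4.0,
    sheet_thickness_mm: float = 8.0,
    margin_mm: float = 20.0,
    electrode_height_mm: float = 1.5,
    seed: int = 0,
    jitter_mm: float = 1.0,
    rotation_deg: float | None = None,
) -> SyntheticScene:
    """Build a gray-matter slab with an electrode grid directly above it.

    The slab spans ``z in [-sheet_thickness_mm, 0)`` in world mm; electrodes
    sit on a regular ``grid_shape`` grid at ``pitch_mm`` spacing, centred at
    the origin in-plane, at ``z = electrode_height_mm``.  Two sources of
    geometric realism are applied from the seeded generator: the grid is
    rotated in-plane relative to the voxel lattice (a clinical grid is never
    aligned with scanner axes; ``rotation_deg=None`` draws an angle from
    5-40 degrees, or pass an explicit angle, 0 for none), and Gaussian
    jitter of SD ``jitter_mm`` (truncated at 2 SD) is applied per electrode
    in all three axes, emulating the couple of millimetres of localization
    scatter of real electrode coordinates; heights are clipped to stay above
    the slab.
    """
    if pitch_mm <= 0 or voxel_mm <= 0 or sheet_thickness_mm <= 0:
        raise ValueError("pitch, voxel size and thickness must be positive")
    gx, gy = grid_shape
    if gx < 1 or gy < 1:
        raise ValueError("grid_shape counts must be >= 1")
    extent_x = (gx - 1) * pitch_mm
    extent_y = (gy - 1) * pitch_mm
    nx = int(np.ceil((extent_x + 2 * margin_mm) / voxel_mm)) + 1
    ny = int(np.ceil((extent_y + 2 * margin_mm) / voxel_mm)) + 1
    nz_slab = int(np.round(sheet_thickness_mm / voxel_mm))
    if nz_slab < 1:
        raise ValueError("slab is empty at the requested voxel resolution")
    pad_z = max(int(np.ceil(8.0 / voxel_mm)), 2)
    nz = nz_slab + 2 * pad_z
    # voxel index (i, j, k) maps to the voxel *center* in world mm
    origin = np.array(
        [
            -(nx - 1) * voxel_mm / 2.0,
            -(ny - 1) * voxel_mm / 2.0,
            -(pad_z + nz_slab - 0.5) * voxel_mm,
        ]
    )
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = origin
    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[:, :, pad_z : pad_z + nz_slab] = True

    rng = np.random.default_rng(seed)
    if rotation_deg is None:
        rotation_deg = float(rng.uniform(5.0, 40.0))
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    xs = (np.arange(gx) - (gx - 1) / 2.0) * pitch_mm
    ys = (np.arange(gy) - (gy - 1) / 2.0) * pitch_mm
    names, xyz = [], []
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            names.append(f"G{i * gy + j + 1:03d}")
            if jitter_mm > 0:
                dx, dy, dz = np.clip(
                    rng.normal(0.0, jitter_mm, 3), -2 * jitter_mm, 2 * jitter_mm
                )
            else:
                dx = dy = dz = 0.0
            px, py = rot @ np.array([x, y])
            xyz.append(
                [px + dx, py + dy, max(electrode_height_mm + dz, 0.25)]
            )
    return SyntheticScene(mask, affine, voxel_mm, tuple(names), np.array(xyz))


def _nearest_gm_value(scene: SyntheticScene, field: np.ndarray, xyz: np.ndarray):
    coords = scene.gm_coords()
    vals = field[scene.gm_mask]
    out = np.empty(len(xyz))
    for i, p in enumerate(xyz):
        d2 = ((coords - p) ** 2).sum(axis=1)
        out[i] = vals[np.argmin(d2)]
    return out


def make_truth(
    scene: SyntheticScene,
    n_foci: int = 2,
    focus_width_mm: float = 16.0,
    sigma_true: float = 4.0,
    seed: int = 0,
    band_effects: dict | None = None,
    noise: NoiseParams = NoiseParams(),
    bold_amplitude: float = 3.0,
) -> SyntheticTruth:
    """Place Gaussian activation foci in the gray matter under the grid.

    The activation field is a sum of isotropic Gaussian bumps of width
    ``focus_width_mm`` centred at randomly chosen gray-matter voxel centers
    inside the electrode grid's in-plane footprint, normalised to max 1.
    """
    if n_foci < 1:
        raise ValueError("n_foci must be >= 1")
    if focus_width_mm <= 0 or sigma_true <= 0:
        raise ValueError("widths must be positive")
    effects = dict(DEFAULT_BAND_EFFECTS if band_effects is None else band_effects)
    rng = np.random.default_rng(seed)
    coords = scene.gm_coords()
    exyz = scene.electrode_xyz
    # candidate foci: gray matter actually under the grid, i.e. within one
    # inter-electrode pitch (in-plane) of some electrode
    d2_inplane = (
        (coords[:, None, :2] - exyz[None, :, :2]) ** 2
    ).sum(axis=2).min(axis=1)
    pitches = np.sqrt(((exyz[:, None, :2] - exyz[None, :, :2]) ** 2).sum(axis=2))
    pitch = (
        float(np.min(pitches[pitches > 0])) if len(exyz) > 1 else 2.0 * scene.voxel_size
    )
    inside = d2_inplane <= pitch**2
    candidates = coords[inside] if inside.any() else coords
    foci = candidates[rng.choice(len(candidates), size=n_foci, replace=False)]
    field3d = np.zeros(scene.gm_mask.shape)
    acc = np.zeros(len(coords))
    for f in foci:
        d2 = ((coords - f) ** 2).sum(axis=1)
        acc += np.exp(-d2 / (2.0 * focus_width_mm**2))
    acc /= acc.max()
    field3d[scene.gm_mask] = acc
    efield = _nearest_gm_value(scene, field3d, exyz)
    return SyntheticTruth(
        field3d,
        float(sigma_true),
        effects,
        noise,
        int(seed),
        foci,
        float(focus_width_mm),
        efield,
        float(bold_amplitude),
    )


def _one_over_f_noise(rng, n_ch: int, n_samp: int, fs: float, slope: float, sd: float):
    """Gaussian noise with power spectral density proportional to 1/f^slope."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-slope / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samp, axis=-1)
    shaped *= sd / shaped.std(axis=-1, keepdims=True)
    return shaped


def simulate_ecog(
    scene: SyntheticScene,
    truth: SyntheticTruth,
    design: TaskDesign,
    fs: float = 512.0,
    bands=DEFAULT_BANDS,
    artifact_channels: tuple[str, ...] = (),
    artifact_gain: float = 30.0,
) -> EcogRecording:
    """Simulate the multichannel ECoG recording for the task design.

    Each channel is independent 1/f background noise.  The noise is split
    spectrally into in-band and out-of-band components (brick-wall masks on
    the full-recording spectrum); during movement blocks the in-band
    component of band ``b`` is rescaled so that the channel's band power is
    multiplied by ``1 + band_effects[b] * field(electrode)``.  Channels named
    in ``artifact_channels`` are multiplied by ``artifact_gain`` to emulate
    high-variance artifact channels.
    """
    top = max(b.f_hi for b in bands)
    if fs < 2.0 * top:
        raise ValueError(
            f"sampling rate {fs} Hz is below 2x the top analysis frequency "
            f"({top} Hz, band "
            f"{max(bands, key=lambda b: b.f_hi).name!r})"
        )
    if design.total_duration <= 0:
        raise ValueError("design has zero duration")
    for b in bands:
        eff = truth.band_effects.get(b.name, 0.0)
        if np.any(1.0 + eff * truth.electrode_field <= 0):
            raise ValueError(f"band effect for {b.name!r} drives power non-positive")
    n_ch = len(scene.electrode_names)
    n_samp = int(round(design.total_duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 20210806]))
    noise = _one_over_f_noise(
        rng, n_ch, n_samp, fs, truth.noise.ecog_slope, truth.noise.ecog_noise_sd
    )
    spec = np.fft.rfft(noise, axis=-1)
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    t = np.arange(n_samp) / fs
    moving = design.movement_indicator(t).astype(bool)
    out = noise.copy()
    for b in bands:
        eff = truth.band_effects.get(b.name, 0.0)
        mask = (f >= b.f_lo) & (f <= b.f_hi)
        component = np.fft.irfft(spec * mask, n=n_samp, axis=-1)
        gain = np.sqrt(1.0 + eff * truth.electrode_field)  # per channel
        out += component * ((gain[:, None] - 1.0) * moving[None, :])
    for name in artifact_channels:
        out[scene.electrode_names.index(name)] *= artifact_gain
    return EcogRecording(out, fs, scene.electrode_names, reference="raw")


def gm_blur(field: np.ndarray, gm_mask: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Gray-matter-restricted Gaussian blur with mass-conserving weights.

    Each gray-matter voxel's field mass is redistributed over gray-matter
    voxels with Gaussian weights normalised per *source* voxel:
    ``out_i = sum_j k_ij f_j / s_j`` with ``s_j = sum_{i in GM} k_ij``.
    This renormalisation makes the blur conserve the total field mass over
    the mask exactly (up to the 6-sigma kernel truncation).
    """
    gm = np.asarray(gm_mask, dtype=bool)
    if sigma_vox < 1e-3:
        return np.where(gm, field, 0.0)
    kw = dict(sigma=sigma_vox, mode="constant", cval=0.0, truncate=6.0)
    s = ndimage.gaussian_filter(gm.astype(float), **kw)
    g = np.where(gm, field / np.maximum(s, 1e-300), 0.0)
    out = ndimage.gaussian_filter(g, **kw)
    return np.where(gm, out, 0.0)


def simulate_bold(
    scene: SyntheticScene,
    truth: SyntheticTruth,
    design: TaskDesign,
    tr: float = 0.608,
    baseline: float = 100.0,
    hrf_params: HrfParams = HrfParams(),
) -> BoldSeries:
    """Simulate the 4D BOLD series for the task design.

    The spatial amplitude map is the truth field blurred with
    :func:`gm_blur` at width ``sigma_true``; each gray-matter voxel's time
    series is ``baseline + amplitude * (boxcar (x) HRF) + drift + noise``
    with a per-voxel random linear drift and a slow cosine (drift period from
    the noise parameters).  The noise has two components: hemodynamic noise
    that is spatially smoothed by the same point-spread width ``sigma_true``
    as the signal (the vascular blur acts on everything hemodynamic), and a
    spatially white thermal component.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    n_vols = int(np.floor(design.total_duration / tr))
    amp = gm_blur(truth.activation_field, scene.gm_mask, truth.sigma_true / scene.voxel_size)
    reg = build_regressor(design, tr, n_vols, hrf_params=hrf_params, center=False)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 20210807]))
    gm = scene.gm_mask
    n_gm = int(gm.sum())
    t = np.arange(n_vols) * tr
    ramp = (t - t.mean()) / t.max()
    cosine = np.cos(2 * np.pi * t / truth.noise.drift_period_s)
    sigma_vox = truth.sigma_true / scene.voxel_size

    def _smooth_field(vol: np.ndarray) -> np.ndarray:
        if sigma_vox < 1e-3:
            return vol
        return ndimage.gaussian_filter(
            vol,
            sigma=(sigma_vox,) * 3 + (0.0,) * (vol.ndim - 3),
            mode="constant",
            truncate=4.0,
        )

    def _unit_gm(vol: np.ndarray) -> np.ndarray:
        flat = vol[gm]
        return flat / flat.std()

    # drift coefficients vary smoothly in space, like everything vascular
    c_ramp = _unit_gm(_smooth_field(rng.standard_normal(gm.shape)))
    c_cos = _unit_gm(_smooth_field(rng.standard_normal(gm.shape)))
    drift = (
        c_ramp[:, None] * ramp[None, :] + c_cos[:, None] * cosine[None, :]
    ) * truth.noise.drift_amplitude
    hemo = _unit_gm(_smooth_field(rng.standard_normal(gm.shape + (n_vols,))))
    noise = (
        hemo * truth.noise.bold_noise_sd
        + rng.standard_normal((n_gm, n_vols)) * truth.noise.bold_thermal_sd
    )
    series = (
        baseline
        + amp[gm][:, None] * truth.bold_amplitude * reg.raw[None, :]
        + drift
        + noise
    )
    data = np.zeros(gm.shape + (n_vols,))
    data[gm] = series
    return BoldSeries(data, scene.affine, tr)


# ---------------------------------------------------------------------------
# dataset writer (BIDS-like layout)
# ---------------------------------------------------------------------------


def write_subject(
    root: Path,
    subject: str,
    scene: SyntheticScene,
    truth: SyntheticTruth,
    ecog_design: TaskDesign,
    bold_design: TaskDesign,
    rec: EcogRecording,
    bold: BoldSeries,
) -> Path:
    """Write one subject's raw tree (electrodes/channels/events TSVs,
    ECoG matrix + sidecar, BOLD + GM mask NIfTI, truth JSON)."""
    import nibabel as nib
    import pandas as pd

    root = Path(root)
    sub = root / subject
    ieeg, func, anat = sub / "ieeg", sub / "func", sub / "anat"
    for d in (ieeg, func, anat):
        d.mkdir(parents=True, exist_ok=True)
    pre = f"{subject}_task-motor"

    pd.DataFrame(
        {
            "name": scene.electrode_names,
            "x": scene.electrode_xyz[:, 0],
            "y": scene.electrode_xyz[:, 1],
            "z": scene.electrode_xyz[:, 2],
        }
    ).to_csv(ieeg / f"{pre}_electrodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"name": rec.channel_names, "status": ["good"] * rec.n_channels}
    ).to_csv(ieeg / f"{pre}_channels.tsv", sep="\t", index=False)
    ecog_design.to_frame().to_csv(ieeg / f"{pre}_events.tsv", sep="\t", index=False)
    np.save(ieeg / f"{pre}_ieeg.npy", rec.samples)
    (ieeg / f"{pre}_ieeg.json").write_text(
        json.dumps(
            {
                "SamplingFrequency": rec.fs,
                "Reference": rec.reference,
                "ChannelOrder": list(rec.channel_names),
            },
            indent=2,
        )
    )

    bold_design.to_frame().to_csv(func / f"{pre}_events.tsv", sep="\t", index=False)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms((scene.voxel_size,) * 3 + (bold.tr,))
    nib.save(img, func / f"{pre}_bold.nii.gz")
    nib.save(
        nib.Nifti1Image(scene.gm_mask.astype(np.uint8), scene.affine),
        anat / f"{subject}_mask-gm.nii.gz",
    )
    (sub / f"{subject}_truth.json").write_text(
        json.dumps(
            {
                "sigma_true": truth.sigma_true,
                "band_effects": truth.band_effects,
                "noise": asdict(truth.noise),
                "seed": truth.seed,
                "focus_width_mm": truth.focus_width_mm,
                "bold_amplitude": truth.bold_amplitude,
                "foci_xyz": truth.foci_xyz.tolist(),
                "tr": bold.tr,
            },
            indent=2,
        )
    )
    return sub
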