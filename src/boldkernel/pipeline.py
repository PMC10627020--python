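"""Pipeline orchestration: simulate -> ecog -> fmri -> kernel -> group.

Each stage reads and writes a BIDS-like subject tree (raw data under
``<root>/<subject>/``, derived outputs under ``<root>/derivatives/``),
logs structured progress lines, and is idempotent: re-running with the same
configuration and seeds overwrites the same outputs deterministically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, synth
from .design import make_design
from .ecog import DEFAULT_BANDS, BandSpec, band_responses
from .fmri import HrfParams, bold_zmap
from .kernel import DEFAULT_TRUNC_K, kernel_curve

log = logging.getLogger("boldkernel")

__all__ = ["SynthConfig", "RunConfig", "GroupSummary", "simulate_subject",
           "ecog_stage", "fmri_stage", "kernel_stage", "run_subject",
           "aggregate_group", "load_config", "save_config"]


@dataclass
class SynthConfig:
    """Synthetic dataset parameters (defaults mirror the study conditions)."""

    grid_shape: tuple[int, int] = (8, 8)
    pitch_mm: float = 10.0
    voxel_mm: float = 4.0
    sheet_thickness_mm: float = 8.0
    fs: float = 512.0
    tr: float = 0.608
    block_s: float = 30.0
    ecog_blocks: tuple[int, int] = (5, 5)  # movement, rest
    bold_blocks: tuple[int, int] = (4, 5)
    n_foci: int = 2
    focus_width_mm: float = 16.0
    sigma_true: float = 4.0
    band_effects: dict = field(
        default_factory=lambda: dict(synth.DEFAULT_BAND_EFFECTS)
    )
    noise: synth.NoiseParams = field(default_factory=synth.NoiseParams)
    bold_amplitude: float = 3.0


@dataclass
class RunConfig:
    """Analysis parameters for every pipeline stage."""

    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    sigma_start: float = 1.0
    sigma_stop: float = 20.0
    sigma_step: float = 0.25
    alpha_electrode: float = 0.05
    window_s: float = 2.0
    reject_k_sd: float = 3.0
    highpass_sigma_s: float = 45.0
    trunc_k: float = DEFAULT_TRUNC_K
    derivative_step_mm: float = 1.0
    hrf: HrfParams = field(default_factory=HrfParams)
    welch: bool = False
    spearman: bool = False
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        if self.sigma_start <= 0 or self.sigma_stop <= self.sigma_start:
            raise ValueError("need 0 < sigma_start < sigma_stop")
        if self.sigma_step <= 0:
            raise ValueError("sigma_step must be positive")
        if not 0 < self.alpha_electrode < 1:
            raise ValueError("alpha_electrode must be in (0, 1)")

    @property
    def sigma_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.sigma_start, self.sigma_stop + 1e-9, self.sigma_step), 10
        )


def save_config(cfg: RunConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def load_config(path: Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "bands" in raw:
        raw["bands"] = tuple(BandSpec(**b) for b in raw["bands"])
    if "hrf" in raw:
        raw["hrf"] = HrfParams(**raw["hrf"])
    if "synth" in raw:
        s = dict(raw["synth"])
        if "noise" in s:
            s["noise"] = synth.NoiseParams(**s["noise"])
        for key in ("grid_shape", "ecog_blocks", "bold_blocks"):
            if key in s:
                s[key] = tuple(s[key])
        raw["synth"] = SynthConfig(**s)
    return RunConfig(**raw)


def _stage(subject: str, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("subject=%s stage=%s status=start", subject, name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            status = "error" if exc else "done"
            log.info("subject=%s stage=%s status=%s elapsed=%.2fs",
                     subject, name, status, dt)
            return False

    return _Timer()


def simulate_subject(root: Path, subject: str, cfg: RunConfig, seed: int) -> Path:
    """Generate and write one synthetic subject (ECoG + BOLD + metadata)."""
    s = cfg.synth
    with _stage(subject, "simulate"):
        scene = synth.make_scene(
            grid_shape=s.grid_shape, pitch_mm=s.pitch_mm, voxel_mm=s.voxel_mm,
            sheet_thickness_mm=s.sheet_thickness_mm, seed=seed,
        )
        truth = synth.make_truth(
            scene, n_foci=s.n_foci, focus_width_mm=s.focus_width_mm,
            sigma_true=s.sigma_true, seed=seed, band_effects=s.band_effects,
            noise=s.noise, bold_amplitude=s.bold_amplitude,
        )
        ecog_design = make_design(*s.ecog_blocks, s.block_s)
        bold_design = make_design(*s.bold_blocks, s.block_s)
        rec = synth.simulate_ecog(scene, truth, ecog_design, fs=s.fs, bands=cfg.bands)
        bold = synth.simulate_bold(scene, truth, bold_design, tr=s.tr)
        return synth.write_subject(
            root, subject, scene, truth, ecog_design, bold_design, rec, bold
        )


def ecog_stage(root: Path, subject: str, cfg: RunConfig) -> Path:
    """Per-electrode band z-scores -> ``<subject>_electrodes_response.tsv``."""
    p = io.subject_paths(root, subject)
    with _stage(subject, "ecog"):
        channels = io.read_channels(p["channels"])
        rec = io.read_ecog(p["ecog_data"], p["ecog_sidecar"], channels)
        design = io.read_events(p["ecog_events"])
        electrodes = io.read_electrodes(p["electrodes"])
        resp = band_responses(
            rec, design, electrodes.rename(columns=str.lower),
            bands=cfg.bands, win_s=cfg.window_s,
            alpha_electrode=cfg.alpha_electrode, k_sd=cfg.reject_k_sd,
            equal_var=not cfg.welch,
        )
        out = p["derivatives"]
        out.mkdir(parents=True, exist_ok=True)
        dest = out / f"{subject}_electrodes_response.tsv"
        resp.to_csv(dest, sep="\t", index=False)
        n_sig = int(resp["significant"].sum())
        log.info("subject=%s stage=ecog electrodes=%d significant=%d",
                 subject, len(resp), n_sig)
        return dest


def fmri_stage(root: Path, subject: str, cfg: RunConfig) -> Path:
    """GM-restricted GLM z-map -> ``<subject>_zmap.nii.gz`` + summary TSV."""
    import nibabel as nib

    p = io.subject_paths(root, subject)
    with _stage(subject, "fmri"):
        bold, mask = io.read_bold(p["bold"], p["gm_mask"])
        design = io.read_events(p["bold_events"])
        zmap = bold_zmap(bold, design, mask,
                         highpass_sigma_s=cfg.highpass_sigma_s, hrf_params=cfg.hrf)
        out = p["derivatives"]
        out.mkdir(parents=True, exist_ok=True)
        dest = out / f"{subject}_zmap.nii.gz"
        nib.save(nib.Nifti1Image(zmap.z.astype(np.float32), zmap.affine), dest)
        nib.save(
            nib.Nifti1Image(zmap.gm_mask.astype(np.uint8), zmap.affine),
            out / f"{subject}_zmap_mask.nii.gz",
        )
        pd.DataFrame([zmap.summary()]).to_csv(
            out / f"{subject}_zmap_summary.tsv", sep="\t", index=False
        )
        return dest


def kernel_stage(root: Path, subject: str, cfg: RunConfig) -> Path:
    """Kernel-width sweep per band -> curve TSVs + ``kernel_summary.json``.

    A band with fewer than 3 significant electrodes is marked skipped in the
    summary; the other bands complete.
    """
    p = io.subject_paths(root, subject)
    out = p["derivatives"]
    with _stage(subject, "kernel"):
        from .fmri import ZMap

        zvol, affine = io.read_gm_mask(out / f"{subject}_zmap_mask.nii.gz")
        import nibabel as nib

        zimg = nib.load(str(out / f"{subject}_zmap.nii.gz"))
        zmap = ZMap(np.asarray(zimg.dataobj, dtype=float), zvol, zimg.affine)
        resp = pd.read_csv(out / f"{subject}_electrodes_response.tsv", sep="\t")
        summary: dict = {"subject": subject, "bands": {}}
        for band in cfg.bands:
            tab = resp[resp["band"] == band.name]
            try:
                curve = kernel_curve(
                    zmap, tab, sigma_grid=cfg.sigma_grid, trunc_k=cfg.trunc_k,
                    spearman=cfg.spearman,
                    derivative_step_mm=cfg.derivative_step_mm,
                )
            except ValueError as err:
                log.warning("subject=%s stage=kernel band=%s skipped: %s",
                            subject, band.name, err)
                summary["bands"][band.name] = {"skipped": True, "reason": str(err)}
                continue
            curve.to_frame().to_csv(
                out / f"{subject}_band-{band.name}_kernel_curve.tsv",
                sep="\t", index=False,
            )
            summary["bands"][band.name] = {"skipped": False, **curve.summary()}
        dest = out / f"{subject}_kernel_summary.json"
        dest.write_text(json.dumps(summary, indent=2))
        return dest


def run_subject(root: Path, subject: str, cfg: RunConfig,
                simulate: bool = False, seed: int | None = None) -> dict:
    """Run every stage for one subject and return its kernel summary.

    The effective configuration is serialised next to the outputs for
    provenance.  Raises with subject context if a required input is missing.
    """
    root = Path(root)
    p = io.subject_paths(root, subject)
    p["derivatives"].mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(p["derivatives"] / f"{subject}_pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        if simulate:
            simulate_subject(root, subject, cfg, cfg.seed if seed is None else seed)
        if not p["subject_dir"].exists():
            raise FileNotFoundError(f"subject directory missing: {p['subject_dir']}")
        ecog_stage(root, subject, cfg)
        fmri_stage(root, subject, cfg)
        kernel_stage(root, subject, cfg)
        save_config(cfg, p["derivatives"] / f"{subject}_config.yaml")
    finally:
        log.removeHandler(handler)
        handler.close()
    return json.loads((p["derivatives"] / f"{subject}_kernel_summary.json").read_text())


@dataclass(frozen=True)
class GroupSummary:
    """Across-subject statistics of the kernel-width estimates, per band."""

    table: pd.DataFrame  # one row per subject x band
    stats: pd.DataFrame  # one row per band

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_subject": self.table.to_dict(orient="records"),
                "per_band": self.stats.to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )


def aggregate_group(summaries: list[dict]) -> GroupSummary:
    """Aggregate per-subject kernel summaries into group statistics.

    Peak statistics exclude subjects whose peak sits on the grid boundary
    (a boundary argmax is censored, not estimated); concavity statistics
    exclude subjects with a missing concavity point.  Excluded subjects are
    counted in the report.  Standard deviations use the sample (n-1)
    formula and are missing for a single subject.
    """
    rows = []
    for s in summaries:
        for band, v in s.get("bands", {}).items():
            if v.get("skipped"):
                rows.append({"subject": s["subject"], "band": band, "skipped": True})
                continue
            rows.append(
                {
                    "subject": s["subject"],
                    "band": band,
                    "skipped": False,
                    "n_electrodes": v["n_electrodes"],
                    "peak_sigma": v["peak_sigma"],
                    "peak_r2": v["peak_r2"],
                    "peak_on_boundary": v["peak_on_boundary"],
                    "slope_at_peak": v["slope_at_peak"],
                    "concavity_sigma": v["concavity_sigma"],
                    "concavity_r2": v["concavity_r2"],
                    "concavity_missing": v["concavity_missing"],
                }
            )
    table = pd.DataFrame(rows)
    usable = table[~table.get("skipped", False).astype(bool)]
    if len(usable) == 0:
        raise ValueError("no unflagged subject summaries to aggregate")

    def _stats(g: pd.DataFrame) -> pd.Series:
        peaks = g.loc[~g["peak_on_boundary"].astype(bool), "peak_sigma"]
        concs = g.loc[~g["concavity_missing"].astype(bool), "concavity_sigma"].dropna()
        conc_r2 = g.loc[~g["concavity_missing"].astype(bool), "concavity_r2"].dropna()
        return pd.Series(
            {
                "n_subjects": len(g),
                "n_peak_boundary_excluded": int(g["peak_on_boundary"].sum()),
                "n_concavity_missing": int(g["concavity_missing"].sum()),
                "peak_sigma_mean": peaks.mean(),
                "peak_sigma_sd": peaks.std(ddof=1) if len(peaks) > 1 else np.nan,
                "peak_sigma_min": peaks.min(),
                "peak_sigma_max": peaks.max(),
                "peak_r2_mean": g["peak_r2"].mean(),
                "peak_r2_sd": g["peak_r2"].std(ddof=1) if len(g) > 1 else np.nan,
                "concavity_sigma_mean": concs.mean(),
                "concavity_sigma_sd": concs.std(ddof=1) if len(concs) > 1 else np.nan,
                "concavity_r2_mean": conc_r2.mean(),
                "slope_mean": g["slope_at_peak"].mean(),
                "n_slope_positive": int((g["slope_at_peak"] > 0).sum()),
                "n_slope_negative": int((g["slope_at_peak"] < 0).sum()),
            }
        )

    stats = (
        usable.groupby("band", sort=False).apply(_stats, include_groups=False)
        .reset_index()
    )
    return GroupSummary(table, stats)


def write_group(root: Path, group: GroupSummary, histograms: bool = True) -> Path:
    """Write group outputs (TSV + JSON + per-band histograms) under derivatives."""
    out = Path(root) / "derivatives" / "group"
    out.mkdir(parents=True, exist_ok=True)
    group.table.to_csv(out / "group_table.tsv", sep="\t", index=False)
    group.stats.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    (out / "group_summary.json").write_text(group.to_json())
    if histograms:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        usable = group.table[~group.table.get("skipped", False).astype(bool)]
        for band, g in usable.groupby("band"):
            fig, axes = plt.subplots(1, 3, figsize=(9, 3))
            for ax, col, title in zip(
                axes,
                ["peak_sigma", "concavity_sigma", "peak_r2"],
                ["peak kernel width (mm)", "concavity width (mm)", "peak $r^2$"],
            ):
                vals = g[col].dropna()
                if len(vals):
                    ax.hist(vals, bins=10, color="steelblue", edgecolor="k")
                ax.set_xlabel(title)
            fig.suptitle(f"band {band}")
            fig.tight_layout()
            fig.savefig(out / f"group_band-{band}_hist.png", dpi=100)
            plt.close(fig)
    return out
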