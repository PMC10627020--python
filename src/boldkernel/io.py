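"""Readers and writers for the BIDS-like subject tree."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import TaskDesign
from .ecog import EcogRecording
from .fmri import BoldSeries

__all__ = [
    "read_events",
    "read_electrodes",
    "read_channels",
    "read_ecog",
    "read_bold",
    "read_gm_mask",
    "subject_paths",
]


def subject_paths(root: Path, subject: str) -> dict[str, Path]:
    root = Path(root)
    sub = root / subject
    pre = f"{subject}_task-motor"
    return {
        "subject_dir": sub,
        "electrodes": sub / "ieeg" / f"{pre}_electrodes.tsv",
        "channels": sub / "ieeg" / f"{pre}_channels.tsv",
        "ecog_events": sub / "ieeg" / f"{pre}_events.tsv",
        "ecog_data": sub / "ieeg" / f"{pre}_ieeg.npy",
        "ecog_sidecar": sub / "ieeg" / f"{pre}_ieeg.json",
        "bold_events": sub / "func" / f"{pre}_events.tsv",
        "bold": sub / "func" / f"{pre}_bold.nii.gz",
        "gm_mask": sub / "anat" / f"{subject}_mask-gm.nii.gz",
        "truth": sub / f"{subject}_truth.json",
        "derivatives": root / "derivatives" / subject,
    }


def _require(path: Path) -> Path:
    if not Path(path).exists():
        raise FileNotFoundError(f"required input file is missing: {path}")
    return Path(path)


def read_events(path: Path) -> TaskDesign:
    df = pd.read_csv(_require(path), sep="\t")
    return TaskDesign(
        tuple(df["onset"].astype(float)),
        tuple(df["duration"].astype(float)),
        tuple(df["trial_type"]),
    )


def read_electrodes(path: Path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t")
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"electrodes table {path} lacks columns {sorted(missing)}")
    return df


def read_channels(path: Path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t")
    if "status" not in df.columns:
        df["status"] = "good"
    return df


def read_ecog(data_path: Path, sidecar_path: Path, channels: pd.DataFrame) -> EcogRecording:
    """Load the ECoG matrix, honouring the channels table's status column."""
    samples = np.load(_require(data_path))
    meta = json.loads(_require(sidecar_path).read_text())
    names = tuple(meta.get("ChannelOrder", channels["name"].tolist()))
    rec = EcogRecording(samples, float(meta["SamplingFrequency"]), names,
                        reference=meta.get("Reference", "raw"))
    good = channels.loc[channels["status"] == "good", "name"].tolist()
    good = [n for n in rec.channel_names if n in good]
    if len(good) < rec.n_channels:
        rec = rec.pick(good)
    return rec


def read_gm_mask(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(_require(path)))
    return np.asarray(img.dataobj).astype(bool), img.affine


def read_bold(
    path: Path, gm_path: Path, tr: float | None = None
) -> tuple[BoldSeries, np.ndarray]:
    """Load the 4D BOLD and the GM mask, enforcing a shared affine.

    The repetition time is taken from the NIfTI header's fourth zoom unless
    ``tr`` overrides it.
    """
    img = nib.load(str(_require(path)))
    mask, mask_affine = read_gm_mask(gm_path)
    if not np.allclose(img.affine, mask_affine, atol=1e-6):
        raise ValueError("BOLD and gray-matter mask affines do not match")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"no repetition time in the header of {path}; pass tr")
    bold = BoldSeries(np.asarray(img.dataobj, dtype=float), img.affine, tr)
    return bold, mask
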