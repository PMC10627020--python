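"""Per-electrode band responses from multichannel ECoG.

Processing chain for one recording: variance-based channel screening,
common-average re-referencing, segmentation into fixed-length windows inside
condition blocks, Hanning-tapered log band power per window, and an unpaired
two-sample t-test (movement vs rest) per electrode and band, converted to a
signed z-score.

The pooled t statistic is computed in closed form here; scipy supplies only
the reference distributions (Student t, standard normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .design import MOVEMENT, REST, TaskDesign

Z_CAP = 38.0  # |z| ceiling; normal quantiles overflow beyond ~37.5

__all__ = [
    "EcogRecording",
    "BandSpec",
    "DEFAULT_BANDS",
    "TestResult",
    "reject_channels",
    "common_average_reference",
    "segment_windows",
    "band_log_power",
    "electrode_band_zscores",
    "band_responses",
    "Z_CAP",
]


@dataclass(frozen=True)
class BandSpec:
    """A closed frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name!r}: need 0 < f_lo < f_hi")


#: High-frequency broadband, alpha and beta — the three analysis bands.
DEFAULT_BANDS = (
    BandSpec("hfb", 65.0, 95.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 13.0, 30.0),
)


@dataclass(frozen=True)
class EcogRecording:
    """Multichannel ECoG samples (channels x time, microvolts)."""

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    reference: str = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2D channels x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != samples.shape[0]:
            raise ValueError("channel_names must align with sample rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.isnan(samples).any():
            raise ValueError("recording contains NaNs")
        if self.reference not in ("raw", "common_average"):
            raise ValueError("reference must be 'raw' or 'common_average'")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, names) -> "EcogRecording":
        idx = [self.channel_names.index(n) for n in names]
        return replace(
            self, samples=self.samples[idx], channel_names=tuple(names)
        )


def reject_channels(
    rec: EcogRecording, k_sd: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Screen channels whose variance is an outlier among the other channels.

    For each channel ``c`` the reference statistics are the mean and sample SD
    of the variances of every *other* channel (leave-one-out, single pass over
    the original set); ``c`` is rejected when its variance falls outside
    ``mean +/- k_sd * sd``.

    Returns the retained channel names and a per-channel report.
    """
    if rec.n_channels < 4:
        raise ValueError("channel rejection needs at least 4 channels")
    v = rec.samples.var(axis=1)
    n = rec.n_channels
    total, total_sq = v.sum(), (v**2).sum()
    rows = []
    for i, name in enumerate(rec.channel_names):
        mu = (total - v[i]) / (n - 1)
        ss = total_sq - v[i] ** 2 - (n - 1) * mu**2
        sd = np.sqrt(max(ss, 0.0) / (n - 2))
        rejected = bool(abs(v[i] - mu) > k_sd * sd)
        rows.append(
            {
                "channel": name,
                "variance": v[i],
                "others_mean": mu,
                "others_sd": sd,
                "rejected": rejected,
            }
        )
    report = pd.DataFrame(rows)
    retained = list(report.loc[~report.rejected, "channel"])
    return retained, report


def common_average_reference(
    rec: EcogRecording, retained: list[str] | None = None
) -> EcogRecording:
    """Re-reference each retained channel to the samplewise mean of the set."""
    names = tuple(retained) if retained is not None else rec.channel_names
    if len(names) == 0:
        raise ValueError("retained channel set is empty")
    sub = rec.pick(names)
    car = sub.samples - sub.samples.mean(axis=0, keepdims=True)
    return EcogRecording(car, rec.fs, names, reference="common_average")


def segment_windows(
    rec: EcogRecording, design: TaskDesign, win_s: float = 2.0
) -> dict[str, list[tuple[int, int]]]:
    """Tile non-overlapping windows inside each condition block.

    Windows start at each block onset and advance in steps of ``win_s``;
    windows that would cross a block boundary or run past the end of the
    recording are dropped.  Returns sample-index ranges per condition.
    """
    if win_s <= 0:
        raise ValueError("window length must be positive")
    win_n = int(round(win_s * rec.fs))
    out: dict[str, list[tuple[int, int]]] = {REST: [], MOVEMENT: []}
    for onset, dur, cond in zip(design.onsets, design.durations, design.conditions):
        n_win = int(np.floor(dur / win_s + 1e-9))
        for k in range(n_win):
            start = int(round((onset + k * win_s) * rec.fs))
            stop = start + win_n
            if stop <= rec.n_samples:
                out[cond].append((start, stop))
    if not out[REST] and not out[MOVEMENT]:
        raise ValueError("design yields no analysis windows for this recording")
    return out


def band_log_power(
    windows: np.ndarray, fs: float, band: BandSpec, psd_floor: float = 1e-30
) -> np.ndarray:
    """Mean log PSD over the band's frequency bins, per window.

    A Hanning taper is applied to each (mean-removed) window, the one-sided
    periodogram is evaluated on the window's natural frequency grid, each bin
    is log-transformed (natural log) and the bins with
    ``f_lo <= f <= f_hi`` (both edges inclusive) are averaged.

    ``windows`` may be of shape ``(n,)`` or ``(..., n)``; the window axis is
    last.  The window must be long enough for <= 0.5 Hz bins (2 s default).
    """
    windows = np.asarray(windows, dtype=float)
    n = windows.shape[-1]
    df = fs / n
    if df > 0.5 + 1e-9:
        raise ValueError(
            f"window of {n} samples at fs={fs} gives {df:.3f} Hz bins; need <= 0.5 Hz"
        )
    if not band.f_hi < fs / 2:
        raise ValueError(f"band {band.name!r} upper edge {band.f_hi} Hz >= Nyquist")
    freqs, psd = signal.periodogram(
        windows, fs=fs, window="hann", detrend="constant", axis=-1
    )
    sel = (freqs >= band.f_lo - 1e-9) & (freqs <= band.f_hi + 1e-9)
    psd_band = psd[..., sel]
    if np.any(psd_band <= psd_floor):
        warnings.warn(
            f"band {band.name!r}: PSD bins at or below floor {psd_floor:g}; "
            "log power floored",
            RuntimeWarning,
            stacklevel=2,
        )
        psd_band = np.maximum(psd_band, psd_floor)
    return np.log(psd_band).mean(axis=-1)


@dataclass(frozen=True)
class TestResult:
    """Movement-vs-rest test for one electrode/band."""

    t_stat: float
    p_value: float
    z_score: float
    significant: bool
    df: float


def _t_to_z(t: float, p: float, z_cap: float = Z_CAP) -> float:
    """Signed standard-normal quantile at the two-sided p of the t statistic."""
    if p <= 0:
        z = z_cap
    else:
        z = stats.norm.isf(p / 2.0)
    z = min(float(z), z_cap)
    return float(np.sign(t) * z) if t != 0 else 0.0


def electrode_band_zscores(
    powers_movement: np.ndarray,
    powers_rest: np.ndarray,
    alpha_electrode: float = 0.05,
    equal_var: bool = True,
    z_cap: float = Z_CAP,
) -> TestResult:
    """Unpaired two-sample t-test (movement minus rest) with a z conversion.

    The pooled (equal-variance) t is the default; Welch is available via
    ``equal_var=False``.  The z-score is the standard-normal quantile at
    ``1 - p/2`` carrying the sign of t, capped at ``+/- z_cap``.  Significance
    is the uncorrected two-sided ``p < alpha_electrode``.
    """
    x = np.asarray(powers_movement, dtype=float)
    y = np.asarray(powers_rest, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 windows per condition")
    d = x.mean() - y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = n1 + n2 - 2.0
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = (
            (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
            if se > 0
            else n1 + n2 - 2.0
        )
    if se == 0.0:
        if d == 0.0:
            return TestResult(0.0, 1.0, 0.0, False, df)
        warnings.warn(
            "zero pooled variance with unequal means; z capped", RuntimeWarning
        )
        t = np.sign(d) * np.inf
        return TestResult(float(t), 0.0, float(np.sign(d) * z_cap), True, df)
    t = float(d / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    z = _t_to_z(t, p, z_cap)
    return TestResult(t, p, z, bool(p < alpha_electrode), df)


def band_responses(
    rec: EcogRecording,
    design: TaskDesign,
    electrodes: pd.DataFrame,
    bands=DEFAULT_BANDS,
    win_s: float = 2.0,
    alpha_electrode: float = 0.05,
    k_sd: float = 3.0,
    equal_var: bool = True,
    reject: bool = True,
) -> pd.DataFrame:
    """Full ECoG stage: screen, re-reference, window, and test every band.

    ``electrodes`` is a table with columns ``name, x, y, z`` (world mm).
    Returns one row per retained electrode and band with columns
    ``electrode, band, t_stat, z_score, p_value, significant, x, y, z``.
    """
    if reject:
        retained, _ = reject_channels(rec, k_sd=k_sd)
    else:
        retained = list(rec.channel_names)
    car = common_average_reference(rec, retained)
    wins = segment_windows(car, design, win_s=win_s)
    if len(wins[MOVEMENT]) < 2 or len(wins[REST]) < 2:
        raise ValueError("need at least 2 windows per condition")

    def stack(ranges):
        return np.stack([car.samples[:, a:b] for a, b in ranges], axis=1)

    seg_m, seg_r = stack(wins[MOVEMENT]), stack(wins[REST])  # (ch, win, n)
    coords = electrodes.set_index("name")
    rows = []
    for band in bands:
        pm = band_log_power(seg_m, car.fs, band)
        pr = band_log_power(seg_r, car.fs, band)
        for i, name in enumerate(car.channel_names):
            if name not in coords.index:
                continue
            res = electrode_band_zscores(
                pm[i], pr[i], alpha_electrode=alpha_electrode, equal_var=equal_var
            )
            xyz = coords.loc[name]
            rows.append(
                {
                    "electrode": name,
                    "band": band.name,
                    "t_stat": res.t_stat,
                    "z_score": res.z_score,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "x": float(xyz["x"]),
                    "y": float(xyz["y"]),
                    "z": float(xyz["z"]),
                }
            )
    return pd.DataFrame(rows)
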