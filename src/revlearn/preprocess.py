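"""Pupil preprocessing: raw two-eye samples -> baseline-corrected 50 Hz epochs.

Cleaning order: eye-average, blink deletion (either-eye flag), 3-SD outlier
deletion with a 10-sample (40 ms) pad on each side, resampling to 50 Hz by
missing-aware 5-sample block means, linear interpolation of remaining gaps
(nearest-value extension at the edges) and Savitzky-Golay smoothing (frame 9,
order 4).  Epochs span -1 s ... +6 s around feedback on the 50 Hz grid (350
bins, feedback onset at bin 50) and are corrected by the mean of the 500 ms
pre-feedback window, which is retained as the per-trial nuisance covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "EPOCH_N_BINS",
    "EPOCH_START_S",
    "EPOCH_END_S",
    "CleanSeries",
    "clean_series",
    "epoch_and_baseline",
    "participant_exclusion",
]

OUT_RATE = 50.0
EPOCH_START_S = -1.0
EPOCH_END_S = 6.0
EPOCH_N_BINS = 350  # half-open [-1, 6) grid at 50 Hz
BASELINE_BINS = slice(25, 50)  # the 500 ms immediately preceding feedback
OUTLIER_SD = 3.0
OUTLIER_PAD = 10  # samples at the input rate (40 ms at 250 Hz)
SG_WINDOW = 9
SG_ORDER = 4
N_DROP_FIRST = 5


@dataclass
class CleanSeries:
    """Cleaned, interpolated and smoothed 50 Hz series."""

    time_s: np.ndarray
    value: np.ndarray
    interpolated: np.ndarray  # bool, per 50 Hz bin
    percent_interpolated: float
    n_deleted_input: int  # raw-rate samples removed before resampling


def _pad_mask(mask: np.ndarray, pad: int) -> np.ndarray:
    """Dilate a boolean deletion mask by ``pad`` samples on each side."""
    if not mask.any() or pad == 0:
        return mask
    idx = np.flatnonzero(mask)
    out = mask.copy()
    for i in idx:
        out[max(0, i - pad): i + pad + 1] = True
    return out


def clean_series(recording) -> CleanSeries:
    """Run the cleaning chain on a raw recording (see module docstring)."""
    left, right = recording.left, recording.right
    avg = (left + right) / 2.0

    # blink deletion: flagged on at least one eye
    missing = recording.left_blink | recording.right_blink | ~np.isfinite(avg)
    series = np.where(missing, np.nan, avg)
    if not np.isfinite(series).any():
        raise ValueError("series entirely missing")

    # 3-SD outlier deletion with +/- 10-sample padding, on the raw-rate series
    mu = np.nanmean(series)
    sd = np.nanstd(series)
    if sd > 0:
        outlier = np.abs(series - mu) > OUTLIER_SD * sd
        outlier &= ~np.isnan(series)
        deleted = _pad_mask(outlier, OUTLIER_PAD)
        series = np.where(deleted, np.nan, series)
        n_deleted = int((deleted & ~missing).sum())
    else:
        n_deleted = 0

    # resample to 50 Hz: missing-aware mean over non-overlapping 5-sample blocks
    block = int(round(recording.sample_rate / OUT_RATE))
    n_blocks = series.shape[0] // block
    trimmed = series[: n_blocks * block].reshape(n_blocks, block)
    counts = np.sum(np.isfinite(trimmed), axis=1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, np.nansum(trimmed, axis=1) / np.maximum(counts, 1), np.nan)
    t_blocks = recording.time_s[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)

    # linear interpolation of gaps; nearest-value extension at the edges
    interpolated = ~np.isfinite(values)
    good = np.flatnonzero(~interpolated)
    if good.size == 0:
        raise ValueError("series entirely missing after resampling")
    filled = np.interp(np.arange(n_blocks), good, values[good])

    smoothed = savgol_filter(filled, SG_WINDOW, SG_ORDER) if n_blocks >= SG_WINDOW else filled

    return CleanSeries(
        time_s=t_blocks,
        value=smoothed,
        interpolated=interpolated,
        percent_interpolated=100.0 * float(interpolated.mean()),
        n_deleted_input=n_deleted,
    )


def epoch_and_baseline(
    cleaned: CleanSeries,
    events: pd.DataFrame,
    drop_first: int = N_DROP_FIRST,
    drop_last: bool = True,
) -> pd.DataFrame:
    """Cut feedback-locked epochs and baseline-correct them.

    The first ``drop_first`` trials and the final trial are excluded.  Returns
    a long frame (trial, bin, time_s, value, baseline, interpolated_fraction)
    with exactly ``EPOCH_N_BINS`` rows per retained trial.  Raises if a
    retained trial's window exceeds the recording span.
    """
    offsets = EPOCH_START_S + np.arange(EPOCH_N_BINS) / OUT_RATE
    trials = events["trial"].to_numpy()
    onsets = events["feedback_onset_s"].to_numpy(float)
    keep = np.ones(trials.shape[0], dtype=bool)
    keep[:drop_first] = False
    if drop_last:
        keep[-1] = False

    t0, t1 = cleaned.time_s[0], cleaned.time_s[-1]
    frames = []
    for trial, onset in zip(trials[keep], onsets[keep]):
        times = onset + offsets
        if times[0] < t0 - 1.0 / OUT_RATE or times[-1] > t1 + 1.0 / OUT_RATE:
            raise ValueError(f"epoch window for trial {trial} exceeds recording span")
        vals = np.interp(times, cleaned.time_s, cleaned.value)
        interp_frac = float(np.interp(times, cleaned.time_s,
                                      cleaned.interpolated.astype(float)).mean())
        baseline = float(vals[BASELINE_BINS].mean())
        frames.append(pd.DataFrame({
            "trial": trial,
            "bin": np.arange(EPOCH_N_BINS),
            "time_s": offsets,
            "value": vals - baseline,
            "baseline": baseline,
            "interpolated_fraction": interp_frac,
        }))
    if not frames:
        return pd.DataFrame(columns=["trial", "bin", "time_s", "value",
                                     "baseline", "interpolated_fraction"])
    return pd.concat(frames, ignore_index=True)


def participant_exclusion(percent_interpolated, n_sd: float = 2.5) -> np.ndarray:
    """Flag participants whose interpolated % exceeds cohort mean + n_sd * SD.

    Flags apply to pupil analyses only; behavioral and model-fit outputs keep
    every participant.
    """
    pct = np.asarray(percent_interpolated, dtype=float)
    if pct.shape[0] < 2:
        raise ValueError("need at least two participants")
    sd = float(np.std(pct, ddof=1))
    if sd == 0.0:
        return np.zeros(pct.shape[0], dtype=bool)
    return pct > pct.mean() + n_sd * sd
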