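"""Synthetic two-eye pupil recordings with known ground-truth effect structure.

Generates 250 Hz left/right pupil-diameter streams around a simulated
session: a participant baseline plus a smooth feedback-locked evoked response
whose amplitude is a linear combination of feedback valence and the filter's
per-trial uncertainty estimates, with AR(1) noise, independent per-eye
measurement noise, and blink gaps.  Everything downstream (cleaning,
epoching, mixed-model statistics) is validated against these known effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "PupilGenSpec",
    "RawPupilRecording",
    "generate_recording",
    "inject_artifacts",
    "recording_to_tsv",
    "read_recording_tsv",
]


@dataclass(frozen=True)
class PupilGenSpec:
    sample_rate: float = 250.0
    baseline_mean: float = 4.0  # mm
    baseline_sd: float = 0.0  # across-participant spread, applied by caller
    kernel_shape: float = 2.0
    kernel_scale: float = 0.5  # seconds
    kernel_duration: float = 6.0  # seconds of kernel support kept
    b_feedback: float = 0.0  # mm added for negative feedback
    b_changeprob: float = 0.0  # mm per unit state change probability
    b_entropy: float = 0.0  # mm per bit of state entropy
    ar_coef: float = 0.97
    noise_sd: float = 0.01  # AR(1) innovation SD, mm
    eye_noise_sd: float = 0.02  # independent per-eye measurement noise, mm
    blink_rate: float = 0.1  # blinks per second
    blink_duration_mean: float = 0.15  # seconds
    blink_duration_sd: float = 0.05
    tail_s: float = 8.0  # recording continues this long after the last feedback

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if abs(self.ar_coef) >= 1:
            raise ValueError("AR coefficient must satisfy |phi| < 1")
        if self.blink_duration_mean <= 0:
            raise ValueError("blink durations must be positive")


@dataclass
class RawPupilRecording:
    """Raw sample stream plus the event channel (feedback onsets)."""

    time_s: np.ndarray
    left: np.ndarray
    right: np.ndarray
    left_blink: np.ndarray
    right_blink: np.ndarray
    events: pd.DataFrame  # trial, feedback_onset_s, feedback_sign, predictors
    sample_rate: float

    @property
    def n_samples(self) -> int:
        return self.time_s.shape[0]


def _evoked_kernel(spec: PupilGenSpec) -> np.ndarray:
    n = int(round(spec.kernel_duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    k = stats.gamma.pdf(t, a=spec.kernel_shape, scale=spec.kernel_scale)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_recording(
    spec: PupilGenSpec,
    session,
    estimates: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    baseline: float | None = None,
) -> RawPupilRecording:
    """Render one participant's recording for ``session``.

    ``estimates`` must carry ``state_change_probability`` and
    ``state_entropy`` aligned to the session's trials (NaNs treated as 0
    contribution).  The evoked amplitude of trial t is
    ``b_feedback * 1{negative} + b_changeprob * q_t + b_entropy * H_t``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(estimates) != session.n_trials:
        raise ValueError("session and estimates are not aligned")
    base = spec.baseline_mean if baseline is None else float(baseline)

    onsets = session.feedback_onset_s
    duration = float(onsets[-1] + spec.tail_s)
    n = int(round(duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    q = np.nan_to_num(estimates["state_change_probability"].to_numpy(float))
    h = np.nan_to_num(estimates["state_entropy"].to_numpy(float))
    negative = (session.reward < 0).astype(float)
    amp = spec.b_feedback * negative + spec.b_changeprob * q + spec.b_entropy * h

    clean = np.full(n, base)
    kernel = _evoked_kernel(spec)
    for onset, a in zip(onsets, amp):
        if a == 0.0:
            continue
        i0 = int(round(onset * spec.sample_rate))
        i1 = min(n, i0 + kernel.shape[0])
        if i0 < n:
            clean[i0:i1] += a * kernel[: i1 - i0]  # overlapping kernels sum

    if spec.noise_sd > 0:
        innov = rng.normal(0.0, spec.noise_sd, size=n)
        clean = clean + signal.lfilter([1.0], [1.0, -spec.ar_coef], innov)

    left = clean + (rng.normal(0.0, spec.eye_noise_sd, size=n) if spec.eye_noise_sd > 0 else 0.0)
    right = clean + (rng.normal(0.0, spec.eye_noise_sd, size=n) if spec.eye_noise_sd > 0 else 0.0)

    left_blink = np.zeros(n, dtype=bool)
    right_blink = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(spec.blink_rate * duration)
    for _ in range(n_blinks):
        onset = rng.uniform(0.0, duration)
        dur = max(0.02, rng.normal(spec.blink_duration_mean, spec.blink_duration_sd))
        i0 = int(onset * spec.sample_rate)
        i1 = min(n, i0 + max(1, int(dur * spec.sample_rate)))
        left_blink[i0:i1] = True
        right_blink[i0:i1] = True
    left = np.where(left_blink, np.nan, left)
    right = np.where(right_blink, np.nan, right)

    events = pd.DataFrame(
        {
            "trial": np.arange(1, session.n_trials + 1),
            "feedback_onset_s": onsets,
            "feedback_sign": np.where(negative > 0, -1, 1),
            "state_change_probability": estimates["state_change_probability"].to_numpy(float),
            "state_entropy": estimates["state_entropy"].to_numpy(float),
        }
    )
    return RawPupilRecording(
        time_s=t, left=left, right=right,
        left_blink=left_blink, right_blink=right_blink,
        events=events, sample_rate=spec.sample_rate,
    )


def inject_artifacts(
    recording: RawPupilRecording,
    n_spikes: int,
    magnitude_sd_units: float,
    seed: int | np.random.Generator = 0,
) -> tuple[RawPupilRecording, np.ndarray]:
    """Add isolated single-sample spikes at random non-blink positions.

    Magnitude is expressed in SDs of the eye-averaged series so the 3-SD
    outlier rule downstream is guaranteed (precondition: > 3) to fire.
    Returns the modified recording and the spike sample indices.
    """
    if n_spikes == 0:
        return recording, np.array([], dtype=int)
    if magnitude_sd_units <= 3:
        raise ValueError("spike magnitude must exceed 3 SD to be detectable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    avg = (recording.left + recording.right) / 2.0
    free = np.flatnonzero(~(recording.left_blink | recording.right_blink))
    if n_spikes > free.size:
        raise ValueError("more spikes than free samples")
    sd = float(np.nanstd(avg))
    # keep spikes isolated: resample until min separation > 25 samples
    for _ in range(100):
        idx = np.sort(rng.choice(free, size=n_spikes, replace=False))
        if n_spikes == 1 or np.min(np.diff(idx)) > 25:
            break
    left = recording.left.copy()
    right = recording.right.copy()
    left[idx] += magnitude_sd_units * sd
    right[idx] += magnitude_sd_units * sd
    out = dc_replace(recording, left=left, right=right)
    return out, idx


def recording_to_tsv(recording: RawPupilRecording, samples_path, events_path) -> None:
    pd.DataFrame(
        {
            "time_s": recording.time_s,
            "left_mm": recording.left,
            "right_mm": recording.right,
            "left_blink": recording.left_blink.astype(int),
            "right_blink": recording.right_blink.astype(int),
        }
    ).to_csv(samples_path, sep="\t", index=False)
    recording.events.to_csv(events_path, sep="\t", index=False)


def read_recording_tsv(samples_path, events_path, sample_rate: float = 250.0) -> RawPupilRecording:
    df = pd.read_csv(samples_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    return RawPupilRecording(
        time_s=df["time_s"].to_numpy(float),
        left=df["left_mm"].to_numpy(float),
        right=df["right_mm"].to_numpy(float),
        left_blink=df["left_blink"].to_numpy(bool),
        right_blink=df["right_blink"].to_numpy(bool),
        events=events,
        sample_rate=sample_rate,
    )
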