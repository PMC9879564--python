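"""EEG theta/beta-ratio pipeline at Fz and head-actigraphy metrics.

EEG processing: zero-phase low-pass at 35 Hz, per-channel linear detrend,
segmentation of each condition x phase subset into non-overlapping 5 s
epochs (mean-subtracted, amplitude-screened), continuous wavelet transform
(complex Morlet, ~6 cycles) on a log-spaced 85-frequency grid from 0.1 to
35 Hz evaluated on a 4 ms time grid, and finally mean theta (4-7 Hz) and
beta (13-30 Hz) power over 0.5-4.5 s of each epoch.  The theta/beta ratio
(TBR) is the ratio of those band means; it is invariant to any common gain
applied to the raw EEG.

Wavelet power is normalized per frequency (divided by the wavelet scale) so
that equal-amplitude sinusoids at different frequencies yield comparable
power, making band means commensurable across the log grid.

Head actigraphy: the ~90 Hz HMD position trace is anti-alias downsampled to
~10 Hz and summarized by the mean Euclidean distance between consecutive 3D
positions — a simple, translation- and rotation-invariant measure of head
movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import signal

from .session import Phase, PhaseSchedule, TimeSeriesStream, slice_stream

__all__ = [
    "TBRResult",
    "ActigraphySummary",
    "preprocess_eeg",
    "segment_eeg",
    "wavelet_power",
    "band_powers",
    "tbr",
    "tbr_pipeline",
    "head_displacement",
    "WAVELET",
    "CWT_FREQS",
]

EEG_RATE = 500.0
EPOCH_SECONDS = 5.0
CWT_TIME_STEP = 0.004        # 4 ms power grid
CWT_WINDOW = (0.5, 4.5)      # s within the epoch
THETA_BAND = (4.0, 7.0)
BETA_BAND = (13.0, 30.0)
AMPLITUDE_THRESHOLD_UV = 100.0

#: Complex Morlet; bandwidth 1.82 makes the Gaussian envelope span ~6 cycles
#: (sigma_t = n_cycles / (2 pi f) with n_cycles = 6).
WAVELET = "cmor1.82-1.0"
#: 85 log-spaced analysis frequencies, 0.1-35 Hz.
CWT_FREQS = np.geomspace(0.1, 35.0, 85)


@dataclass
class TBRResult:
    theta_power: float
    beta_power: float
    tbr: float
    n_segments_used: int
    n_segments_rejected: int
    condition: Optional[str] = None
    phase_type: Optional[str] = None


@dataclass
class ActigraphySummary:
    mean_displacement: float  # meters per downsampled step
    n_steps: int
    rate: float


def preprocess_eeg(recording: TimeSeriesStream, low_pass: float = 35.0
                   ) -> TimeSeriesStream:
    """Zero-phase Butterworth low-pass at ``low_pass`` Hz + linear detrend."""
    fs = recording.nominal_rate
    if fs < 2 * low_pass:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {low_pass} Hz low-pass")
    sos = signal.butter(4, low_pass, btype="low", fs=fs, output="sos")
    # detrend first: removing the drift before filtering avoids smearing
    # the ramp's edge transients through the zero-phase filter
    detrended = signal.detrend(recording.values, axis=0, type="linear")
    filtered = signal.sosfiltfilt(sos, detrended, axis=0)
    return TimeSeriesStream(
        name=recording.name, nominal_rate=fs, channels=recording.channels,
        timestamps=recording.timestamps, values=filtered,
    )


def segment_eeg(
    recording: TimeSeriesStream,
    schedule: PhaseSchedule,
    phase: Phase,
    epoch_seconds: float = EPOCH_SECONDS,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD_UV,
) -> tuple[list[np.ndarray], int]:
    """Non-overlapping epochs fully inside the given phase type.

    Each epoch is mean-subtracted per channel (baseline correction) and
    rejected if any sample on any channel exceeds ``amplitude_threshold`` µV
    in magnitude afterwards.  Returns ``(epochs, n_rejected)``; each epoch is
    an ``(n_samples, n_channels)`` array.
    """
    fs = recording.nominal_rate
    n_per = int(round(epoch_seconds * fs))
    epochs: list[np.ndarray] = []
    n_rejected = 0
    for start, end in schedule.windows(phase):
        sub = slice_stream(recording, start, end)
        n_epochs = int(len(sub) // n_per)
        for k in range(n_epochs):
            ep = sub.values[k * n_per:(k + 1) * n_per].copy()
            ep -= ep.mean(axis=0, keepdims=True)
            if np.abs(ep).max() > amplitude_threshold:
                n_rejected += 1
                continue
            epochs.append(ep)
    return epochs, n_rejected


def wavelet_power(
    epoch: np.ndarray,
    fs: float = EEG_RATE,
    freqs: np.ndarray = CWT_FREQS,
    time_step: float = CWT_TIME_STEP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CWT power of a 1-D epoch on the log frequency grid.

    Returns ``(power, freqs, times)`` with ``power`` of shape
    ``(n_freqs, n_times)`` evaluated every ``time_step`` seconds.  Power is
    scale-normalized so equal-amplitude sinusoids give comparable values
    across frequencies.
    """
    x = np.asarray(epoch, float)
    if x.ndim != 1:
        raise ValueError("wavelet_power expects a single-channel epoch")
    expected = int(round(EPOCH_SECONDS * fs))
    if x.shape[0] != expected:
        raise ValueError(
            f"epoch length {x.shape[0]} != {expected} samples "
            f"({EPOCH_SECONDS} s at {fs} Hz)")
    scales = pywt.frequency2scale(WAVELET, freqs / fs)
    coef, _ = pywt.cwt(x, scales, WAVELET, sampling_period=1.0 / fs)
    power = (np.abs(coef) ** 2) / scales[:, None]
    step = max(1, int(round(time_step * fs)))
    times = np.arange(x.shape[0])[::step] / fs
    return power[:, ::step], freqs, times


def band_powers(
    power: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = CWT_WINDOW,
    theta_band: tuple[float, float] = THETA_BAND,
    beta_band: tuple[float, float] = BETA_BAND,
) -> tuple[float, float]:
    """Mean theta and beta power over the analysis window."""
    tmask = (times >= window[0]) & (times <= window[1])
    th = (freqs >= theta_band[0]) & (freqs <= theta_band[1])
    be = (freqs >= beta_band[0]) & (freqs <= beta_band[1])
    return (float(power[np.ix_(th, tmask)].mean()),
            float(power[np.ix_(be, tmask)].mean()))


def tbr(theta_power: float, beta_power: float) -> float:
    """Theta/beta ratio; requires strictly positive beta power."""
    if beta_power <= 0:
        raise ValueError(f"beta power must be > 0, got {beta_power}")
    return theta_power / beta_power


def tbr_pipeline(
    recording: TimeSeriesStream,
    schedule: PhaseSchedule,
    phase: Phase,
    channel: str = "Fz",
    condition: Optional[str] = None,
    low_pass: float = 35.0,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD_UV,
) -> TBRResult:
    """Full per-(condition, phase) TBR: filter, epoch, CWT, band means.

    Band powers are averaged across retained epochs before the ratio is
    taken, mirroring "average power across segments".
    """
    clean = preprocess_eeg(recording, low_pass=low_pass)
    epochs, n_rej = segment_eeg(clean, schedule, phase,
                                amplitude_threshold=amplitude_threshold)
    if not epochs:
        raise ValueError(
            f"no artifact-free epochs for phase {phase} "
            f"({n_rej} rejected)")
    ch = clean.channels.index(channel)
    thetas, betas = [], []
    for ep in epochs:
        p, f, t = wavelet_power(ep[:, ch], fs=clean.nominal_rate)
        th, be = band_powers(p, f, t)
        thetas.append(th)
        betas.append(be)
    theta = float(np.mean(thetas))
    beta = float(np.mean(betas))
    return TBRResult(
        theta_power=theta, beta_power=beta, tbr=tbr(theta, beta),
        n_segments_used=len(epochs), n_segments_rejected=n_rej,
        condition=condition, phase_type=phase.value,
    )


def head_displacement(
    head: TimeSeriesStream,
    target_rate: float = 10.0,
) -> ActigraphySummary:
    """Mean consecutive-sample 3D displacement after downsampling to ~10 Hz.

    Downsampling uses block averaging (boxcar anti-aliasing) by the integer
    factor closest to ``nominal_rate / target_rate``: each output position
    is the mean of one block of consecutive input positions, which rejects
    above-Nyquist jitter without edge transients.  The metric is invariant
    to constant positional offsets and to global rotations of the frame.
    """
    if len(head) < 2:
        raise ValueError("head trace must contain at least two samples")
    duration = head.timestamps[-1] - head.timestamps[0]
    if duration <= 1.0:
        raise ValueError("head trace must span more than 1 s")
    factor = max(1, int(round(head.nominal_rate / target_rate)))
    if factor > 1:
        n_blocks = len(head) // factor
        pos = head.values[:n_blocks * factor].reshape(
            n_blocks, factor, -1).mean(axis=1)
    else:
        pos = head.values
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return ActigraphySummary(
        mean_displacement=float(steps.mean()) if steps.size else 0.0,
        n_steps=int(steps.size),
        rate=head.nominal_rate / factor,
    )
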