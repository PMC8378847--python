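"""Preprocessing of pulse-oximeter and breathing-belt recordings.

The pulse waveform is reduced to beat times, from which a beat-per-minute
heart-rate series is built on a uniform grid (default 10 Hz) and cleaned with
a Hampel outlier-replacement filter.  The breathing-belt trace is linearly
detrended, outlier-corrected, low-pass filtered at 5 Hz (zero-phase) and
z-scored; respiratory flow is the square of the derivative of a further
smoothed (1.5 s moving average) breathing signal, a non-negative measure of
the instantaneous magnitude of inhalation and exhalation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import PhysioRecording, UniformSeries, UnusableRecordingError

HAMPEL_MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian data


@dataclass
class PeakDetectionConfig:
    """Tunables for pulse-wave peak detection.

    ``min_prominence_frac``: minimum peak prominence as a fraction of the
    rolling signal amplitude (robust inter-quantile range).
    ``min_distance_frac``: minimum peak spacing as a fraction of the running
    inter-beat-interval estimate.
    """

    min_prominence_frac: float = 0.3
    min_distance_frac: float = 0.5
    rolling_window_s: float = 10.0
    hr_bounds_bpm: tuple[float, float] = (40.0, 200.0)


def detect_cardiac_peaks(
    recording: PhysioRecording, config: PeakDetectionConfig | None = None
) -> np.ndarray:
    """Detect heartbeat times (s) in the pulse-oximeter channel.

    Returns strictly increasing beat times.  Raises
    :class:`UnusableRecordingError` on flat or near-flat traces, or when
    fewer than two beats are found.
    """
    config = config or PeakDetectionConfig()
    if recording.duration < 10:
        raise ValueError("recording must be at least 10 s long")
    x = recording.cardiac
    amplitude = _rolling_amplitude(x, int(config.rolling_window_s * recording.fs))
    if np.median(amplitude) <= 1e-12 * max(1.0, np.abs(x).max()):
        raise UnusableRecordingError("flat cardiac trace")

    lo_bpm, hi_bpm = config.hr_bounds_bpm
    # first pass: distance bound from the fastest plausible heart rate
    min_dist = max(1, int(round(recording.fs * 60.0 / hi_bpm)))
    peaks, _ = signal.find_peaks(
        x, distance=min_dist, prominence=config.min_prominence_frac * amplitude
    )
    if peaks.size >= 3:
        # second pass: tighten spacing around the running rate estimate
        rr_est = np.median(np.diff(peaks)) / recording.fs
        rr_est = float(np.clip(rr_est, 60.0 / hi_bpm, 60.0 / lo_bpm))
        min_dist = max(1, int(round(config.min_distance_frac * rr_est * recording.fs)))
        peaks, _ = signal.find_peaks(
            x, distance=min_dist, prominence=config.min_prominence_frac * amplitude
        )
    if peaks.size < 2:
        raise UnusableRecordingError("fewer than two heartbeats detected")
    return recording.start_time + peaks / recording.fs


def _rolling_amplitude(x: np.ndarray, window: int) -> np.ndarray:
    window = max(3, window | 1)
    s = pd.Series(x)
    hi = s.rolling(window, center=True, min_periods=1).quantile(0.95)
    lo = s.rolling(window, center=True, min_periods=1).quantile(0.05)
    return (hi - lo).to_numpy()


def replace_outliers(series: np.ndarray, window: int = 11, n_sigmas: float = 3.0) -> np.ndarray:
    """Hampel filter: replace samples deviating from the rolling median by more
    than ``n_sigmas`` robust standard deviations (1.4826 x rolling MAD) with the
    rolling median.  Zero-MAD (locally constant) stretches are left unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(series, dtype=float)
    n = x.size
    w = min(window, n if n % 2 else n - 1)
    if w < 3:
        return x.copy()
    half = w // 2
    windows = np.lib.stride_tricks.sliding_window_view(np.pad(x, half, mode="reflect"), w)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    out = x.copy()
    # strict inequality keeps constant stretches (deviation 0) untouched even
    # where the MAD degenerates to 0
    bad = np.abs(x - med) > n_sigmas * HAMPEL_MAD_SCALE * mad
    out[bad] = med[bad]
    return out


def compute_heart_rate(
    beat_times: np.ndarray,
    out_fs: float = 10.0,
    hampel_window: int = 11,
    hampel_sigmas: float = 3.0,
) -> UniformSeries:
    """Heart rate in bpm on a uniform grid.

    HR is 60/RR at beat-interval midpoints.  Outlier replacement (Hampel) runs
    on the beatwise values — a single spurious beat is only an isolated
    outlier there — before linear interpolation to the ``out_fs`` grid with
    edge hold.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise ValueError("need at least two beats")
    rr = np.diff(beat_times)
    hr = 60.0 / rr
    if hr.size >= 3:
        w = min(hampel_window, hr.size if hr.size % 2 else hr.size - 1)
        hr = replace_outliers(hr, window=max(w, 3), n_sigmas=hampel_sigmas)
    mid = beat_times[:-1] + rr / 2.0
    grid = np.arange(beat_times[0], beat_times[-1], 1.0 / out_fs)
    values = np.interp(grid, mid, hr)  # np.interp holds edges
    return UniformSeries(values=values, fs=out_fs, start_time=float(grid[0]) if grid.size else 0.0)


def preprocess_respiration(
    recording: PhysioRecording,
    lowpass_hz: float = 5.0,
    hampel_window: int = 101,
    hampel_sigmas: float = 4.0,
) -> UniformSeries:
    """Clean the breathing-belt trace: linear detrend, outlier replacement,
    zero-phase low-pass at 5 Hz, z-score (mean 0, sd 1)."""
    if recording.duration < 10:
        raise ValueError("recording must be at least 10 s long")
    x = np.asarray(recording.respiratory, dtype=float)
    if np.std(x) == 0:
        raise UnusableRecordingError("zero-variance respiratory trace")
    x = signal.detrend(x, type="linear")
    x = replace_outliers(x, window=hampel_window, n_sigmas=hampel_sigmas)
    if lowpass_hz < recording.fs / 2:
        sos = signal.butter(4, lowpass_hz, btype="low", fs=recording.fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise UnusableRecordingError("respiratory trace constant after filtering")
    x = (x - x.mean()) / sd
    return UniformSeries(values=x, fs=recording.fs, start_time=recording.start_time)


def compute_respiratory_flow(
    cleaned_resp: UniformSeries, smooth_window: float = 1.5, out_fs: float = 10.0
) -> UniformSeries:
    """Respiratory flow: moving-average smooth (``smooth_window`` s), first
    difference divided by dt, square, resample to ``out_fs``.  Non-negative by
    construction."""
    x = cleaned_resp.values
    fs = cleaned_resp.fs
    n_smooth = max(1, int(round(smooth_window * fs)))
    if n_smooth > 1:
        kernel = np.ones(n_smooth) / n_smooth
        pad = n_smooth // 2
        xp = np.pad(x, pad, mode="edge")
        x = np.convolve(xp, kernel, mode="same")[pad : pad + cleaned_resp.values.size]
    flow = np.gradient(x) * fs
    flow = flow**2
    n_out = int(round(cleaned_resp.values.size * out_fs / fs))
    if n_out != flow.size:
        t_in = np.arange(flow.size) / fs
        t_out = np.arange(n_out) / out_fs
        flow = np.interp(t_out, t_in, flow)
    flow = np.maximum(flow, 0.0)
    return UniformSeries(values=flow, fs=out_fs, start_time=cleaned_resp.start_time)


def qc_exclude(
    hr_series_by_scan: dict[str, UniformSeries],
    beat_times_by_scan: dict[str, np.ndarray | None],
    rr_sd_threshold_s: float = 0.001,
) -> dict[str, bool]:
    """Per-subject keep/drop flags (True = keep).

    A subject is dropped when the median heart rate rounds to exactly 48 bpm
    while the inter-beat intervals show essentially no variability (a known
    hardware-failure signature), or when peak detection failed on any scan.
    """
    keep: dict[str, bool] = {}
    for scan_id, hr in hr_series_by_scan.items():
        beats = beat_times_by_scan.get(scan_id)
        if beats is None or len(beats) < 2:
            keep[scan_id] = False
            continue
        rr_sd = float(np.std(np.diff(np.asarray(beats, dtype=float))))
        median_hr = float(np.median(hr.values))
        flatline_48 = round(median_hr) == 48 and rr_sd < rr_sd_threshold_s
        keep[scan_id] = not flatline_48
    return keep
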