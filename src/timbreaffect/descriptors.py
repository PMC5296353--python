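"""Audio descriptor extraction (Timbre Toolbox style).

Computation proceeds in three stages:

1. input representations — the temporal energy envelope (amplitude of the
   analytic signal, low-pass filtered with a 3rd-order Butterworth at 5 Hz)
   and a short-time Fourier magnitude spectrogram whose bin centres are
   carried on an ERB-rate (auditory) frequency axis;
2. descriptors — three scalar temporal descriptors (log attack time,
   attack slope, temporal centroid, with the attack segment found by the
   weakest-effort threshold method) and ten spectral descriptor time
   series per frame (centroid, spread, skewness, kurtosis, slope,
   decrease, rolloff, variation, flatness, crest);
3. summarisation — median and interquartile range of each time series over
   the non-silent frames, giving 23 scalars per clip.

All spectral descriptors are computed from *magnitude* spectra on the
ERB-rate axis; only the 95% rolloff uses squared magnitude ("energy").
STFT bin 0 (DC) is excluded from every spectral descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .synth import AudioClip

log = logging.getLogger(__name__)

# STFT geometry: 23.2 ms Hamming window / 5.8 ms hop at 44.1 kHz rounds to
# 1024 / 256 samples.
WINDOW_SAMPLES = 1024
HOP_SAMPLES = 256
ENVELOPE_CUTOFF_HZ = 5.0
#: frames whose peak magnitude is below this (dB re clipwise max) are
#: treated as silent and excluded from descriptor time series
SILENCE_FLOOR_DB = -60.0

ATTACK_THRESHOLDS = np.arange(0.1, 0.91, 0.1)
ATTACK_EFFORT_MULTIPLIER = 3.0

#: Canonical 23 descriptor names, in output-column order.
CANONICAL_DESCRIPTORS = [
    "spec_centroid_med", "spec_centroid_iqr",
    "spec_spread_med", "spec_spread_iqr",
    "spec_skewness_med", "spec_skewness_iqr",
    "spec_kurtosis_med", "spec_kurtosis_iqr",
    "spec_slope_med", "spec_slope_iqr",
    "spec_decrease_med", "spec_decrease_iqr",
    "spec_rolloff_med", "spec_rolloff_iqr",
    "spec_variation_med", "spec_variation_iqr",
    "spec_flatness_med", "spec_flatness_iqr",
    "spec_crest_med", "spec_crest_iqr",
    "log_attack_time", "attack_slope", "temp_centroid",
]


class DescriptorError(ValueError):
    """Raised for inputs on which descriptors are undefined."""


# ---------------------------------------------------------------------------
# Stage 1a: temporal energy envelope
# ---------------------------------------------------------------------------


@dataclass
class TemporalEnvelope:
    times: np.ndarray
    values: np.ndarray
    sample_rate: int


def temporal_envelope(clip: AudioClip) -> TemporalEnvelope:
    """Amplitude of the analytic signal, low-pass filtered at 5 Hz.

    A zero-phase 3rd-order Butterworth is used so the envelope is not
    delayed relative to the waveform; negative post-filter excursions are
    clipped to zero.
    """
    x = np.asarray(clip.samples, dtype=float)
    if x.size == 0:
        raise DescriptorError("empty clip")
    analytic = np.abs(sp_signal.hilbert(x))
    sos = sp_signal.butter(3, ENVELOPE_CUTOFF_HZ, btype="low",
                           fs=clip.sample_rate, output="sos")
    env = sp_signal.sosfiltfilt(sos, analytic)
    env = np.clip(env, 0.0, None)
    times = np.arange(x.size) / clip.sample_rate
    return TemporalEnvelope(times=times, values=env, sample_rate=clip.sample_rate)


# ---------------------------------------------------------------------------
# Stage 2a: attack detection and temporal scalars
# ---------------------------------------------------------------------------


@dataclass
class AttackSegment:
    t_start: float
    t_end: float


def detect_attack(env: TemporalEnvelope,
                  thresholds: np.ndarray = ATTACK_THRESHOLDS,
                  effort_multiplier: float = ATTACK_EFFORT_MULTIPLIER) -> AttackSegment:
    """Weakest-effort attack estimation.

    First-crossing times are found at fixed fractions (10%..90%) of the
    envelope maximum; the "effort" of adjacent thresholds is the interval
    between their crossings.  The attack is bounded by the crossings whose
    efforts stay below ``effort_multiplier`` times the mean effort, which
    discards slow late portions (e.g. a gradual swell after a fast onset).
    Falls back to the direct 10%/90% crossings if the selection degenerates.
    """
    v = env.values
    peak = float(np.max(v))
    if peak <= 0:
        raise DescriptorError("envelope maximum must be positive")
    crossings = []
    for frac in thresholds:
        idx = np.argmax(v >= frac * peak)  # first index at/above threshold
        crossings.append(idx)
    crossings = np.asarray(crossings)
    dt = 1.0 / env.sample_rate

    efforts = np.diff(crossings).astype(float)
    valid = np.where(efforts <= effort_multiplier * max(np.mean(efforts), 0.0))[0]
    if valid.size == 0 or np.any(np.diff(crossings) < 0):
        log.warning("weakest-effort selection degenerate; falling back to 10/90 crossings")
        i_start, i_end = crossings[0], crossings[-1]
    else:
        i_start, i_end = crossings[valid[0]], crossings[valid[-1] + 1]
    t_start = i_start * dt
    t_end = max(i_end * dt, t_start + dt)  # enforce a strictly positive duration
    return AttackSegment(t_start=t_start, t_end=t_end)


def temporal_scalars(env: TemporalEnvelope, seg: AttackSegment
                     ) -> tuple[float, float, float]:
    """(log attack time, attack slope, temporal centroid).

    Log attack time is log10 of the attack duration in seconds; attack
    slope is the mean of the local envelope slopes over the attack;
    temporal centroid is the envelope's centre of gravity over the whole
    clip.
    """
    if seg.t_end <= seg.t_start:
        raise DescriptorError("zero-duration attack segment")
    dt = 1.0 / env.sample_rate
    lat = float(np.log10(seg.t_end - seg.t_start))
    i0 = int(round(seg.t_start * env.sample_rate))
    i1 = int(round(seg.t_end * env.sample_rate))
    i1 = min(max(i1, i0 + 1), len(env.values) - 1)
    slopes = np.diff(env.values[i0:i1 + 1]) / dt
    attack_slope = float(np.mean(slopes)) if slopes.size else 0.0
    total = float(np.sum(env.values))
    if total <= 0:
        raise DescriptorError("all-zero envelope")
    centroid = float(np.sum(env.times * env.values) / total)
    return lat, attack_slope, centroid


# ---------------------------------------------------------------------------
# Stage 1b: ERB-rate spectrogram
# ---------------------------------------------------------------------------


def erb_rate(f) -> np.ndarray | float:
    """Glasberg-Moore ERB-rate of frequency ``f`` (Hz):
    ``21.4 * log10(4.37 * f / 1000 + 1)``; strictly increasing, 0 at 0 Hz."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise DescriptorError("frequency must be nonnegative")
    out = 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ERBSpectrogram:
    frame_times: np.ndarray
    bin_freqs_hz: np.ndarray
    bin_freqs_erb: np.ndarray
    magnitudes: np.ndarray  # frames x bins
    silent: np.ndarray      # per-frame bool


def erb_spectrogram(clip: AudioClip,
                    window: int = WINDOW_SAMPLES,
                    hop: int = HOP_SAMPLES) -> ERBSpectrogram:
    """Hamming-window STFT magnitudes with bin centres on Hz and ERB axes.

    Frames are taken without padding: ``1 + floor((N - window) / hop)``
    frames for an N-sample clip.  The DC bin is dropped.  Frames whose peak
    magnitude falls below the silence floor (relative to the loudest frame)
    are flagged silent.
    """
    x = np.asarray(clip.samples, dtype=float)
    if x.size < window:
        raise DescriptorError("clip shorter than one analysis window")
    n_frames = 1 + (x.size - window) // hop
    win = np.hamming(window)
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    mags = np.abs(np.fft.rfft(frames, axis=1))[:, 1:]  # drop DC
    freqs_hz = np.fft.rfftfreq(window, 1.0 / clip.sample_rate)[1:]
    frame_times = (hop * np.arange(n_frames) + window / 2) / clip.sample_rate
    peaks = mags.max(axis=1)
    floor = peaks.max() * 10.0 ** (SILENCE_FLOOR_DB / 20.0)
    silent = peaks <= floor
    return ERBSpectrogram(frame_times=frame_times, bin_freqs_hz=freqs_hz,
                          bin_freqs_erb=erb_rate(freqs_hz), magnitudes=mags,
                          silent=silent)


# ---------------------------------------------------------------------------
# Stage 2b: frame-level spectral descriptors
# ---------------------------------------------------------------------------


def spectral_moments(mags: np.ndarray, freqs: np.ndarray
                     ) -> tuple[float, float, float, float]:
    """(centroid, spread, skewness, kurtosis) of one magnitude frame.

    Magnitudes are treated as a probability mass over the frequency axis
    (here ERB-rate), so all four moments are gain-invariant.  A single
    active bin has zero spread; skewness and kurtosis are then reported
    as 0.
    """
    total = float(np.sum(mags))
    if total <= 0:
        raise DescriptorError("all-zero frame")
    p = mags / total
    mu = float(np.sum(p * freqs))
    var = float(np.sum(p * (freqs - mu) ** 2))
    sigma = np.sqrt(var)
    if sigma == 0:
        return mu, 0.0, 0.0, 0.0
    skew = float(np.sum(p * (freqs - mu) ** 3) / sigma**3)
    kurt = float(np.sum(p * (freqs - mu) ** 4) / sigma**4)
    return mu, sigma, skew, kurt


def spectral_shape(mags: np.ndarray, freqs: np.ndarray
                   ) -> tuple[float, float, float, float, float]:
    """(slope, decrease, rolloff, flatness, crest) of one magnitude frame.

    Slope is the least-squares slope of magnitude against frequency;
    decrease averages the per-bin slopes from the first bin, weighted as
    ``sum_{k>=2}((a_k - a_1) / (k - 1)) / sum_{k>=2} a_k``; rolloff is the
    lowest frequency below which 95% of the squared-magnitude energy lies;
    flatness is the geometric/arithmetic mean ratio; crest the max/mean
    ratio.
    """
    total = float(np.sum(mags))
    if total <= 0:
        raise DescriptorError("all-zero frame")
    K = mags.size
    if K == 1:
        return 0.0, 0.0, float(freqs[0]), 1.0, 1.0
    fbar = np.mean(freqs)
    denom = float(np.sum((freqs - fbar) ** 2))
    slope = float(np.sum((freqs - fbar) * (mags - np.mean(mags))) / denom)
    tail = float(np.sum(mags[1:]))
    if tail > 0:
        k = np.arange(2, K + 1)
        decrease = float(np.sum((mags[1:] - mags[0]) / (k - 1)) / tail)
    else:
        decrease = 0.0
    energy = np.cumsum(mags**2)
    roll_idx = int(np.searchsorted(energy, 0.95 * energy[-1]))
    rolloff = float(freqs[min(roll_idx, K - 1)])
    mean = total / K
    flatness = 0.0 if np.any(mags <= 0) else float(np.exp(np.mean(np.log(mags))) / mean)
    crest = float(np.max(mags) / mean)
    return slope, decrease, rolloff, flatness, crest


def spectral_variation(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """1 minus the normalised correlation of two successive magnitude
    frames; 0 for identical (or rescaled) frames, 1 for disjoint support."""
    na = float(np.sqrt(np.sum(frame_a**2)))
    nb = float(np.sqrt(np.sum(frame_b**2)))
    if na == 0 or nb == 0:
        raise DescriptorError("silent frame in variation pair")
    return float(1.0 - np.dot(frame_a, frame_b) / (na * nb))


def summarize_series(series) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolated percentiles) of
    one descriptor time series over retained frames."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise DescriptorError("empty descriptor series")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q75 - q25)


# ---------------------------------------------------------------------------
# Stage 3: full descriptor vector
# ---------------------------------------------------------------------------


def extract_all(clip: AudioClip) -> dict[str, float]:
    """Full 23-descriptor vector for one clip, keyed by canonical names.

    Spectral series are summarised by median/IQR over non-silent frames;
    the spectral-centroid median is log10-transformed (both it and attack
    time are modelled on log scales).
    """
    if not np.any(np.asarray(clip.samples) != 0):
        raise DescriptorError("silent clip")
    env = temporal_envelope(clip)
    seg = detect_attack(env)
    lat, aslope, tcent = temporal_scalars(env, seg)

    spec = erb_spectrogram(clip)
    keep = ~spec.silent
    frames = spec.magnitudes[keep]
    if frames.shape[0] == 0:
        raise DescriptorError("no non-silent frames")
    freqs = spec.bin_freqs_erb

    series: dict[str, list[float]] = {name: [] for name in
                                      ("centroid", "spread", "skewness", "kurtosis",
                                       "slope", "decrease", "rolloff", "flatness",
                                       "crest")}
    for m in frames:
        mu, sd, sk, ku = spectral_moments(m, freqs)
        sl, de, ro, fl, cr = spectral_shape(m, freqs)
        for name, val in zip(series, (mu, sd, sk, ku, sl, de, ro, fl, cr)):
            series[name].append(val)
    variation = [spectral_variation(a, b) for a, b in zip(frames[:-1], frames[1:])]

    out: dict[str, float] = {}
    for name, vals in series.items():
        med, iqr = summarize_series(vals)
        out[f"spec_{name}_med"] = med
        out[f"spec_{name}_iqr"] = iqr
    var_med, var_iqr = summarize_series(variation) if variation else (0.0, 0.0)
    out["spec_variation_med"] = var_med
    out["spec_variation_iqr"] = var_iqr
    out["spec_centroid_med"] = float(np.log10(out["spec_centroid_med"]))
    out["log_attack_time"] = lat
    out["attack_slope"] = aslope
    out["temp_centroid"] = tcent
    return {name: out[name] for name in CANONICAL_DESCRIPTORS}


def extract_matrix(clips) -> "pd.DataFrame":
    """Stimuli x 23 descriptor DataFrame, indexed by stimulus id."""
    import pandas as pd

    rows = {clip.stimulus_id or str(i): extract_all(clip)
            for i, clip in enumerate(clips)}
    return pd.DataFrame.from_dict(rows, orient="index")[CANONICAL_DESCRIPTORS]
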