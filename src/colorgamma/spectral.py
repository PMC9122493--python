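"""Baseline-normalized power-change spectra from virtual-dipole trials.

Trials are cut into a baseline (−1.0 to 0 s relative to stimulus onset) and a
stimulus (0.3 to 1.3 s) period, segmented into 50%-overlapping epochs of
500 ms (≤20 Hz analyses, single Hann taper) or 333 ms (>20 Hz analyses,
three Slepian tapers), demeaned, detrended, zero-padded to 1 s, and Fourier
transformed.  Percent power change is computed per frequency bin relative to
the trial-set-averaged baseline spectrum.  A sliding-window variant produces
a baseline-normalized time–frequency representation on a 0.25 Hz grid
(4 s zero-padding).

All tapers are scaled to unit energy and power is averaged (not summed)
across tapers, so the mean power of white noise across the full FFT grid
equals its variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend
from scipy.signal.windows import dpss, hann

BASELINE_WINDOW = (-1.0, 0.0)
STIMULUS_WINDOW = (0.3, 1.3)
LOW_BAND_WINDOW_S = 0.5
HIGH_BAND_WINDOW_S = 1.0 / 3.0
N_TAPERS_HIGH = 3
SMOOTHING_HZ = 3.0
PAD_TO_S = 1.0


@dataclass
class EpochSet:
    """Equal-length, detrended signal windows from one trial period."""

    epochs: np.ndarray  # (n_epochs, n_samples) or (n_dipoles, n_epochs, n_samples)
    fs: float
    window_len_s: float
    overlap: float
    period: str


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray
    n_segments: int = 1  # epochs*tapers(*trials) averaged into `power`


@dataclass
class PowerChangeSpectrum:
    freqs_hz: np.ndarray
    change_percent: np.ndarray


def _window_samples(fs: float, freq_band: str) -> int:
    if freq_band == "low":
        return int(round(fs * LOW_BAND_WINDOW_S))
    if freq_band == "high":
        return int(round(fs * HIGH_BAND_WINDOW_S))
    raise ValueError(f"unknown freq_band {freq_band!r}")


def segment_epochs(
    samples: np.ndarray,
    t0_index: int,
    fs: float,
    period: str,
    freq_band: str = "high",
) -> EpochSet:
    """Cut one period into 50%-overlapping, demeaned, detrended epochs.

    ``samples`` may be 1-D (one dipole) or 2-D (dipoles × time); epochs are
    taken identically along the last axis.
    """
    windows = {"baseline": BASELINE_WINDOW, "stimulus": STIMULUS_WINDOW}
    if period not in windows:
        raise ValueError(f"unknown period {period!r}")
    lo_s, hi_s = windows[period]
    start = t0_index + int(round(lo_s * fs))
    stop = t0_index + int(round(hi_s * fs))
    if start < 0 or stop > samples.shape[-1]:
        raise ValueError("trial does not cover the requested period")
    seg = samples[..., start:stop]
    win = _window_samples(fs, freq_band)
    if seg.shape[-1] < win:
        raise ValueError("period shorter than one analysis window")
    step = win // 2
    starts = range(0, seg.shape[-1] - win + 1, step)
    epochs = np.stack([seg[..., s : s + win] for s in starts], axis=-2)
    epochs = detrend(epochs, axis=-1, type="constant")
    epochs = detrend(epochs, axis=-1, type="linear")
    window_s = LOW_BAND_WINDOW_S if freq_band == "low" else HIGH_BAND_WINDOW_S
    return EpochSet(epochs, float(fs), window_s, 0.5, period)


def _tapers(n: int, fs: float, freq_band: str) -> np.ndarray:
    """Unit-energy taper bank, shape (n_tapers, n)."""
    if freq_band == "low":
        w = hann(n)
        return (w / np.sqrt(np.sum(w**2)))[None, :]
    nw = (n / fs) * SMOOTHING_HZ  # time–half-bandwidth for ±3 Hz
    w = dpss(n, nw, Kmax=N_TAPERS_HIGH)
    return w / np.sqrt(np.sum(w**2, axis=1, keepdims=True))


def epoch_power_spectrum(epochs: EpochSet, freq_band: str = "high") -> PowerSpectrum:
    """Multitaper power spectrum averaged over tapers and epochs.

    Zero-padding to 1 s gives a 1 Hz frequency grid.  Negative frequencies
    are folded in, so the power summed over the one-sided grid equals the
    tapered epoch energy — the signal variance, for unit-energy tapers.
    White noise therefore yields a flat spectrum summing to its variance.
    """
    e = np.asarray(epochs.epochs, dtype=float)
    if e.size == 0:
        raise ValueError("empty epoch set")
    n = e.shape[-1]
    fs = epochs.fs
    nfft = int(round(PAD_TO_S * fs))
    tapers = _tapers(n, fs, freq_band)
    # (..., n_epochs, n_tapers, n)
    tapered = e[..., :, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, n=nfft, axis=-1)
    power = np.abs(spec) ** 2
    # fold negative frequencies so the one-sided mean matches variance
    power[..., 1:] *= 2.0
    if nfft % 2 == 0:
        power[..., -1] /= 2.0
    power = power.mean(axis=tuple(range(power.ndim - 1))) / nfft
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    n_segments = int(np.prod(tapered.shape[:-1]))
    return PowerSpectrum(freqs, power, n_segments)


def average_power_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Weighted average of spectra on a common grid (weights = segment counts)."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs_hz
    for s in spectra[1:]:
        if not np.array_equal(s.freqs_hz, f0):
            raise ValueError("frequency grid mismatch")
    weights = np.array([s.n_segments for s in spectra], dtype=float)
    stack = np.stack([s.power for s in spectra])
    power = (stack * weights[:, None]).sum(axis=0) / weights.sum()
    return PowerSpectrum(f0, power, int(weights.sum()))


def power_change_spectrum(
    stim: PowerSpectrum, baseline_avg: PowerSpectrum
) -> PowerChangeSpectrum:
    """Percent power change per bin relative to the averaged baseline."""
    if not np.array_equal(stim.freqs_hz, baseline_avg.freqs_hz):
        raise ValueError("frequency grid mismatch between stimulus and baseline")
    if np.any(baseline_avg.power <= 0):
        raise ValueError("baseline power must be strictly positive at every bin")
    change = 100.0 * (stim.power - baseline_avg.power) / baseline_avg.power
    return PowerChangeSpectrum(stim.freqs_hz, change)


def band_power_change(
    change: PowerChangeSpectrum,
    peak_hz: float,
    mode: str = "band",
    halfwidth_hz: float = 10.0,
) -> float:
    """Change at the individual gamma peak: ±10 Hz band mean or nearest bin.

    Nearest-bin ties resolve to the lower frequency.
    """
    if not 15.0 <= peak_hz <= 120.0:
        raise ValueError("peak frequency outside the 15–120 Hz analysis range")
    f = change.freqs_hz
    if mode == "band":
        sel = (f >= peak_hz - halfwidth_hz) & (f <= peak_hz + halfwidth_hz)
        return float(change.change_percent[sel].mean())
    if mode == "bin":
        d = np.abs(f - peak_hz)
        # ties to the lower frequency
        idx = int(np.flatnonzero(d == d.min())[0])
        return float(change.change_percent[idx])
    raise ValueError(f"unknown mode {mode!r}")


def trial_change_spectrum(
    trials_samples: list[np.ndarray],
    t0_index: int,
    fs: float,
    freq_band: str = "high",
) -> PowerChangeSpectrum:
    """Trial-set power-change spectrum: each trial's stimulus and baseline
    spectra are computed, averaged over trials (and dipoles), and the change
    is taken relative to the per-trial-set average baseline.
    """
    stim = [
        epoch_power_spectrum(segment_epochs(s, t0_index, fs, "stimulus", freq_band), freq_band)
        for s in trials_samples
    ]
    base = [
        epoch_power_spectrum(segment_epochs(s, t0_index, fs, "baseline", freq_band), freq_band)
        for s in trials_samples
    ]
    return power_change_spectrum(average_power_spectra(stim), average_power_spectra(base))


def time_frequency(
    samples: np.ndarray,
    t0_index: int,
    fs: float,
    freq_band: str = "high",
    pad_to_s: float = 4.0,
    decimate_to_hz: float | None = 100.0,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window baseline-normalized time–frequency transform.

    Returns ``(times_s, freqs_hz, change_percent)`` with change of shape
    (n_freqs, n_times).  Windows are centered on each (decimated) timepoint;
    zero-padding to 4 s gives a 0.25 Hz grid.  Baseline per frequency is the
    mean power over timepoints whose windows lie fully inside the baseline.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n_samp = x.shape[-1]
    win = _window_samples(fs, freq_band)
    half = win // 2
    step = 1 if decimate_to_hz is None else max(1, int(round(fs / decimate_to_hz)))
    centers = np.arange(half, n_samp - (win - half) + 1, step)
    tapers = _tapers(win, fs, freq_band)
    nfft = int(round(pad_to_s * fs))
    # (n_dipoles, n_centers, win)
    idx = centers[:, None] + np.arange(win)[None, :] - half
    segs = x[:, idx]
    segs = detrend(detrend(segs, axis=-1, type="constant"), axis=-1, type="linear")
    tapered = segs[:, :, None, :] * tapers[None, None, :, :]
    power = (np.abs(np.fft.rfft(tapered, n=nfft, axis=-1)) ** 2).mean(axis=(0, 2)) / nfft
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    times = (centers - t0_index) / fs
    lo, hi = baseline_window
    in_base = (times - half / fs >= lo) & (times + (win - half) / fs <= hi)
    if not np.any(in_base):
        raise ValueError("no timepoint window lies fully inside the baseline")
    base = power[in_base].mean(axis=0)
    if np.any(base <= 0):
        raise ValueError("baseline power must be strictly positive")
    change = 100.0 * (power - base[None, :]) / base[None, :]
    return times, freqs, change.T
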