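"""Event-related field processing and N70 feature extraction.

Virtual-dipole traces are low-pass filtered with an acausal (zero-phase)
Gaussian kernel whose magnitude response is −6 dB at 80 Hz, z-scored against
the per-trial baseline (−1.0 to 0 s, computed before cutting), and cut to
−0.2 to 0.6 s.  Dipoles whose all-condition average trace is positive-going
during the N70 window (55–95 ms) are flipped, one sign per dipole shared by
every condition.  The N70 peak time is the minimum of the condition-average
trace between 50 and 110 ms; the component slope is the least-squares line
over 2–12 ms before the peak; per-trial amplitudes are means over ±10 ms
around the condition-average peak time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

CUT_WINDOW_S = (-0.2, 0.6)
ZSCORE_BASELINE_S = (-1.0, 0.0)
FLIP_WINDOW_MS = (55.0, 95.0)
PEAK_SEARCH_MS = (50.0, 110.0)
SLOPE_WINDOW_MS = (2.0, 12.0)  # before the peak
AMP_HALFWIDTH_MS = 10.0
LOWPASS_MINUS6DB_HZ = 80.0

# |H(f)| = exp(−2π²σ²f²); solving |H(f6)| = 0.5 gives the kernel width
_SIGMA_S = np.sqrt(np.log(2.0) / 2.0) / (np.pi * LOWPASS_MINUS6DB_HZ)


def gaussian_lowpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase Gaussian smoothing, −6 dB at 80 Hz, reflect-padded edges."""
    return ndimage.gaussian_filter1d(
        np.asarray(x, dtype=float), sigma=_SIGMA_S * fs, axis=-1,
        mode="reflect", truncate=4.0,
    )


@dataclass
class ErfTrace:
    """Filtered, baseline-z-scored dipole traces cut to −0.2 to 0.6 s."""

    samples: np.ndarray  # (n_dipoles, n_samples) in z units
    times_ms: np.ndarray
    fs: float
    flip_signs: np.ndarray | None = None  # ±1 per dipole if applied

    def mean_trace(self) -> np.ndarray:
        return self.samples.mean(axis=0)


@dataclass
class N70Features:
    peak_time_ms: float
    amplitude_z: float  # mean over ±10 ms around the peak, averaged over trials
    slope_z_per_ms: float
    edge_flagged: bool
    per_trial_amplitudes: np.ndarray


def lowpass_zscore(
    samples: np.ndarray,
    t0_index: int,
    fs: float,
    baseline_s: tuple[float, float] = ZSCORE_BASELINE_S,
) -> ErfTrace:
    """Filter, z-score against the per-trial baseline, and cut one trial.

    ``samples`` is (n_dipoles, n_samples) or 1-D.  The baseline mean and SD
    are taken per dipole from the filtered full-length trace.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    filtered = gaussian_lowpass(x, fs)
    b0 = t0_index + int(round(baseline_s[0] * fs))
    b1 = t0_index + int(round(baseline_s[1] * fs))
    if b0 < 0 or b1 > x.shape[-1] or b1 <= b0:
        raise ValueError("trial does not cover the z-scoring baseline window")
    base = filtered[:, b0:b1]
    sd = base.std(axis=-1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("zero baseline variance; cannot z-score")
    z = (filtered - base.mean(axis=-1, keepdims=True)) / sd
    c0 = t0_index + int(round(CUT_WINDOW_S[0] * fs))
    c1 = t0_index + int(round(CUT_WINDOW_S[1] * fs))
    if c0 < 0 or c1 > x.shape[-1]:
        raise ValueError("trial does not cover the −0.2 to 0.6 s ERF window")
    times_ms = 1000.0 * (np.arange(c0, c1) - t0_index) / fs
    return ErfTrace(z[:, c0:c1], times_ms, fs)


def determine_flip_signs(traces: list[ErfTrace]) -> np.ndarray:
    """One ±1 per dipole from the all-condition average trace.

    A dipole is flipped (−1) when its across-trial average is positive-going
    in the 55–95 ms N70 window; identical signs apply to every condition.
    """
    if not traces:
        raise ValueError("need at least one trial")
    stack = np.stack([t.samples for t in traces])  # (n_trials, n_dipoles, n)
    avg = stack.mean(axis=0)
    t_ms = traces[0].times_ms
    win = (t_ms >= FLIP_WINDOW_MS[0]) & (t_ms <= FLIP_WINDOW_MS[1])
    return np.where(avg[:, win].mean(axis=-1) > 0, -1.0, 1.0)


def apply_flip(trace: ErfTrace, signs: np.ndarray) -> ErfTrace:
    return ErfTrace(trace.samples * signs[:, None], trace.times_ms, trace.fs, signs)


def n70_features(traces: list[ErfTrace]) -> N70Features:
    """Peak time, slope, and amplitude of the N70 from condition trials.

    Peak time and slope come from the dipole- and trial-average trace;
    per-trial amplitudes are the ±10 ms window means of each trial's
    dipole-average trace at the condition's peak time.
    """
    if not traces:
        raise ValueError("need at least one trial")
    t_ms = traces[0].times_ms
    per_trial = np.stack([t.mean_trace() for t in traces])  # (n_trials, n)
    avg = per_trial.mean(axis=0)
    search = (t_ms >= PEAK_SEARCH_MS[0]) & (t_ms <= PEAK_SEARCH_MS[1])
    if not np.any(search):
        raise ValueError("traces do not cover the 50–110 ms search window")
    idx_search = np.flatnonzero(search)
    peak_idx = idx_search[np.argmin(avg[idx_search])]
    peak_ms = float(t_ms[peak_idx])
    edge = peak_idx in (idx_search[0], idx_search[-1])

    s_lo = peak_ms - SLOPE_WINDOW_MS[1]
    s_hi = peak_ms - SLOPE_WINDOW_MS[0]
    s_win = (t_ms >= s_lo) & (t_ms <= s_hi)
    slope = float(np.polyfit(t_ms[s_win], avg[s_win], 1)[0])

    a_win = (t_ms >= peak_ms - AMP_HALFWIDTH_MS) & (t_ms <= peak_ms + AMP_HALFWIDTH_MS)
    amps = per_trial[:, a_win].mean(axis=-1)
    return N70Features(
        peak_time_ms=peak_ms,
        amplitude_z=float(amps.mean()),
        slope_z_per_ms=slope,
        edge_flagged=bool(edge),
        per_trial_amplitudes=amps,
    )
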