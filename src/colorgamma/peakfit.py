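"""Constrained three-model spectral peak detection with adjusted-R² selection.

The trial-averaged power-change spectrum between 15 and 120 Hz is fit with
three nested candidates: (1) a line, (2) a line plus one Gaussian, (3) a line
plus two Gaussians.  Gaussians are constrained to a minimum amplitude of 5%
and a standard deviation between 1.5 and 10 Hz; the single (and first)
Gaussian mean must exceed 21 Hz, the second 61 Hz.  Bins are weighted by
their scaled power change; the candidate with the highest adjusted R² wins,
and the fitted Gaussian means are the reported gamma-peak frequencies.

Fitted peaks are classified low-gamma (mean ≤ 61 Hz) vs high-gamma
(mean > 61 Hz); "first/second peak" reporting keys on that split so a
one-Gaussian fit that captures the high-gamma bump is not mistaken for a
low-gamma peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .spectral import PowerChangeSpectrum

FIT_RANGE_HZ = (15.0, 120.0)
MIN_AMPLITUDE = 5.0  # percent
SD_BOUNDS_HZ = (1.5, 10.0)
MIN_MEAN_FIRST_HZ = 21.0
MIN_MEAN_SECOND_HZ = 61.0
HIGH_GAMMA_SPLIT_HZ = 61.0
MODEL_NAMES = ("line", "line+1gauss", "line+2gauss")
N_PARAMS = {"line": 2, "line+1gauss": 5, "line+2gauss": 8}


@dataclass
class PeakFitResult:
    model: str
    slope: float
    intercept: float
    peaks: list[tuple[float, float, float]]  # (amplitude %, mean Hz, sd Hz)
    adjusted_r2: dict
    no_fit: bool = False

    @property
    def first_peak_hz(self) -> float | None:
        """Low-gamma peak frequency (fitted mean ≤ 61 Hz), if any."""
        lows = [m for _, m, _ in self.peaks if m <= HIGH_GAMMA_SPLIT_HZ]
        return min(lows) if lows else None

    @property
    def second_peak_hz(self) -> float | None:
        """High-gamma peak frequency (fitted mean > 61 Hz), if any."""
        highs = [m for _, m, _ in self.peaks if m > HIGH_GAMMA_SPLIT_HZ]
        return max(highs) if highs else None


def _weights(change: np.ndarray, scheme: str = "scaled", eps: float = 0.01) -> np.ndarray:
    """Per-bin fit weights.

    "scaled": min–max convention for "weighted according to their scaled
    power change" — w = max(change, eps) / max(change), so strongly
    responding bins dominate.  "uniform" and "softmax" are alternatives
    kept behind this switch.
    """
    if scheme == "uniform":
        return np.ones_like(change)
    if scheme == "scaled":
        top = change.max()
        if top <= eps:
            return np.ones_like(change)
        return np.maximum(change, eps) / top
    if scheme == "softmax":
        z = change - change.max()
        return np.exp(z / max(change.std(), 1e-9))
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _gauss(f, amp, mean, sd):
    return amp * np.exp(-0.5 * ((f - mean) / sd) ** 2)


def _predict(f: np.ndarray, params: np.ndarray, n_peaks: int) -> np.ndarray:
    y = params[0] + params[1] * f
    for i in range(n_peaks):
        amp, mean, sd = params[2 + 3 * i : 5 + 3 * i]
        y = y + _gauss(f, amp, mean, sd)
    return y


def _weighted_line(f, y, w):
    sw = np.sqrt(w)
    a = np.column_stack([np.ones_like(f), f]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(a, y * sw, rcond=None)
    return coef  # intercept, slope


def _adjusted_r2(y, yhat, w, n_params):
    ssr = np.sum(w * (y - yhat) ** 2)
    ybar = np.sum(w * y) / np.sum(w)
    sst = np.sum(w * (y - ybar) ** 2)
    if sst <= 0:
        return -np.inf
    r2 = 1.0 - ssr / sst
    n = len(y)
    if n - n_params - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _peak_seeds(f, y, lo, hi, k=4):
    """Frequencies of the k largest local maxima of the smoothed change."""
    smooth = ndimage.gaussian_filter1d(y, 2.0, mode="nearest")
    interior = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] >= smooth[2:])
    cand = np.flatnonzero(interior) + 1
    cand = cand[(f[cand] > lo) & (f[cand] < hi)]
    if len(cand) == 0:
        cand = np.array([np.argmax(np.where((f > lo) & (f < hi), smooth, -np.inf))])
    order = np.argsort(smooth[cand])[::-1]
    return f[cand[order][:k]]


def _fit_candidate(f, y, w, n_peaks, weight_scheme_seeds=None):
    """Bounded weighted least squares with deterministic multi-start."""
    upper_f = FIT_RANGE_HZ[1]
    line = _weighted_line(f, y, w)
    if n_peaks == 0:
        return line, _predict(f, line, 0)

    sw = np.sqrt(w)

    def residuals(params):
        return sw * (_predict(f, params, n_peaks) - y)

    lo_b = [-np.inf, -np.inf]
    hi_b = [np.inf, np.inf]
    lo_b += [MIN_AMPLITUDE, MIN_MEAN_FIRST_HZ, SD_BOUNDS_HZ[0]]
    hi_b += [np.inf, upper_f, SD_BOUNDS_HZ[1]]
    if n_peaks == 2:
        lo_b += [MIN_AMPLITUDE, MIN_MEAN_SECOND_HZ, SD_BOUNDS_HZ[0]]
        hi_b += [np.inf, upper_f, SD_BOUNDS_HZ[1]]
    bounds = (np.array(lo_b), np.array(hi_b))

    seeds1 = _peak_seeds(f, y, MIN_MEAN_FIRST_HZ, upper_f)
    seeds2 = _peak_seeds(f, y, MIN_MEAN_SECOND_HZ, upper_f)
    sd_starts = (2.5, 6.0)
    best = None
    for m1 in seeds1:
        for sd0 in sd_starts:
            amp0 = max(MIN_AMPLITUDE, float(np.interp(m1, f, y)))
            start = list(line) + [amp0, float(np.clip(m1, MIN_MEAN_FIRST_HZ + 0.1, upper_f - 0.1)), sd0]
            if n_peaks == 2:
                m2 = seeds2[0] if len(seeds2) else 0.5 * (MIN_MEAN_SECOND_HZ + upper_f)
                amp2 = max(MIN_AMPLITUDE, float(np.interp(m2, f, y)))
                start += [amp2, float(np.clip(m2, MIN_MEAN_SECOND_HZ + 0.1, upper_f - 0.1)), sd0]
            start = np.clip(start, bounds[0], bounds[1])
            try:
                sol = optimize.least_squares(
                    residuals, start, bounds=bounds, max_nfev=400, method="trf"
                )
            except Exception:
                continue
            cost = sol.cost
            if best is None or cost < best[0]:
                best = (cost, sol.x)
    if best is None:
        return None, None
    params = best[1]
    return params, _predict(f, params, n_peaks)


def fit_peak_models(
    change: PowerChangeSpectrum,
    weight_scheme: str = "scaled",
    tie_tol: float = 1e-9,
) -> PeakFitResult:
    """Fit the three candidates and select by adjusted R² (ties → simpler)."""
    f_all = np.asarray(change.freqs_hz, dtype=float)
    sel = (f_all >= FIT_RANGE_HZ[0]) & (f_all <= FIT_RANGE_HZ[1])
    f = f_all[sel]
    if f.size == 0 or f[0] > FIT_RANGE_HZ[0] + 1 or f[-1] < FIT_RANGE_HZ[1] - 1:
        raise ValueError("spectrum must cover 15–120 Hz")
    y = np.asarray(change.change_percent, dtype=float)[sel]
    w = _weights(y, weight_scheme)

    fits = {}
    adj = {}
    for name, n_peaks in zip(MODEL_NAMES, (0, 1, 2)):
        params, yhat = _fit_candidate(f, y, w, n_peaks)
        if params is None:
            adj[name] = -np.inf
            fits[name] = None
        else:
            adj[name] = _adjusted_r2(y, yhat, w, N_PARAMS[name])
            fits[name] = params

    if all(v == -np.inf for v in adj.values()):
        return PeakFitResult("line", 0.0, 0.0, [], adj, no_fit=True)

    # argmax with ties (within tie_tol) resolved toward the simpler model
    best_name = MODEL_NAMES[0]
    for name in MODEL_NAMES[1:]:
        if adj[name] > adj[best_name] + tie_tol:
            best_name = name
    params = fits[best_name]
    n_peaks = (0, 1, 2)[MODEL_NAMES.index(best_name)]
    peaks = [
        (float(params[2 + 3 * i]), float(params[3 + 3 * i]), float(params[4 + 3 * i]))
        for i in range(n_peaks)
    ]
    return PeakFitResult(
        model=best_name,
        slope=float(params[1]),
        intercept=float(params[0]),
        peaks=peaks,
        adjusted_r2=adj,
    )


def fallback_peak_frequency(
    participant_results: dict[str, PeakFitResult],
) -> dict[str, tuple[float, bool]]:
    """Fill conditions lacking a low-gamma peak with the participant mean.

    Returns condition -> (peak frequency, filled) where ``filled`` marks
    conditions that received the fall-back value; those stay usable for
    band-power extraction but are excluded from analyses that explicitly
    report peak frequencies.  Raises if the participant has no peak anywhere.
    """
    found = {
        c: r.first_peak_hz
        for c, r in participant_results.items()
        if r.first_peak_hz is not None
    }
    if not found:
        raise ValueError("participant has no detected gamma peak in any condition")
    mean_freq = float(np.mean(list(found.values())))
    out = {}
    for c in participant_results:
        if c in found:
            out[c] = (found[c], False)
        else:
            out[c] = (mean_freq, True)
    return out
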