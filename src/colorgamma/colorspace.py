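"""DKL cone-opponent color space from measured display spectra.

Converts emission spectra of display primaries into L/M/S cone excitations,
builds a background-relative DKL (Derrington–Krauskopf–Lennie) calibration
whose axes are normalized so that an on-axis stimulus of unit pooled cone
contrast receives a unit coordinate, samples equiluminant stimulus ellipses
inside the display gamut, and inverts the chain back to gun values.

Conventions
-----------
Weber cone contrasts are taken against the adaptation background,
``(L - L_bg) / L_bg`` etc.  Pooled cone contrast is their root mean square,
so equal contrast ``c`` on all three cone classes pools to ``c``.  The raw
opponent projection is::

    lum_raw = dL/L + dM/M
    lm_raw  = dL/L - dM/M
    s_raw   = dS/S - (dL/L + dM/M) / 2

and each axis is scaled by its normalization constant ``k``.  The luminance
term subtracted from the S axis is the mean L/M contrast, so a pure
luminance modulation (equal contrast on all cones) has ``s = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpectralPowerDistribution:
    """Tabulated radiance per wavelength, arbitrary radiometric units."""

    wavelengths_nm: np.ndarray
    radiance: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.radiance, dtype=float)
        if w.shape != r.shape or w.ndim != 1:
            raise ValueError("wavelengths and radiance must be equal-length 1-D")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("radiance must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "radiance", r)

    def scaled(self, factor: float) -> "SpectralPowerDistribution":
        return SpectralPowerDistribution(self.wavelengths_nm, self.radiance * factor)


@dataclass(frozen=True)
class ConeFundamentals:
    """L/M/S spectral sensitivity curves on a common wavelength grid."""

    wavelengths_nm: np.ndarray
    sensitivity_l: np.ndarray
    sensitivity_m: np.ndarray
    sensitivity_s: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        curves = [np.asarray(c, dtype=float) for c in
                  (self.sensitivity_l, self.sensitivity_m, self.sensitivity_s)]
        if any(c.shape != w.shape for c in curves):
            raise ValueError("sensitivity curves must match the wavelength grid")
        if any(np.any(c < 0) for c in curves):
            raise ValueError("sensitivities must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", w)
        for name, c in zip(("sensitivity_l", "sensitivity_m", "sensitivity_s"), curves):
            object.__setattr__(self, name, c)

    @property
    def matrix(self) -> np.ndarray:
        """(3, n_wavelengths) array in L, M, S order."""
        return np.vstack([self.sensitivity_l, self.sensitivity_m, self.sensitivity_s])


@dataclass(frozen=True)
class ConeExcitation:
    L: float
    M: float
    S: float

    def __post_init__(self):
        if min(self.L, self.M, self.S) < 0:
            raise ValueError("cone excitations must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.S], dtype=float)

    def __add__(self, other: "ConeExcitation") -> "ConeExcitation":
        return ConeExcitation(self.L + other.L, self.M + other.M, self.S + other.S)


@dataclass(frozen=True)
class DKLCalibration:
    """Background adaptation point plus the three axis normalization constants."""

    background: ConeExcitation
    k_lum: float
    k_lm: float
    k_s: float

    def __post_init__(self):
        bg = self.background
        if bg.L <= 0 or bg.M <= 0 or bg.S <= 0:
            raise ValueError("background cone excitations must be strictly positive")
        if min(self.k_lum, self.k_lm, self.k_s) <= 0:
            raise ValueError("normalization constants must be positive")


@dataclass(frozen=True)
class DKLCoordinates:
    lum: float
    lm: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.lum, self.lm, self.s], dtype=float)


def make_pseudo_fundamentals(
    wavelengths_nm: np.ndarray | None = None,
    peaks_nm: Sequence[float] = (565.0, 540.0, 445.0),
    log_sigma: float = 0.06,
) -> ConeFundamentals:
    """Synthetic log-Gaussian cone fundamentals (L, M, S peak order).

    Stand-in for a measured 10-deg fundamentals table: each curve is a
    Gaussian in log-wavelength with a single global maximum of 1.  Adequate
    for exercising the calibration chain; not a fit to any observer.
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(390.0, 831.0, 1.0)
    w = np.asarray(wavelengths_nm, dtype=float)
    curves = [np.exp(-0.5 * ((np.log(w / p)) / log_sigma) ** 2) for p in peaks_nm]
    return ConeFundamentals(w, *curves)


def make_gaussian_primaries(
    centers_nm: Sequence[float] = (610.0, 545.0, 465.0),
    width_nm: float = 30.0,
    wavelengths_nm: np.ndarray | None = None,
) -> list[SpectralPowerDistribution]:
    """Three synthetic display primaries (R, G, B) with Gaussian emission."""
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(390.0, 831.0, 1.0)
    w = np.asarray(wavelengths_nm, dtype=float)
    return [
        SpectralPowerDistribution(w, np.exp(-0.5 * ((w - c) / width_nm) ** 2))
        for c in centers_nm
    ]


def cone_excitation(
    spd: SpectralPowerDistribution, fundamentals: ConeFundamentals
) -> ConeExcitation:
    """Integrate radiance against each cone fundamental (trapezoid rule).

    The SPD is linearly interpolated onto the fundamentals grid; radiance is
    treated as zero outside the SPD's tabulated range.
    """
    w_f = fundamentals.wavelengths_nm
    w_s = spd.wavelengths_nm
    if w_s[-1] < w_f[0] or w_s[0] > w_f[-1]:
        raise ValueError("SPD and fundamentals wavelength ranges do not overlap")
    radiance = np.interp(w_f, w_s, spd.radiance, left=0.0, right=0.0)
    vals = np.trapezoid(radiance * fundamentals.matrix, w_f, axis=1)
    return ConeExcitation(*vals)


def cone_contrasts(stimulus: ConeExcitation, background: ConeExcitation) -> np.ndarray:
    """Weber cone contrasts (dL/L, dM/M, dS/S) against the background."""
    bg = background.as_array()
    if np.any(bg <= 0):
        raise ValueError("background cone excitations must be strictly positive")
    return (stimulus.as_array() - bg) / bg


def pooled_cone_contrast(
    stimulus: ConeExcitation, background: ConeExcitation
) -> float:
    """Root-mean-square of the three Weber cone contrasts."""
    c = cone_contrasts(stimulus, background)
    return float(np.sqrt(np.mean(c**2)))


def _raw_projection(contrasts: np.ndarray) -> np.ndarray:
    cl, cm, cs = contrasts
    lum = cl + cm
    lm = cl - cm
    s = cs - lum / 2.0
    return np.array([lum, lm, s])


def compute_dkl_calibration(background: ConeExcitation) -> DKLCalibration:
    """Axis normalization constants from the unit-pooled-contrast convention.

    For each cardinal axis the unique on-axis modulation with pooled cone
    contrast 1 must map to coordinate 1.  With RMS pooling these follow in
    closed form: the luminance axis has contrasts (1, 1, 1) so ``lum_raw = 2``;
    the L−M axis has contrasts (a, −a, 0) with ``a = sqrt(3/2)`` so
    ``lm_raw = sqrt(6)``; the S axis has contrasts (0, 0, sqrt(3)) so
    ``s_raw = sqrt(3)``.
    """
    bg = background.as_array()
    if np.any(bg <= 0):
        raise ValueError("background cone excitations must be strictly positive")
    return DKLCalibration(
        background=background,
        k_lum=1.0 / 2.0,
        k_lm=1.0 / np.sqrt(6.0),
        k_s=1.0 / np.sqrt(3.0),
    )


def to_dkl(stimulus: ConeExcitation, cal: DKLCalibration) -> DKLCoordinates:
    """Background-relative opponent projection, k-normalized per axis."""
    raw = _raw_projection(cone_contrasts(stimulus, cal.background))
    return DKLCoordinates(
        lum=raw[0] * cal.k_lum, lm=raw[1] * cal.k_lm, s=raw[2] * cal.k_s
    )


def dkl_to_cone_excitation(dkl: DKLCoordinates, cal: DKLCalibration) -> ConeExcitation:
    """Invert the opponent projection back to absolute cone excitations."""
    raw = np.array([dkl.lum / cal.k_lum, dkl.lm / cal.k_lm, dkl.s / cal.k_s])
    # raw = P @ contrasts with P rows (1,1,0), (1,-1,0), (-1/2,-1/2,1)
    proj = np.array([[1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [-0.5, -0.5, 1.0]])
    contrasts = np.linalg.solve(proj, raw)
    bg = cal.background.as_array()
    return ConeExcitation(*(bg * (1.0 + contrasts)))


class OutOfGamutError(ValueError):
    """Requested color cannot be produced with gun values in [0, 1]."""


def _primary_matrix(
    primaries: Sequence[SpectralPowerDistribution], fundamentals: ConeFundamentals
) -> np.ndarray:
    """(3, 3) matrix mapping gun values to cone excitations (columns = guns)."""
    cols = [cone_excitation(p, fundamentals).as_array() for p in primaries]
    m = np.column_stack(cols)
    if abs(np.linalg.det(m)) < 1e-12 * np.abs(m).max() ** 3:
        raise ValueError("primaries are linearly dependent in cone space")
    return m


def dkl_to_gun_values(
    dkl: DKLCoordinates,
    cal: DKLCalibration,
    primaries: Sequence[SpectralPowerDistribution],
    fundamentals: ConeFundamentals,
    tol: float = 1e-9,
) -> np.ndarray:
    """Gun intensities producing the requested DKL coordinates.

    Raises :class:`OutOfGamutError` naming the offending gun when the linear
    solution leaves [0, 1].
    """
    m = _primary_matrix(primaries, fundamentals)
    excitation = dkl_to_cone_excitation(dkl, cal).as_array()
    guns = np.linalg.solve(m, excitation)
    for i, g in enumerate(guns):
        if g < -tol or g > 1.0 + tol:
            raise OutOfGamutError(
                f"gun {i} requires intensity {g:.4f} outside [0, 1]"
            )
    return np.clip(guns, 0.0, 1.0)


def _gamut_limit(
    direction: DKLCoordinates,
    cal: DKLCalibration,
    primaries: Sequence[SpectralPowerDistribution],
    fundamentals: ConeFundamentals,
) -> float:
    """Largest t such that t * direction is displayable (bisection)."""
    def in_gamut(t: float) -> bool:
        d = DKLCoordinates(direction.lum * t, direction.lm * t, direction.s * t)
        try:
            dkl_to_gun_values(d, cal, primaries, fundamentals)
            return True
        except (OutOfGamutError, ValueError):
            return False

    if not in_gamut(0.0):
        raise OutOfGamutError("background itself is outside the gamut")
    hi = 1.0
    while in_gamut(hi):
        hi *= 2.0
        if hi > 1e6:
            return hi
    lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if in_gamut(mid):
            lo = mid
        else:
            hi = mid
    return lo


def sample_equiluminant_ellipse(
    cal: DKLCalibration,
    primaries: Sequence[SpectralPowerDistribution],
    fundamentals: ConeFundamentals,
    n: int,
    gamut_fraction: float = 0.95,
) -> list[DKLCoordinates]:
    """``n`` equiluminant colors at equal arc-length spacing along an ellipse.

    The ellipse lies in the lum = 0 plane, centered on the background, axes
    aligned with the lm/s axes, each semi-axis at ``gamut_fraction`` of the
    tighter of the two gamut limits along that axis (so antipodal points are
    both displayable).  Point 0 sits on the +lm axis; points proceed
    counterclockwise (toward +s).
    """
    if n < 3:
        raise ValueError("need at least 3 points on the ellipse")
    r_lm = gamut_fraction * min(
        _gamut_limit(DKLCoordinates(0, 1, 0), cal, primaries, fundamentals),
        _gamut_limit(DKLCoordinates(0, -1, 0), cal, primaries, fundamentals),
    )
    r_s = gamut_fraction * min(
        _gamut_limit(DKLCoordinates(0, 0, 1), cal, primaries, fundamentals),
        _gamut_limit(DKLCoordinates(0, 0, -1), cal, primaries, fundamentals),
    )
    # equal arc-length placement via dense polyline inversion
    theta = np.linspace(0.0, 2.0 * np.pi, 20001)
    x = r_lm * np.cos(theta)
    y = r_s * np.sin(theta)
    seg = np.hypot(np.diff(x), np.diff(y))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = arclen[-1] * np.arange(n) / n
    th = np.interp(targets, arclen, theta)
    return [
        DKLCoordinates(0.0, r_lm * np.cos(t), r_s * np.sin(t)) for t in th
    ]


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_spd_csv(path) -> SpectralPowerDistribution:
    """Two-column delimited text with header: wavelength_nm, radiance."""
    df = pd.read_csv(path)
    return SpectralPowerDistribution(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def read_fundamentals_csv(path) -> ConeFundamentals:
    """Four-column delimited text with header: wavelength_nm, L, M, S."""
    df = pd.read_csv(path)
    return ConeFundamentals(
        df.iloc[:, 0].to_numpy(),
        df.iloc[:, 1].to_numpy(),
        df.iloc[:, 2].to_numpy(),
        df.iloc[:, 3].to_numpy(),
    )


def stimulus_table(
    labels: Sequence[str],
    coords: Sequence[DKLCoordinates],
    cal: DKLCalibration,
    primaries: Sequence[SpectralPowerDistribution],
    fundamentals: ConeFundamentals,
) -> pd.DataFrame:
    """Per-stimulus DKL coordinates and Weber cone contrasts, one row each."""
    rows = []
    for label, d in zip(labels, coords):
        exc = dkl_to_cone_excitation(d, cal)
        cc = cone_contrasts(exc, cal.background)
        rows.append(
            {
                "stimulus": label,
                "dkl_lum": d.lum,
                "dkl_lm": d.lm,
                "dkl_s": d.s,
                "contrast_l": cc[0],
                "contrast_m": cc[1],
                "contrast_s": cc[2],
                "pooled_contrast": float(np.sqrt(np.mean(cc**2))),
            }
        )
    return pd.DataFrame(rows)
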