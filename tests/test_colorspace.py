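"""DKL calibration chain: integration, projection, gamut, ellipse sampling."""

import numpy as np
import pytest

from colorgamma import colorspace as cs


@pytest.fixture(scope="module")
def fundamentals():
    return cs.make_pseudo_fundamentals()


@pytest.fixture(scope="module")
def primaries():
    return cs.make_gaussian_primaries()


@pytest.fixture(scope="module")
def setup(fundamentals, primaries):
    bg = cs.ConeExcitation(0.0, 0.0, 0.0)
    for p in primaries:
        bg = bg + cs.cone_excitation(p.scaled(0.5), fundamentals)
    cal = cs.compute_dkl_calibration(bg)
    return bg, cal


# ---------------------------------------------------------------- excitation


def test_zero_radiance_gives_zero_excitation(fundamentals):
    w = fundamentals.wavelengths_nm
    spd = cs.SpectralPowerDistribution(w, np.zeros_like(w))
    exc = cs.cone_excitation(spd, fundamentals)
    assert exc.as_array().tolist() == [0.0, 0.0, 0.0]


def test_narrow_impulse_matches_fundamental_lookup(fundamentals):
    # unit-area triangular impulse at 550 nm, 1 nm support
    w0 = 550.0
    w = np.array([w0 - 1.0, w0, w0 + 1.0])
    spd = cs.SpectralPowerDistribution(w, np.array([0.0, 1.0, 0.0]))
    exc = cs.cone_excitation(spd, fundamentals).as_array()
    idx = np.argmin(np.abs(fundamentals.wavelengths_nm - w0))
    expected = fundamentals.matrix[:, idx]  # unit area x sensitivity(550)
    assert np.allclose(exc, expected, rtol=1e-6)


def test_excitation_linearity(fundamentals, primaries):
    a, b = primaries[0], primaries[1]
    summed = cs.SpectralPowerDistribution(
        a.wavelengths_nm, a.radiance + b.radiance
    )
    lhs = cs.cone_excitation(summed, fundamentals).as_array()
    rhs = (
        cs.cone_excitation(a, fundamentals).as_array()
        + cs.cone_excitation(b, fundamentals).as_array()
    )
    assert np.allclose(lhs, rhs, rtol=1e-10)
    # homogeneity, against an independent trapezoid computation
    scaled = cs.cone_excitation(a.scaled(2.5), fundamentals).as_array()
    direct = np.trapezoid(
        2.5
        * np.interp(
            fundamentals.wavelengths_nm, a.wavelengths_nm, a.radiance, left=0, right=0
        )
        * fundamentals.matrix,
        fundamentals.wavelengths_nm,
        axis=1,
    )
    assert np.allclose(scaled, direct, rtol=1e-12)


def test_non_overlapping_ranges_error(fundamentals):
    spd = cs.SpectralPowerDistribution(np.array([100.0, 110.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        cs.cone_excitation(spd, fundamentals)


def test_negative_radiance_rejected():
    with pytest.raises(ValueError):
        cs.SpectralPowerDistribution(np.array([500.0, 501.0]), np.array([1.0, -1.0]))


# ------------------------------------------------------------- pooled contrast


def test_pooled_contrast_examples():
    bg = cs.ConeExcitation(1.0, 2.0, 3.0)
    same = cs.pooled_cone_contrast(bg, bg)
    assert same == 0.0
    stim = cs.ConeExcitation(1.1, 2.2, 3.3)  # contrasts (0.1, 0.1, 0.1)
    assert np.isclose(cs.pooled_cone_contrast(stim, bg), 0.1)
    stim2 = cs.ConeExcitation(1.3, 2.0, 3.0)  # contrasts (0.3, 0, 0)
    assert np.isclose(cs.pooled_cone_contrast(stim2, bg), 0.3 / np.sqrt(3.0))


# ------------------------------------------------------------------ projection


def test_background_maps_to_origin(setup):
    bg, cal = setup
    dkl = cs.to_dkl(bg, cal)
    assert np.allclose(dkl.as_array(), 0.0, atol=1e-12)


def test_axis_purity_s_only(setup):
    bg, cal = setup
    stim = cs.ConeExcitation(bg.L, bg.M, bg.S * 1.2)
    dkl = cs.to_dkl(stim, cal)
    assert abs(dkl.lum) < 1e-8
    assert abs(dkl.lm) < 1e-8
    assert dkl.s != 0.0


def test_unit_pooled_contrast_gives_unit_coordinate(setup):
    bg, cal = setup
    b = bg.as_array()
    # luminance axis: equal contrast on all cones, pooled contrast 1
    lum_stim = cs.ConeExcitation(*(b * 2.0))
    assert np.isclose(cs.pooled_cone_contrast(lum_stim, bg), 1.0)
    d = cs.to_dkl(lum_stim, cal)
    assert np.allclose(d.as_array(), [1.0, 0.0, 0.0], atol=1e-8)
    # L-M axis: contrasts (c, -c, 0) pool to c*sqrt(2/3); unit contrast is
    # physically out of range (M would go negative), so check proportionality
    c = 0.3
    lm_stim = cs.ConeExcitation(b[0] * (1 + c), b[1] * (1 - c), b[2])
    pooled = cs.pooled_cone_contrast(lm_stim, bg)
    assert np.isclose(pooled, c * np.sqrt(2.0 / 3.0))
    d = cs.to_dkl(lm_stim, cal)
    assert np.allclose(d.as_array(), [0.0, pooled, 0.0], atol=1e-8)
    # S axis: contrasts (0, 0, sqrt(3))
    s_stim = cs.ConeExcitation(b[0], b[1], b[2] * (1 + np.sqrt(3.0)))
    assert np.isclose(cs.pooled_cone_contrast(s_stim, bg), 1.0)
    d = cs.to_dkl(s_stim, cal)
    assert np.allclose(d.as_array(), [0.0, 0.0, 1.0], atol=1e-8)


def test_background_scale_invariance(setup):
    bg, _ = setup
    for c in (0.5, 3.0):
        scaled_bg = cs.ConeExcitation(*(bg.as_array() * c))
        cal_c = cs.compute_dkl_calibration(scaled_bg)
        # same Weber contrasts on the scaled background
        stim = cs.ConeExcitation(*(scaled_bg.as_array() * np.array([1.1, 0.95, 1.2])))
        ref_cal = cs.compute_dkl_calibration(bg)
        ref_stim = cs.ConeExcitation(*(bg.as_array() * np.array([1.1, 0.95, 1.2])))
        assert np.allclose(
            cs.to_dkl(stim, cal_c).as_array(),
            cs.to_dkl(ref_stim, ref_cal).as_array(),
            atol=1e-12,
        )


def test_invalid_background_rejected():
    with pytest.raises(ValueError):
        cs.compute_dkl_calibration(cs.ConeExcitation(0.0, 1.0, 1.0))


# ----------------------------------------------------------------- inversion


def test_round_trip_random_in_gamut(setup, primaries, fundamentals):
    bg, cal = setup
    rng = np.random.default_rng(11)
    worst = 0.0
    count = 0
    while count < 100:
        guns = rng.uniform(0.05, 0.95, size=3)
        exc = cs.ConeExcitation(0.0, 0.0, 0.0)
        for g, p in zip(guns, primaries):
            exc = exc + cs.cone_excitation(p.scaled(g), fundamentals)
        dkl = cs.to_dkl(exc, cal)
        back = cs.dkl_to_gun_values(dkl, cal, primaries, fundamentals)
        worst = max(worst, np.max(np.abs(back - guns)))
        # and dkl -> excitation -> dkl closes as well
        dkl2 = cs.to_dkl(cs.dkl_to_cone_excitation(dkl, cal), cal)
        worst = max(worst, np.max(np.abs(dkl2.as_array() - dkl.as_array())))
        count += 1
    assert worst < 1e-6


def test_origin_returns_background_guns(setup, primaries, fundamentals):
    bg, cal = setup
    guns = cs.dkl_to_gun_values(
        cs.DKLCoordinates(0.0, 0.0, 0.0), cal, primaries, fundamentals
    )
    assert np.allclose(guns, 0.5, atol=1e-9)


def test_out_of_gamut_error_names_gun(setup, primaries, fundamentals):
    bg, cal = setup
    with pytest.raises(cs.OutOfGamutError, match="gun"):
        cs.dkl_to_gun_values(
            cs.DKLCoordinates(50.0, 0.0, 0.0), cal, primaries, fundamentals
        )


# ------------------------------------------------------------------- ellipse


def test_equiluminant_ellipse_contract(setup, primaries, fundamentals):
    bg, cal = setup
    pts = cs.sample_equiluminant_ellipse(cal, primaries, fundamentals, 8)
    assert len(pts) == 8
    for p in pts:
        assert p.lum == 0.0
        cs.dkl_to_gun_values(p, cal, primaries, fundamentals)  # in gamut
    # antipodal symmetry
    for i in range(4):
        s = pts[i].as_array() + pts[i + 4].as_array()
        assert np.allclose(s, 0.0, atol=1e-6)


def test_ellipse_equal_arc_spacing(setup, primaries, fundamentals):
    bg, cal = setup
    pts = cs.sample_equiluminant_ellipse(cal, primaries, fundamentals, 8)
    xy = np.array([[p.lm, p.s] for p in pts])
    # dense polyline arc length between consecutive sampled points
    r_lm = max(abs(p.lm) for p in pts)
    r_s = max(abs(p.s) for p in pts)
    theta = np.linspace(0, 2 * np.pi, 200001)
    dense = np.column_stack([r_lm * np.cos(theta), r_s * np.sin(theta)])
    seg = np.hypot(*np.diff(dense, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    ang = np.mod(np.arctan2(xy[:, 1] / r_s, xy[:, 0] / r_lm), 2 * np.pi)
    pos = np.interp(ang, theta, arclen)
    gaps = np.diff(np.sort(np.concatenate([pos, [pos.min() + arclen[-1]]])))
    assert gaps.max() / gaps.min() - 1.0 < 0.01


def test_ellipse_needs_three_points(setup, primaries, fundamentals):
    bg, cal = setup
    with pytest.raises(ValueError):
        cs.sample_equiluminant_ellipse(cal, primaries, fundamentals, 2)


# ------------------------------------------------------------------------- IO


def test_csv_round_trip(tmp_path, fundamentals, primaries, setup):
    bg, cal = setup
    spd_path = tmp_path / "spd.csv"
    p = primaries[0]
    import pandas as pd

    pd.DataFrame(
        {"wavelength_nm": p.wavelengths_nm, "radiance": p.radiance}
    ).to_csv(spd_path, index=False)
    back = cs.read_spd_csv(spd_path)
    assert np.allclose(back.radiance, p.radiance)

    f_path = tmp_path / "fund.csv"
    pd.DataFrame(
        {
            "wavelength_nm": fundamentals.wavelengths_nm,
            "L": fundamentals.sensitivity_l,
            "M": fundamentals.sensitivity_m,
            "S": fundamentals.sensitivity_s,
        }
    ).to_csv(f_path, index=False)
    back_f = cs.read_fundamentals_csv(f_path)
    assert np.allclose(back_f.matrix, fundamentals.matrix)


def test_stimulus_table_layout(setup, primaries, fundamentals):
    bg, cal = setup
    pts = cs.sample_equiluminant_ellipse(cal, primaries, fundamentals, 4)
    table = cs.stimulus_table(["a", "b", "c", "d"], pts, cal, primaries, fundamentals)
    assert list(table.columns) == [
        "stimulus", "dkl_lum", "dkl_lm", "dkl_s",
        "contrast_l", "contrast_m", "contrast_s", "pooled_contrast",
    ]
    assert np.allclose(table.dkl_lum, 0.0, atol=1e-9)
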