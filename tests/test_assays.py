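"""4PL dose-response, relative potency, AC-SINS peak, and SEC calibration."""

import math
import warnings

import numpy as np
import pytest

from abdev.assays import (BindingCurve, SecCalibration, Spectrum, acsins_lambda_max,
                          acsins_shift, fit_4pl, four_pl, relative_potency,
                          sec_mw_estimate)
from abdev.synthetic import make_assay_fixtures


def curve_from_bundle(bundle):
    df = bundle.tables["binding"]
    return BindingCurve(df["concentration_pM"].to_numpy(), df["response"].to_numpy())


def spectrum_from_bundle(bundle):
    df = bundle.tables["spectrum"]
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy())


def test_4pl_noiseless_recovery_within_0p1pct():
    bundle = make_assay_fixtures("binding", {"bottom": 0.05, "top": 2.0,
                                             "ec50": 200.0, "hill": 1.0,
                                             "n_concentrations": 12}, noise=0.0)
    fit = fit_4pl(curve_from_bundle(bundle))
    assert fit.converged
    assert fit.ec50 == pytest.approx(200.0, rel=1e-3)
    assert fit.hill == pytest.approx(1.0, rel=1e-3)
    assert fit.top == pytest.approx(2.0, rel=1e-3)


def test_4pl_noisy_recovery_median_error_below_5pct():
    errors = []
    for seed in range(20):
        bundle = make_assay_fixtures("binding", {"ec50": 200.0}, noise=0.02, seed=seed)
        fit = fit_4pl(curve_from_bundle(bundle))
        assert fit.converged
        errors.append(abs(fit.ec50 - 200.0) / 200.0)
    assert np.median(errors) < 0.05


def test_4pl_flat_data_flagged_not_silently_fit():
    conc = np.logspace(0, 3, 8)
    flat = BindingCurve(conc, np.full_like(conc, 1.3))
    fit = fit_4pl(flat)
    assert not fit.converged


def test_4pl_descending_curve_recovered():
    conc = np.logspace(0, 4, 10)
    y = four_pl(conc, 2.0, 0.1, 150.0, 1.2)   # decreasing: 2.0 -> 0.1
    assert y[0] > y[-1]
    fit = fit_4pl(BindingCurve(conc, y))
    assert fit.converged
    assert fit.ec50 == pytest.approx(150.0, rel=1e-3)
    # canonical form has top > bottom; direction is carried by the hill sign
    assert fit.hill == pytest.approx(-1.2, rel=1e-3)
    assert fit.top == pytest.approx(2.0, rel=1e-3)
    assert fit.bottom == pytest.approx(0.1, rel=1e-2)


def test_binding_curve_validation():
    with pytest.raises(ValueError, match="positive"):
        BindingCurve([-1.0, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5])
    with pytest.raises(ValueError, match="5 distinct"):
        BindingCurve([1.0, 1.0, 2.0, 2.0], [0.1, 0.1, 0.2, 0.2])


def test_relative_potency_identity_and_printed_ranges():
    assert relative_potency(200.0, 200.0) == pytest.approx(100.0)
    # reference and sample EC50s at the boundaries of the two reported ranges
    assert relative_potency(148.0, 518.0) == pytest.approx(79.96, abs=0.01)
    with pytest.raises(ValueError, match="ambiguous"):
        relative_potency(148.0, 0.5)
    with pytest.raises(ValueError):
        relative_potency(-1.0, 100.0)


def test_relative_potency_log_antisymmetry():
    for a, b in [(148.0, 518.0), (260.0, 1609.0), (150.0, 151.0)]:
        assert relative_potency(a, b) * relative_potency(b, a) == pytest.approx(100.0**2)


def test_acsins_vertex_exact_on_noiseless_quadratic():
    bundle = make_assay_fixtures("acsins", {"lambda_max": 530.0, "a": -0.001}, noise=0.0)
    fit = acsins_lambda_max(spectrum_from_bundle(bundle))
    assert fit.valid
    assert fit.lambda_max == pytest.approx(530.0, abs=1e-9)
    # coefficient identity: vertex = -b / 2a
    assert -fit.b / (2 * fit.a) == pytest.approx(530.0, abs=1e-9)


def test_acsins_vertex_formula_instance():
    # y = -(x - 530)^2 + 5 has a = -1, b = 1060
    x = np.arange(500.0, 561.0, 2.0)
    y = -1.0 * (x - 530.0) ** 2 + 5.0
    fit = acsins_lambda_max(Spectrum(x, y))
    assert fit.a == pytest.approx(-1.0)
    assert fit.b == pytest.approx(1060.0)
    assert fit.lambda_max == pytest.approx(530.0)


def test_acsins_noise_recovery_within_0p2nm():
    devs = []
    for seed in range(100):
        bundle = make_assay_fixtures("acsins", {"lambda_max": 530.0, "a": -0.001,
                                                "peak_height": 0.5},
                                     noise=0.005, seed=seed)
        fit = acsins_lambda_max(spectrum_from_bundle(bundle))
        assert fit.valid
        devs.append(abs(fit.lambda_max - 530.0))
    assert np.quantile(devs, 0.95) < 0.2


def test_acsins_degenerate_inputs():
    x = np.arange(500.0, 561.0, 2.0)
    rising = acsins_lambda_max(Spectrum(x, 0.001 * (x - 530.0) ** 2))
    assert not rising.valid and math.isnan(rising.lambda_max)
    with pytest.raises(ValueError, match="5 points"):
        acsins_lambda_max(Spectrum(np.array([500.0, 510, 520]), np.zeros(3)))


def test_acsins_shift_subtraction_and_ordering():
    x = np.arange(480.0, 581.0, 2.0)
    control = acsins_lambda_max(Spectrum(x, -0.001 * (x - 530.0) ** 2 + 0.5))
    sample = acsins_lambda_max(Spectrum(x, -0.001 * (x - 532.4) ** 2 + 0.5))
    assert acsins_shift(sample, control) == pytest.approx(2.4, abs=1e-6)
    assert acsins_shift(control, control) == pytest.approx(0.0, abs=1e-9)
    # lower planted shift ranks as lower self-interaction
    shifts = []
    for planted in (0.61, 0.83, 0.97):
        fit = acsins_lambda_max(Spectrum(x, -0.001 * (x - (530.0 + planted)) ** 2 + 0.5))
        shifts.append(acsins_shift(fit, control))
    assert shifts == sorted(shifts)


def test_sec_two_point_calibration_interpolation():
    calib = SecCalibration([(670.0, 8.0), (44.0, 12.0)])
    # geometric midpoint of the two standards: sqrt(670 * 44) = 171.70
    assert sec_mw_estimate(10.0, calib) == pytest.approx(171.70, abs=0.01)
    # exact on the knots
    assert sec_mw_estimate(8.0, calib) == pytest.approx(670.0, rel=1e-9)
    assert sec_mw_estimate(12.0, calib) == pytest.approx(44.0, rel=1e-9)


def test_sec_validation_and_extrapolation_warning():
    with pytest.raises(ValueError, match="at least 2"):
        SecCalibration([(670.0, 8.0)])
    with pytest.raises(ValueError, match="negative"):
        SecCalibration([(44.0, 8.0), (670.0, 12.0)])
    calib = SecCalibration([(670.0, 8.0), (44.0, 12.0)])
    with pytest.warns(UserWarning, match="outside the calibrated range"):
        sec_mw_estimate(16.0, calib)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        sec_mw_estimate(10.0, calib)   # inside: no warning


def test_sec_synthetic_fixture_recovers_true_line():
    bundle = make_assay_fixtures("sec", noise=0.0)
    df = bundle.tables["sec_standards"]
    calib = SecCalibration(list(zip(df["mw_kda"], df["retention_ml"])))
    assert calib.slope == pytest.approx(bundle.truth["slope"], abs=1e-9)
    assert calib.intercept == pytest.approx(bundle.truth["intercept"], abs=1e-9)
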