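import numpy as np
import pytest

from phpcoevol.biophys import (
    KineticFit,
    Spectrum,
    Trace,
    center_of_mass,
    fit_chemical_denaturation,
    fit_first_order_decay,
    fit_thermal_melt,
    mean_residue_ellipticity,
    read_trace_csv,
    reduce_plate_reads,
    relative_rates,
    two_state_melt_signal,
    write_trace_csv,
)
from phpcoevol.errors import ValidationError
from phpcoevol.synth import denat_trace, kinetic_trace, melt_spectra, melt_trace


def test_center_of_mass_closed_forms():
    lam = tuple(float(w) for w in range(295, 398, 2))
    flat = Spectrum(wavelengths=lam, intensities=(1.0,) * len(lam))
    assert center_of_mass(flat) == pytest.approx(346.0)
    two = Spectrum(wavelengths=(295.0, 397.0), intensities=(1.0, 3.0))
    assert center_of_mass(two) == pytest.approx(371.5)  # (295 + 3*397)/4
    delta = Spectrum(wavelengths=lam, intensities=(0.0,) * 30 + (5.0,) + (0.0,) * (len(lam) - 31))
    assert center_of_mass(delta) == pytest.approx(lam[30])
    scaled = Spectrum(wavelengths=two.wavelengths, intensities=(7.0, 21.0))
    assert center_of_mass(scaled) == pytest.approx(center_of_mass(two))


def test_spectrum_validation():
    with pytest.raises(ValidationError):
        Spectrum(wavelengths=(300.0, 300.0), intensities=(1.0, 1.0))
    with pytest.raises(ValidationError):
        Spectrum(wavelengths=(300.0, 302.0), intensities=(0.0, 0.0))


def test_mean_residue_ellipticity():
    assert mean_residue_ellipticity(10.0, 1.0, 1e-6, 100) == pytest.approx(1e4)
    assert mean_residue_ellipticity(0.0, 1.0, 1e-6, 100) == 0.0
    half = mean_residue_ellipticity(10.0, 1.0, 2e-6, 100)
    assert half == pytest.approx(0.5e4)
    with pytest.raises(ValidationError):
        mean_residue_ellipticity(10.0, 0.0, 1e-6, 100)


@pytest.mark.parametrize("tm", [46.0, 39.4])
def test_thermal_melt_noiseless_recovery(tm):
    fit = fit_thermal_melt(melt_trace(tm))
    assert fit.converged
    assert fit.tm_c == pytest.approx(tm, abs=1e-3)
    assert fit.dh_vh_kj == pytest.approx(300.0, rel=1e-3)


def test_thermal_melt_with_sloped_baselines():
    fit = fit_thermal_melt(melt_trace(43.0, baselines=(334.0, 0.05, 349.0, 0.02)))
    assert fit.converged and fit.tm_c == pytest.approx(43.0, abs=1e-3)
    assert fit.b_n == pytest.approx(0.05, abs=1e-4)


def test_thermal_melt_steep_limit_is_half_transition():
    """As dH grows the fitted Tm approaches the half-transition abscissa."""
    trace = melt_trace(45.3, dh_kj=2500.0)
    x, y = np.asarray(trace.x), np.asarray(trace.y)
    half = (y[0] + y[-1]) / 2
    crossing = np.interp(half, y, x)  # y monotone for flat baselines
    fit = fit_thermal_melt(trace)
    assert fit.tm_c == pytest.approx(crossing, abs=0.5)
    assert fit.tm_c == pytest.approx(45.3, abs=0.1)


def test_thermal_melt_flat_trace_flagged_not_raised():
    flat = Trace(x=tuple(range(20, 40)), y=(5.0,) * 20)
    fit = fit_thermal_melt(flat)
    assert not fit.converged and "flat" in fit.message


def test_melt_spectra_center_of_mass_feeds_fit():
    """Spectral reduction end to end: scan COMs trace out the melt curve."""
    scans = melt_spectra(44.0)
    trace = Trace(x=tuple(t for t, _ in scans), y=tuple(center_of_mass(s) for _, s in scans))
    fit = fit_thermal_melt(trace)
    assert fit.converged and fit.tm_c == pytest.approx(44.0, abs=0.05)


def test_denaturation_exclusion_rule_and_recovery():
    trace = denat_trace(20.0, 10.0)
    assert 3.0 in trace.x
    fit = fit_chemical_denaturation(trace)
    assert fit.n_excluded == 1  # the single 3.0 M point
    assert fit.converged
    assert fit.dg_h2o_kj == pytest.approx(20.0, rel=0.01)
    assert fit.m_value_kj_per_m == pytest.approx(10.0, rel=0.01)
    assert fit.cm_molar == pytest.approx(2.0, rel=0.01)


def test_denaturation_insufficient_points_after_exclusion():
    trace = denat_trace(20.0, 10.0, grid_m=tuple(np.linspace(2.8, 4.0, 10)))
    with pytest.raises(ValidationError, match="excluding"):
        fit_chemical_denaturation(trace)


def test_denaturation_flat_trace_flagged():
    flat = Trace(x=tuple(np.linspace(0, 2.8, 12)), y=(3.0,) * 12)
    fit = fit_chemical_denaturation(flat)
    assert not fit.converged and fit.n_excluded == 0


def test_first_order_decay_recovery():
    fit = fit_first_order_decay(kinetic_trace(0.01))
    assert fit.converged
    assert fit.k == pytest.approx(0.01, rel=1e-3)
    assert fit.a0 == pytest.approx(0.25, rel=1e-3)
    trace = kinetic_trace(0.01)
    assert trace.y[0] == pytest.approx(0.25)  # t=0 equals A0 exactly
    const = Trace(x=tuple(range(10)), y=(2.0,) * 10)
    cfit = fit_first_order_decay(const)
    assert cfit.k == 0.0 and cfit.converged


def test_reduce_plate_reads():
    assert reduce_plate_reads(list(range(1, 10)), n_last=5) == pytest.approx(7.0)
    assert reduce_plate_reads([4.0, 4.0, 4.0], n_last=3) == pytest.approx(4.0)
    with pytest.raises(ValidationError):
        reduce_plate_reads([1.0, 2.0], n_last=5)


def test_relative_rates():
    fits = {
        "WT": KineticFit(k=0.01, a0=1, a_inf=0, residual_norm=0, converged=True),
        "3mPHP": KineticFit(k=0.005, a0=1, a_inf=0, residual_norm=0, converged=True),
    }
    rel = relative_rates(fits, "WT")
    assert rel["WT"] == pytest.approx(1.0)
    assert rel["3mPHP"] == pytest.approx(0.5)
    scaled = {
        name: KineticFit(k=f.k * 7.3, a0=1, a_inf=0, residual_norm=0, converged=True)
        for name, f in fits.items()
    }
    assert relative_rates(scaled, "WT")["3mPHP"] == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        relative_rates({"z": KineticFit(k=0.0, a0=1, a_inf=0, residual_norm=0, converged=True)}, "z")


def test_trace_csv_round_trip(tmp_path):
    trace = melt_trace(46.0)
    p = tmp_path / "melt.csv"
    write_trace_csv(trace, p, names=("temp_C", "com_nm"))
    back = read_trace_csv(p)
    assert np.allclose(back.x, trace.x) and np.allclose(back.y, trace.y)
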