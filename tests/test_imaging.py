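"""Detector model against closed forms: Beer-Lambert, CNR, heel averaging."""

import numpy as np
import pytest

from kedgesim import imaging
from kedgesim import materials as mat

from conftest import mono_spectrum


def test_transmission_matches_beer_lambert_for_mono_beam():
    spec = mono_spectrum(60.0)
    w = mat.water()
    t_cm = 5.0
    expected = np.exp(-mat.linear_attenuation(w, 60.0) * t_cm)
    got = imaging.simulate_transmission(spec, [(w, t_cm)], mode="counting")
    assert got == pytest.approx(expected, rel=1e-12)
    # integrating mode scales by the photon energy
    got_e = imaging.simulate_transmission(spec, [(w, t_cm)], mode="integrating")
    assert got_e == pytest.approx(60.0 * expected, rel=1e-12)


def test_transmission_multiplicative_over_path_segments():
    spec = mono_spectrum(80.0)
    w, p = mat.water(), mat.pmma()
    both = imaging.simulate_transmission(spec, [(w, 2.0), (p, 3.0)])
    w_only = imaging.simulate_transmission(spec, [(w, 2.0)])
    p_only = imaging.simulate_transmission(spec, [(p, 3.0)])
    assert both == pytest.approx(w_only * p_only, rel=1e-12)


def test_transmission_validates_inputs():
    spec = mono_spectrum(60.0)
    with pytest.raises(ValueError):
        imaging.simulate_transmission(spec, [(mat.water(), -1.0)])
    with pytest.raises(ValueError):
        imaging.simulate_transmission(spec, [], mode="bogus")


def test_roi_image_poisson_moments_and_reproducibility():
    img1 = imaging.simulate_roi_image(1000.0, (200, 200), seed=3)
    img2 = imaging.simulate_roi_image(1000.0, (200, 200), seed=3)
    np.testing.assert_array_equal(img1.pixels, img2.pixels)
    st = imaging.roi_stats(img1)
    assert st.mean == pytest.approx(1000.0, rel=0.01)
    assert st.sd == pytest.approx(np.sqrt(1000.0), rel=0.05)
    assert st.n == 40000


def test_cnr_closed_form():
    s = imaging.RoiStats(mean=12.0, sd=3.0, n=100)
    w = imaging.RoiStats(mean=10.0, sd=0.5, n=100)
    assert imaging.cnr(s, w) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        imaging.cnr(s, imaging.RoiStats(mean=10.0, sd=0.0, n=100))


def test_heel_average_cancels_linear_gain_ramp():
    rng = np.random.default_rng(0)
    base = rng.poisson(500.0, size=(64, 64)).astype(float)
    ramp = np.linspace(0.9, 1.1, 64)[None, :]
    img_a = imaging.ProjectionImage(base * ramp, mode="counting")
    img_b = imaging.ProjectionImage(base * ramp[:, ::-1], mode="counting")
    avg = imaging.heel_average(img_a, img_b)
    np.testing.assert_allclose(avg.pixels, base, rtol=1e-12)


def test_predicted_hu_signs_and_magnitudes(spectrum_120):
    assert imaging.predicted_hu(spectrum_120, mat.water()) == pytest.approx(0.0)
    assert imaging.predicted_hu(spectrum_120, mat.air()) == pytest.approx(-1000.0)
    sol = mat.solution_material("I", 100.0)
    assert imaging.predicted_hu(spectrum_120, sol) > 100.0


def test_attenuation_ratio_validation():
    assert imaging.attenuation_ratio(2.0, 1.0) == pytest.approx(2.0)
    assert imaging.attenuation_ratio(2.0, 1.0, kerma=2.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        imaging.attenuation_ratio(1.0, 0.0)
    with pytest.raises(ValueError):
        imaging.attenuation_ratio(1.0, 1.0, kerma=0.0)
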