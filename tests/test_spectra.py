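"""Spectrum model invariants: normalization, hardening, grid stability."""

import numpy as np
import pytest

from kedgesim import materials as mat
from kedgesim import spectra as sp


def _filtered(kvp, inherent, cu_mm=0.0, **kw):
    stack = sp.standard_stack(inherent, cu_mm)
    return sp.apply_filtration(sp.generate_spectrum(kvp, **kw), stack)


def test_unit_fluence_and_support():
    spec = sp.generate_spectrum(120.0)
    assert spec.total_fluence == pytest.approx(1.0)
    assert spec.bin_centers[spec.fluence > 0].max() < 120.0
    assert spec.bin_centers.min() >= 5.0


def test_kvp_bounds():
    with pytest.raises(ValueError):
        sp.generate_spectrum(20.0)
    with pytest.raises(ValueError):
        sp.generate_spectrum(300.0)


def test_tungsten_k_lines_present_above_threshold():
    hard = sp.generate_spectrum(120.0)
    soft = sp.generate_spectrum(60.0)  # below the W K edge at 69.5 keV
    line = 59.5  # strongest K-alpha line bin
    i_hard = np.argmin(np.abs(hard.bin_centers - line))
    # a characteristic line shows as a local spike over its neighbors
    assert hard.fluence[i_hard] > 1.5 * hard.fluence[i_hard - 2]
    i_soft = np.argmin(np.abs(soft.bin_centers - line))
    if soft.fluence.size > i_soft + 2 and soft.fluence[i_soft - 2] > 0:
        assert soft.fluence[i_soft] < 1.5 * soft.fluence[i_soft - 2]


def test_beam_hardening_monotonic_in_copper():
    means = [sp.mean_energy(_filtered(120.0, [("Al", 1.0)], cu))
             for cu in (0.0, 0.3, 0.6, 1.2, 1.6, 2.5)]
    assert all(b > a for a, b in zip(means, means[1:]))


def test_mean_energy_increases_with_kvp():
    means = [sp.mean_energy(_filtered(k, [("Al", 2.0)]))
             for k in (60.0, 90.0, 120.0, 150.0)]
    assert all(b > a for a, b in zip(means, means[1:]))


def test_grid_stability():
    ref = sp.mean_energy(_filtered(120.0, [("Al", 1.0), ("Be", 0.15)],
                                   0.6, energy_step=0.5))
    for step in (0.25, 1.0):
        alt = sp.mean_energy(_filtered(120.0, [("Al", 1.0), ("Be", 0.15)],
                                       0.6, energy_step=step))
        assert alt == pytest.approx(ref, rel=1e-3)


def test_filtration_conserves_or_reduces_fluence():
    raw = sp.generate_spectrum(100.0)
    filtered = sp.apply_filtration(raw, sp.standard_stack([("Al", 2.0)], 0.5))
    assert filtered.total_fluence < raw.total_fluence
    assert np.all(filtered.fluence <= raw.fluence + 1e-15)


def test_match_mean_energy_converges_and_validates():
    cfg = sp.ScanConfig("x", 120.0,
                        sp.standard_stack([("Al", 3.9)], 0.0))
    target = 60.0
    spec = sp.match_mean_energy(cfg, target)
    assert sp.mean_energy(spec) == pytest.approx(target, abs=0.05)
    with pytest.raises(ValueError):
        sp.match_mean_energy(cfg, 20.0)  # already harder than that


def test_spectrum_csv_round_trip(tmp_path):
    spec = _filtered(90.0, [("Al", 1.5)], 0.2)
    path = tmp_path / "spec.csv"
    sp.write_spectrum_csv(spec, path)
    back = sp.read_spectrum_csv(path)
    np.testing.assert_allclose(back.bin_centers, spec.bin_centers)
    np.testing.assert_allclose(back.fluence, spec.fluence, rtol=1e-6,
                               atol=1e-30)  # CSV stores 8 significant digits
    assert back.kvp == spec.kvp


def test_air_kerma_weight_positive_and_hardening_sensitive():
    soft = _filtered(120.0, [("Al", 1.0)])
    hard = _filtered(120.0, [("Al", 1.0)], 1.5)
    k_soft, k_hard = sp.air_kerma_weight(soft), sp.air_kerma_weight(hard)
    assert k_soft > k_hard > 0  # filtration removes fluence, thus kerma
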