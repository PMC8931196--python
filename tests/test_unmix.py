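"""Spectral unmixing: NNLS recovery, SO2 derivation, group contrasts."""

import itertools

import numpy as np
import pytest

from tracheapat import unmix as ux
from tracheapat.errors import TracheaPatError
from tracheapat.optics import extinction_matrix
from tracheapat.phantom import CHROMOPHORES
from tracheapat.recon import ReconImage


def _stack_from_pixels(Y, shape=(2, 2)):
    """Build a co-registered stack whose every pixel has spectrum Y (n_l,)."""
    return [ReconImage(pixels=np.full(shape, y), spacing=0.05, origin=(0, 0),
                       wavelength_nm=w)
            for y, w in zip(Y, (760, 840, 910))]


@pytest.fixture(scope="module")
def E(table):
    return extinction_matrix(table)


#: composition classes the phantom can produce (all identifiable):
#: vessel = HbO2/HbR pair, wall = HbO2 + collagen + water, scar/granulation mixes
IDENTIFIABLE_SUPPORTS = [(0, 1), (0, 2), (0, 3), (2, 3), (0, 1, 2), (0, 2, 3)]


@pytest.mark.parametrize("cols", IDENTIFIABLE_SUPPORTS)
def test_phantom_composition_pixels_recover_exactly(E, cols):
    """Noiseless y = E c* recovers c* to 1e-8 for phantom-type compositions."""
    rng = np.random.default_rng(sum(cols))
    c_true = np.zeros(4)
    c_true[list(cols)] = rng.uniform(0.1, 2.0, size=len(cols))
    maps = ux.unmix(_stack_from_pixels(E @ c_true), E)
    c_est = np.array([maps.maps[c][0, 0] for c in CHROMOPHORES])
    np.testing.assert_allclose(c_est, c_true, atol=1e-8)
    assert np.all(maps.residual <= 1e-10)


def test_wall_and_vessel_mixtures_recover_exactly(E):
    """The exact mixtures the phantom rasterizes are uniquely decodable."""
    for c_true in ([0.08, 0.0, 0.2, 0.65],    # healthy wall
                   [0.08, 0.0, 0.2, 0.975],   # edema wall (water boost)
                   [0.08, 0.0, 0.4, 0.65],    # scar wall (collagen boost)
                   [0.225, 0.075, 0.0, 0.0]):  # vessel blood
        maps = ux.unmix(_stack_from_pixels(E @ np.asarray(c_true)), E)
        c_est = np.array([maps.maps[c][0, 0] for c in CHROMOPHORES])
        np.testing.assert_allclose(c_est, c_true, atol=1e-8)


def test_water_without_collagen_is_ambiguous_but_exactly_fit(E):
    """Three wavelengths cannot separate lone water from a collagen mix.

    For water-containing pixels lacking collagen the zero-residual solution
    is not unique; NNLS returns a valid exact representation (residual 0,
    E c = y) whose support may differ.  The phantom avoids this class by
    construction (wall water always co-occurs with collagen).
    """
    c_true = np.array([0.5, 0.8, 0.0, 1.5])  # hbo2 + hbr + water, no collagen
    y = E @ c_true
    maps = ux.unmix(_stack_from_pixels(y), E)
    c_est = np.array([maps.maps[c][0, 0] for c in CHROMOPHORES])
    assert np.all(maps.residual <= 1e-10)
    np.testing.assert_allclose(E @ c_est, y, atol=1e-10)


def test_zero_pixels_stay_exactly_zero(E):
    maps = ux.unmix(_stack_from_pixels([0.0, 0.0, 0.0]), E)
    for c in CHROMOPHORES:
        assert np.all(maps.maps[c] == 0)
    assert np.all(maps.residual == 0)


def test_pure_spectrum_times_five_recovers_concentration_five(E):
    for i, name in enumerate(CHROMOPHORES):
        maps = ux.unmix(_stack_from_pixels(5.0 * E[:, i]), E)
        assert maps.maps[name][0, 0] == pytest.approx(5.0, abs=1e-8)
        others = [maps.maps[c][0, 0] for c in CHROMOPHORES if c != name]
        np.testing.assert_allclose(others, 0.0, atol=1e-8)


def test_scaling_equivariance_and_so2_invariance(E):
    c_true = np.array([0.8, 0.4, 0.0, 0.6])
    y = E @ c_true
    m1 = ux.unmix(_stack_from_pixels(y), E)
    m3 = ux.unmix(_stack_from_pixels(3.0 * y), E)
    for c in CHROMOPHORES:
        np.testing.assert_allclose(m3.maps[c], 3.0 * m1.maps[c], atol=1e-8)
    np.testing.assert_allclose(m3.so2(), m1.so2(), atol=1e-10)


def test_wavelength_count_mismatch_raises(E):
    with pytest.raises(TracheaPatError):
        ux.unmix(_stack_from_pixels([1.0, 2.0, 3.0])[:2], E)


def test_oxygen_saturation_limits():
    mk = lambda hbo2, hbr: ux.UnmixedMaps(
        maps={"hbo2": np.full((2, 2), hbo2), "hbr": np.full((2, 2), hbr),
              "collagen": np.zeros((2, 2)), "water": np.zeros((2, 2))},
        residual=np.zeros((2, 2)), spacing=0.05, origin=(0, 0))
    np.testing.assert_allclose(ux.oxygen_saturation(mk(1.0, 1.0), 0.1), 0.5)
    np.testing.assert_allclose(ux.oxygen_saturation(mk(2.0, 0.0), 0.1), 1.0)
    # zero total hemoglobin is masked, never 0/0
    so2 = ux.oxygen_saturation(mk(0.0, 0.0), 0.1)
    assert np.all(np.isnan(so2))
    with pytest.raises(ValueError):
        ux.oxygen_saturation(mk(1.0, 1.0), -0.5)


def test_so2_default_mask_suppresses_low_hbt_pixels():
    maps = {"hbo2": np.zeros((4, 4)), "hbr": np.zeros((4, 4)),
            "collagen": np.zeros((4, 4)), "water": np.zeros((4, 4))}
    maps["hbo2"][0, 0] = 1.0  # bright perfused pixel
    maps["hbo2"][3, 3] = 1e-4  # noise-level pixel
    m = ux.UnmixedMaps(maps=maps, residual=np.zeros((4, 4)), spacing=0.05,
                       origin=(0, 0))
    so2 = m.so2()
    assert so2[0, 0] == pytest.approx(1.0)
    assert np.isnan(so2[3, 3])


def test_group_contrast_identity_and_errors(E):
    m = ux.unmix(_stack_from_pixels(E @ np.array([1.0, 0.5, 0.2, 0.0])), E)
    mask = np.ones((2, 2), dtype=bool)
    tbl = ux.group_contrast(m, m, mask).set_index("chromophore")
    active = tbl[tbl["mean_x"] > 0]
    np.testing.assert_allclose(active["ratio"], 1.0)
    with pytest.raises(TracheaPatError):
        ux.group_contrast(m, m, np.zeros((2, 2), dtype=bool))
    with pytest.raises(TracheaPatError):
        ux.group_contrast(m, m, np.ones((3, 3), dtype=bool))


def test_unmixed_maps_tiff_roundtrip(tmp_path, E):
    m = ux.unmix(_stack_from_pixels(E @ np.array([0.3, 0.1, 0.0, 0.9])), E)
    path = tmp_path / "u.tif"
    m.save_tiff(path)
    back = ux.UnmixedMaps.load_tiff(path)
    for c in CHROMOPHORES:
        np.testing.assert_allclose(back.maps[c], m.maps[c], rtol=1e-6, atol=1e-9)
    assert back.wavelengths_nm == m.wavelengths_nm
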