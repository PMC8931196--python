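"""Phantom generator: determinism, distributions, respiration, rasterization."""

import dataclasses
import math

import numpy as np
import pytest

from tracheapat import phantom as ph
from tracheapat.errors import DegenerateSpecError, GeometryError


def test_same_spec_and_seed_give_identical_phantoms():
    spec = ph.DEFAULT_GROUP_SPECS["C"]
    a = ph.make_phantom(spec, 42)
    b = ph.make_phantom(spec, 42)
    assert a == b
    assert ph.make_phantom(spec, 43) != a


def test_zero_variance_spec_draws_exact_means():
    spec = ph.GroupSpec("A", twt_mean=0.82, twt_sd=0.0, csa_mean=16.28, csa_sd=0.0)
    p = ph.make_phantom(spec, 0)
    assert p.wall_thickness == 0.82
    assert p.true_csa == pytest.approx(16.28, abs=1e-12)
    assert p.true_csa == pytest.approx(math.pi * p.lumen_radius**2, abs=1e-9)


@pytest.mark.parametrize("label", ["A", "B", "C", "D"])
def test_cohort_statistics_match_spec(label):
    """Generator self-consistency: empirical moments within CLT bounds."""
    spec = ph.DEFAULT_GROUP_SPECS[label]
    cohort = ph.sample_cohort(spec, 200, seed=7)
    twt = np.array([p.wall_thickness for p in cohort])
    csa = np.array([p.true_csa for p in cohort])
    assert abs(twt.mean() - spec.twt_mean) < 4 * spec.twt_sd / np.sqrt(200)
    assert abs(csa.mean() - spec.csa_mean) < 4 * spec.csa_sd / np.sqrt(200)
    # sd estimate has standard error ~ sd / sqrt(2 n)
    assert abs(twt.std(ddof=1) - spec.twt_sd) < 5 * spec.twt_sd / np.sqrt(400)


def test_cohort_reproducible_and_distinct():
    spec = ph.DEFAULT_GROUP_SPECS["A"]
    a = ph.sample_cohort(spec, 3, seed=1)
    b = ph.sample_cohort(spec, 3, seed=1)
    c = ph.sample_cohort(spec, 3, seed=2)
    assert a == b
    assert a != c
    assert len({p.lumen_radius for p in a}) == 3
    with pytest.raises(ValueError):
        ph.sample_cohort(spec, 0, seed=1)


def test_truncation_surfaces_degenerate_draws():
    rng = np.random.default_rng(0)
    with pytest.raises(DegenerateSpecError):
        ph._truncated_positive_normal(rng, -5.0, 0.1, "test")
    with pytest.raises(DegenerateSpecError):
        ph._truncated_positive_normal(rng, -1.0, 0.0, "test")


def test_respiration_closed_form_and_conservation():
    spec = ph.GroupSpec("A", 0.82, 0.0, 16.28, 0.0)
    p = ph.make_phantom(spec, 0)
    a = 0.15
    assert ph.apply_respiration(p, 0.0, a).true_csa == pytest.approx(p.true_csa)
    end_inhale = ph.apply_respiration(p, math.pi, a)
    assert end_inhale.true_csa == pytest.approx(p.true_csa * (1 + a), rel=1e-12)

    wall_area = math.pi * (p.outer_radius**2 - p.lumen_radius**2)
    phases = np.linspace(0, math.pi, 8)
    csas = []
    for phase in phases:
        q = ph.apply_respiration(p, float(phase), a)
        csas.append(q.true_csa)
        wa = math.pi * (q.outer_radius**2 - q.lumen_radius**2)
        assert wa == pytest.approx(wall_area, rel=1e-6)
    assert np.all(np.diff(csas) > 0), "CSA must rise monotonically to end-inhalation"


def test_respiration_keeps_inclusions_inside_the_wall():
    p = ph.make_phantom(ph.DEFAULT_GROUP_SPECS["C"], 5)
    for phase in (0.0, math.pi / 2, math.pi):
        q = ph.apply_respiration(p, phase)
        for inc in q.inclusions:
            rho = math.hypot(inc.x, inc.y)
            assert rho - inc.radius > q.lumen_radius
            assert rho + inc.radius < q.outer_radius + 1e-9


def test_respiration_parameter_errors():
    p = ph.make_phantom(ph.DEFAULT_GROUP_SPECS["A"], 0)
    with pytest.raises(ValueError):
        ph.apply_respiration(p, 7.0)
    with pytest.raises(ValueError):
        ph.apply_respiration(p, 0.0, depth=-0.1)
    with pytest.raises(ValueError):
        ph.apply_respiration(p, 0.0, depth=1.0)


def test_rasterized_lumen_matches_lattice_count_oracle():
    """Pixel-center-in-disk counting, checked against an independent count."""
    spec = ph.GroupSpec("A", 0.82, 0.0, 16.28, 0.0, vessel_density=0)
    p = ph.make_phantom(spec, 0)
    errors = []
    for spacing in (0.2, 0.1, 0.05):
        cmap = ph.rasterize(p, spacing=spacing)
        lumen = ph.lumen_mask(p, cmap)
        # independent oracle: brute-force lattice count over pixel centers
        n = cmap.shape[0]
        axis = (np.arange(n) - (n - 1) / 2.0) * spacing
        count = sum(1 for x in axis for y in axis
                    if math.hypot(x, y) < p.lumen_radius)
        assert lumen.sum() == count
        err = abs(count * spacing**2 - p.true_csa)
        # boundary-cell bound on the pixelization error of a disk
        assert err < 1.5 * 2 * math.pi * p.lumen_radius * spacing
        errors.append(err)
    assert errors[-1] < errors[0], "refinement must reduce the CSA error"


def test_rasterize_chromophore_assignments():
    p = ph.make_phantom(ph.DEFAULT_GROUP_SPECS["C"], 3)
    cmap = ph.rasterize(p)
    stack = cmap.stack()
    lumen = ph.lumen_mask(p, cmap)
    assert np.all(stack[:, lumen] == 0), "air lumen must carry no chromophores"
    assert np.all(stack >= 0)
    active = (stack > 0).sum(axis=0)
    assert active.max() <= 3, "at most 3 chromophores per pixel (identifiability)"
    # vessels carry the HbO2/HbR pair only
    inc = p.inclusions[0]
    xx, yy = cmap.coordinates()
    core = np.hypot(xx - inc.x, yy - inc.y) < inc.radius * 0.5
    assert np.all(cmap.maps["hbr"][core] > 0)
    assert np.all(cmap.maps["collagen"][core] == 0)


def test_rasterize_rejects_out_of_field_phantom():
    p = ph.make_phantom(ph.DEFAULT_GROUP_SPECS["A"], 0)
    big = dataclasses.replace(p, center=(10.0, 0.0))
    with pytest.raises(GeometryError):
        ph.rasterize(big, fov_mm=12.8)


def test_group_boosts_reach_the_rasterized_maps():
    base = ph.rasterize(ph.make_phantom(ph.DEFAULT_GROUP_SPECS["A"], 1))
    edema = ph.rasterize(ph.make_phantom(ph.DEFAULT_GROUP_SPECS["B"], 1))
    scar = ph.rasterize(ph.make_phantom(ph.DEFAULT_GROUP_SPECS["D"], 1))
    assert edema.maps["water"].max() == pytest.approx(1.5 * base.maps["water"].max())
    assert scar.maps["collagen"].max() == pytest.approx(2.0 * base.maps["collagen"].max())


def test_phantom_json_roundtrip(tmp_path):
    p = ph.make_phantom(ph.DEFAULT_GROUP_SPECS["C"], 9)
    path = tmp_path / "p.json"
    ph.save_phantom(p, path)
    assert ph.load_phantom(path) == p


def test_chromophore_map_tiff_roundtrip(tmp_path):
    cmap = ph.rasterize(ph.make_phantom(ph.DEFAULT_GROUP_SPECS["B"], 2))
    path = tmp_path / "m.tif"
    cmap.save_tiff(path)
    back = ph.ChromophoreMap.load_tiff(path)
    assert back.spacing == cmap.spacing
    assert back.origin == pytest.approx(cmap.origin)
    for name in ph.CHROMOPHORES:
        np.testing.assert_allclose(back.maps[name], cmap.maps[name], rtol=1e-6)
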