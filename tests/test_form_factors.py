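"""Physics of the nine form-factor kernels against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from saxsshape import (
    ParticleModel,
    UnsupportedShapeError,
    ValidationError,
    oriented_amplitude,
    orientational_average,
    polydisperse_intensity,
    shape_volume,
)

from .oracles import analytic_sphere_phi, debye_pq, truncated_gaussian_sizes

SLDS = (20.0, 35.0, 9.47)  # core, shell, solvent


@pytest.mark.parametrize(
    "shape, geometry",
    [
        ("sphere", {"radius": 80.0}),
        ("cylinder", {"radius": 30.0, "length": 200.0}),
        ("prolate_ellipsoid", {"r_polar": 120.0, "r_equatorial": 40.0}),
        ("oblate_ellipsoid", {"r_polar": 30.0, "r_equatorial": 90.0}),
        ("core_shell_sphere", {"radius": 60.0, "shell_thickness": 20.0}),
        ("core_shell_cylinder", {"radius": 25.0, "length": 150.0, "shell_thickness": 10.0}),
        ("core_shell_prolate", {"r_polar": 100.0, "r_equatorial": 50.0, "shell_thickness": 15.0}),
        ("core_shell_oblate", {"r_polar": 40.0, "r_equatorial": 110.0, "shell_thickness": 15.0}),
        ("hollow_sphere", {"radius": 70.0, "shell_thickness": 25.0}),
    ],
)
def test_zero_q_amplitude_is_contrast_weighted_volume(shape, geometry):
    """F(q→0) equals the Δρ-weighted particle volume for every shape."""
    sld_core, sld_shell, sld_solvent = SLDS
    if shape == "hollow_sphere":
        sld_core = sld_solvent
    amp = oriented_amplitude(shape, geometry, SLDS, np.array([1e-10]), 0.3)
    v_core = shape_volume(shape, geometry, outer=False)
    if "shell_thickness" in geometry:
        v_outer = shape_volume(shape, geometry, outer=True)
        expected = (sld_core - sld_shell) * v_core + (sld_shell - sld_solvent) * v_outer
    else:
        expected = (sld_core - sld_solvent) * v_core
    assert amp.ravel()[0] == pytest.approx(expected, rel=1e-9)


def test_sphere_first_amplitude_zero_at_4p4934():
    """The sphere amplitude's first zero sits at qR = 4.4934 (tan x = x root)."""
    radius = 50.0
    f = lambda q: float(oriented_amplitude("sphere", {"radius": radius}, SLDS, np.array([q]), 0.0)[0])
    root = brentq(f, 3.5 / radius, 5.5 / radius, xtol=1e-12)
    assert root * radius == pytest.approx(4.493409457909064, abs=1e-6)


def test_core_shell_with_matched_shell_equals_homogeneous_outer_sphere():
    q = np.linspace(1e-4, 0.15, 64)
    cs = oriented_amplitude(
        "core_shell_sphere", {"radius": 50.0, "shell_thickness": 30.0}, (20.0, 20.0, 9.47), q, 0.0
    )
    homog = oriented_amplitude("sphere", {"radius": 80.0}, (20.0, 0.0, 9.47), q, 0.0)
    np.testing.assert_allclose(cs, homog, rtol=1e-12)


def test_degenerate_prolate_matches_sphere():
    q = np.linspace(1e-4, 0.15, 80)
    p_sphere = orientational_average("sphere", {"radius": 80.0}, SLDS, q)
    p_ell = orientational_average(
        "prolate_ellipsoid", {"r_polar": 80.0 + 1e-9, "r_equatorial": 80.0}, SLDS, q
    )
    np.testing.assert_allclose(p_ell, p_sphere, rtol=1e-6)


def test_hollow_sphere_identical_to_solvent_core_shell():
    q = np.linspace(1e-4, 0.15, 50)
    geometry = {"radius": 70.0, "shell_thickness": 25.0}
    hollow = orientational_average("hollow_sphere", geometry, (9.47, 35.0, 9.47), q)
    cs = orientational_average("core_shell_sphere", geometry, (9.47, 35.0, 9.47), q)
    np.testing.assert_array_equal(hollow, cs)


def test_zero_contrast_gives_zero_intensity():
    model = ParticleModel(
        "core_shell_oblate",
        {"r_polar": 40.0, "r_equatorial": 100.0, "shell_thickness": 15.0},
        sld_core=9.47, sld_shell=9.47, sld_solvent=9.47, polydispersity=0.1,
    )
    intensity = polydisperse_intensity(model, np.linspace(1e-3, 0.15, 40))
    i0_scale = 1e-4 * model.volume_fraction * shape_volume(model.shape, model.geometry, outer=True)
    assert np.all(np.abs(intensity) <= 1e-12 * i0_scale)


def test_zero_angle_limit_is_volume_squared():
    """P(0) = (Δρ-weighted volume)² for an anisotropic shape."""
    geometry = {"r_polar": 120.0, "r_equatorial": 40.0}
    p0 = orientational_average("prolate_ellipsoid", geometry, SLDS, np.array([1e-10]))[0]
    expected = ((SLDS[0] - SLDS[2]) * shape_volume("prolate_ellipsoid", geometry)) ** 2
    assert p0 == pytest.approx(expected, rel=1e-8)


def test_intensity_scales_linearly_with_volume_fraction_and_quadratic_in_contrast():
    q = np.linspace(1e-3, 0.1, 20)
    base = ParticleModel("sphere", {"radius": 60.0}, sld_core=12.47, volume_fraction=1e-3)
    doubled_vf = ParticleModel("sphere", {"radius": 60.0}, sld_core=12.47, volume_fraction=2e-3)
    doubled_contrast = ParticleModel("sphere", {"radius": 60.0}, sld_core=15.47, volume_fraction=1e-3)
    i_base = polydisperse_intensity(base, q)
    np.testing.assert_allclose(polydisperse_intensity(doubled_vf, q), 2.0 * i_base, rtol=1e-12)
    np.testing.assert_allclose(polydisperse_intensity(doubled_contrast, q), 4.0 * i_base, rtol=1e-12)


@pytest.mark.parametrize(
    "shape, geometry",
    [
        ("cylinder", {"radius": 20.0, "length": 400.0}),
        ("prolate_ellipsoid", {"r_polar": 150.0, "r_equatorial": 50.0}),
        ("core_shell_sphere", {"radius": 60.0, "shell_thickness": 20.0}),
        ("core_shell_oblate", {"r_polar": 35.0, "r_equatorial": 90.0, "shell_thickness": 12.0}),
    ],
)
def test_orientational_average_matches_debye_monte_carlo(shape, geometry):
    """P(q) agrees with a Debye-formula interior-point oracle within 1%.

    Relative error is asserted where P(q)/P(0) >= 1e-2; in the immediate
    vicinity of the form-factor zeros a relative comparison is not meaningful.
    """
    q = np.linspace(2e-3, 0.1, 20)
    p_analytic = orientational_average(shape, geometry, SLDS, q)
    p_mc = debye_pq(shape, geometry, SLDS, q, n_points=8192, seed=42)
    mask = p_analytic / p_analytic[0] >= 1e-2
    assert mask.sum() >= 10
    rel = np.abs(p_analytic - p_mc)[mask] / p_analytic[mask]
    assert rel.max() < 0.01


def test_polydispersity_zero_reduces_to_monodisperse():
    q = np.linspace(1e-3, 0.15, 60)
    mono = ParticleModel("sphere", {"radius": 100.0}, sld_core=20.0, polydispersity=0.0)
    poly = ParticleModel("sphere", {"radius": 100.0}, sld_core=20.0, polydispersity=1e-12)
    np.testing.assert_allclose(
        polydisperse_intensity(poly, q), polydisperse_intensity(mono, q), rtol=1e-6
    )


def test_polydispersity_fills_minima_and_raises_forward_intensity():
    q = np.linspace(1e-3, 0.15, 400)
    mono = ParticleModel("sphere", {"radius": 100.0}, sld_core=20.0)
    poly = ParticleModel("sphere", {"radius": 100.0}, sld_core=20.0, polydispersity=0.15)
    i_mono = polydisperse_intensity(mono, q)
    i_poly = polydisperse_intensity(poly, q)
    # ⟨V²⟩ >= ⟨V⟩² lifts the zero-angle intensity
    assert i_poly[0] >= i_mono[0]
    # the first sharp minimum (near q = 4.4934/R) is filled in
    window = (q > 0.040) & (q < 0.050)
    assert i_poly[window].min() > 10.0 * i_mono[window].min()


def test_size_average_quadrature_matches_monte_carlo():
    """11-node size quadrature vs 1e5-sample Monte-Carlo average within 0.5%."""
    radius, pd = 100.0, 0.10
    q = np.linspace(1e-3, 0.12, 25)
    model = ParticleModel("sphere", {"radius": radius}, sld_core=20.0, polydispersity=pd)
    i_quad = polydisperse_intensity(model, q, n_pd_points=11)

    rng = np.random.default_rng(7)
    radii = truncated_gaussian_sizes(radius, pd, 100000, rng)
    volumes = 4 * np.pi / 3 * radii**3
    contrast = 20.0 - 9.47
    f_sq = (contrast * volumes[None, :] * analytic_sphere_phi(q[:, None] * radii[None, :])) ** 2
    i_mc = 1e-4 * model.volume_fraction * f_sq.mean(axis=1) / volumes.mean()
    rel = np.abs(i_quad - i_mc) / i_mc
    assert rel.max() < 0.005


def test_validation_errors():
    with pytest.raises(UnsupportedShapeError):
        ParticleModel("dodecahedron", {"radius": 10.0}, sld_core=20.0)
    with pytest.raises(ValidationError):
        ParticleModel("sphere", {"radius": -5.0}, sld_core=20.0)
    with pytest.raises(ValidationError):
        ParticleModel("prolate_ellipsoid", {"r_polar": 30.0, "r_equatorial": 60.0}, sld_core=20.0)
    with pytest.raises(ValidationError):
        ParticleModel("core_shell_sphere", {"radius": 50.0}, sld_core=20.0)  # missing shell
    with pytest.raises(UnsupportedShapeError):
        oriented_amplitude("cube", {"radius": 1.0}, SLDS, np.array([0.01]), 0.0)
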