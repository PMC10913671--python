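"""Analytic SAXS form factors for nine nanoparticle shape classes.

Intensity of a dilute, isotropic suspension of identical (or size-dispersed)
particles.  All lengths are in Å, scattering length densities (SLD) in
1e-6 Å⁻², scattering vectors q in Å⁻¹ and absolute intensities in cm⁻¹.

The nine shape classes are the homogeneous sphere, cylinder, prolate and
oblate ellipsoids of revolution, and their shelled counterparts (core-shell
sphere, hollow sphere, core-shell cylinder, core-shell prolate, core-shell
oblate).  A hollow sphere is a core-shell sphere whose core SLD equals the
solvent SLD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1 as _bessel_j1
from scipy.stats import norm as _norm

SHAPES: tuple[str, ...] = (
    "sphere",
    "cylinder",
    "prolate_ellipsoid",
    "oblate_ellipsoid",
    "core_shell_sphere",
    "hollow_sphere",
    "core_shell_cylinder",
    "core_shell_prolate",
    "core_shell_oblate",
)

CORE_SHELL_SHAPES = frozenset(
    {
        "core_shell_sphere",
        "hollow_sphere",
        "core_shell_cylinder",
        "core_shell_prolate",
        "core_shell_oblate",
    }
)

#: homogeneous base shape underlying each shelled shape
_BASE_SHAPE = {
    "core_shell_sphere": "sphere",
    "hollow_sphere": "sphere",
    "core_shell_cylinder": "cylinder",
    "core_shell_prolate": "prolate_ellipsoid",
    "core_shell_oblate": "oblate_ellipsoid",
}

# absolute-intensity conversion: phi * (1e-6 Å⁻²)² * Å³ -> cm⁻¹
_CM_CONV = 1.0e-4

# default Gauss-Legendre order for the orientational average
DEFAULT_QUAD_ORDER = 76
_MAX_QUAD_ORDER = 1000

# polydispersity: Gaussian in overall size, truncated at ±3 relative sigma
PD_TRUNCATION_NSIGMA = 3.0
DEFAULT_PD_POINTS = 11


class UnsupportedShapeError(ValueError):
    """Raised for a shape name outside the nine supported classes."""


class ValidationError(ValueError):
    """Raised for geometrically invalid particle parameters."""


@dataclass
class ParticleModel:
    """One simulated particle population.

    Parameters
    ----------
    shape : str
        One of :data:`SHAPES`.
    geometry : dict
        Lengths in Å.  Keys by shape: ``radius`` (sphere family),
        ``radius, length`` (cylinder family), ``r_polar, r_equatorial``
        (ellipsoid family), plus ``shell_thickness`` for shelled shapes.
    sld_core, sld_shell, sld_solvent : float
        Scattering length densities in 1e-6 Å⁻².  ``sld_shell`` is ignored
        for homogeneous shapes.
    volume_fraction : float
        Particle volume fraction, dimensionless, dilute (structure factor = 1).
    polydispersity : float
        Relative width sigma_r/r of the Gaussian size distribution applied
        proportionally to all linear dimensions.
    """

    shape: str
    geometry: dict[str, float]
    sld_core: float
    sld_shell: float = 0.0
    sld_solvent: float = 9.47  # water, X-ray, 1e-6 Å⁻²
    volume_fraction: float = 1e-3
    polydispersity: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise UnsupportedShapeError(
                f"unknown shape {self.shape!r}; supported: {', '.join(SHAPES)}"
            )
        for key, value in self.geometry.items():
            if value <= 0:
                raise ValidationError(f"{self.shape}: {key} must be > 0, got {value}")
        needed = _required_geometry(self.shape)
        missing = needed - set(self.geometry)
        if missing:
            raise ValidationError(f"{self.shape}: missing geometry keys {sorted(missing)}")
        if self.shape in ("prolate_ellipsoid", "core_shell_prolate"):
            if not self.geometry["r_polar"] > self.geometry["r_equatorial"]:
                raise ValidationError("prolate requires r_polar > r_equatorial")
        if self.shape in ("oblate_ellipsoid", "core_shell_oblate"):
            if not self.geometry["r_polar"] < self.geometry["r_equatorial"]:
                raise ValidationError("oblate requires r_polar < r_equatorial")
        if not 0 < self.volume_fraction < 1:
            raise ValidationError("volume_fraction must lie in (0, 1)")
        if self.polydispersity < 0:
            raise ValidationError("polydispersity must be >= 0")

    @property
    def is_core_shell(self) -> bool:
        return self.shape in CORE_SHELL_SHAPES

    def effective_slds(self) -> tuple[float, float, float]:
        """(core, shell, solvent) SLDs; hollow sphere forces core = solvent."""
        if self.shape == "hollow_sphere":
            return self.sld_solvent, self.sld_shell, self.sld_solvent
        return self.sld_core, self.sld_shell, self.sld_solvent

    def aspect_ratio(self) -> float | None:
        """r_equatorial / r_polar for ellipsoid classes, else None."""
        if "r_polar" in self.geometry:
            return self.geometry["r_equatorial"] / self.geometry["r_polar"]
        return None


def _required_geometry(shape: str) -> set[str]:
    base = _BASE_SHAPE.get(shape, shape)
    keys: set[str]
    if base == "sphere":
        keys = {"radius"}
    elif base == "cylinder":
        keys = {"radius", "length"}
    else:
        keys = {"r_polar", "r_equatorial"}
    if shape in CORE_SHELL_SHAPES:
        keys.add("shell_thickness")
    return keys


@dataclass
class Curve:
    """One 1D measurement: intensity (cm⁻¹) on a strictly increasing q grid."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    config_id: str | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValidationError("q and intensity must have identical length")
        if self.q.size > 1 and not np.all(np.diff(self.q) > 0):
            raise ValidationError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma must match q length")


# ---------------------------------------------------------------------------
# amplitude kernels
# ---------------------------------------------------------------------------

def _sphere_shape_fn(x: np.ndarray) -> np.ndarray:
    """3 [sin x - x cos x] / x³ with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    # series: 1 - x²/10 + x⁴/280
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _j1c(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x with limit 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = 2.0 * _bessel_j1(x[nz]) / x[nz]
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with limit 1 at x = 0 (unnormalised sinc)."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def shape_volume(shape: str, geometry: dict[str, float], outer: bool = False) -> float:
    """Particle volume in Å³; ``outer=True`` includes the shell."""
    base = _BASE_SHAPE.get(shape, shape)
    g = dict(geometry)
    if outer:
        t = g.get("shell_thickness", 0.0)
        if base == "sphere":
            g["radius"] = g["radius"] + t
        elif base == "cylinder":
            g["radius"] = g["radius"] + t
            g["length"] = g["length"] + 2.0 * t
        else:
            g["r_polar"] = g["r_polar"] + t
            g["r_equatorial"] = g["r_equatorial"] + t
    if base == "sphere":
        return 4.0 * np.pi / 3.0 * g["radius"] ** 3
    if base == "cylinder":
        return np.pi * g["radius"] ** 2 * g["length"]
    return 4.0 * np.pi / 3.0 * g["r_polar"] * g["r_equatorial"] ** 2


def _unit_amplitude(base: str, geometry: dict[str, float], q, alpha) -> np.ndarray:
    """V × shape function for a homogeneous particle at unit contrast.

    ``alpha`` is the angle between the particle symmetry axis and q.
    Broadcasts q against alpha.
    """
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if base == "sphere":
        r = geometry["radius"]
        vol = 4.0 * np.pi / 3.0 * r**3
        return np.broadcast_to(vol * _sphere_shape_fn(q * r), np.broadcast_shapes(q.shape, alpha.shape)).copy()
    if base == "cylinder":
        r, length = geometry["radius"], geometry["length"]
        vol = np.pi * r**2 * length
        ca, sa = np.cos(alpha), np.sin(alpha)
        return vol * _sinc(q * length * ca / 2.0) * _j1c(q * r * sa)
    if base in ("prolate_ellipsoid", "oblate_ellipsoid", "ellipsoid"):
        rp, re = geometry["r_polar"], geometry["r_equatorial"]
        vol = 4.0 * np.pi / 3.0 * rp * re**2
        r_eff = np.sqrt((re * np.sin(alpha)) ** 2 + (rp * np.cos(alpha)) ** 2)
        return vol * _sphere_shape_fn(q * r_eff)
    raise UnsupportedShapeError(f"unknown base shape {base!r}")


def _outer_geometry(shape: str, geometry: dict[str, float]) -> dict[str, float]:
    """Shell added on all faces (cylinder shelled on sides and ends)."""
    base = _BASE_SHAPE[shape]
    t = geometry["shell_thickness"]
    if base == "sphere":
        return {"radius": geometry["radius"] + t}
    if base == "cylinder":
        return {"radius": geometry["radius"] + t, "length": geometry["length"] + 2.0 * t}
    return {"r_polar": geometry["r_polar"] + t, "r_equatorial": geometry["r_equatorial"] + t}


def oriented_amplitude(shape: str, geometry: dict[str, float], slds, q, alpha) -> np.ndarray:
    """Scattering amplitude F(q, alpha) in (1e-6 Å⁻²)·Å³.

    ``slds`` is (sld_core, sld_shell, sld_solvent); for homogeneous shapes the
    shell entry is ignored.  At q → 0 the amplitude equals the contrast-weighted
    particle volume.
    """
    if shape not in SHAPES:
        raise UnsupportedShapeError(f"unknown shape {shape!r}")
    for key, value in geometry.items():
        if value <= 0:
            raise ValidationError(f"{key} must be > 0, got {value}")
    sld_core, sld_shell, sld_solvent = slds
    base = _BASE_SHAPE.get(shape, shape)
    if shape == "hollow_sphere":
        sld_core = sld_solvent
    if shape in CORE_SHELL_SHAPES:
        core = _unit_amplitude(base, geometry, q, alpha)
        outer = _unit_amplitude(base, _outer_geometry(shape, geometry), q, alpha)
        return (sld_core - sld_shell) * core + (sld_shell - sld_solvent) * outer
    return (sld_core - sld_solvent) * _unit_amplitude(base, geometry, q, alpha)


# ---------------------------------------------------------------------------
# orientational average
# ---------------------------------------------------------------------------

_ISOTROPIC = frozenset({"sphere", "core_shell_sphere", "hollow_sphere"})


def _auto_order(shape: str, geometry: dict[str, float], q_max: float) -> int:
    """Quadrature order scaled to the oscillation rate of |F|² over alpha.

    The integrand's phase across the alpha range grows like q·(d_max − d_min)
    where d are the extreme half-dimensions; elongated particles need more
    nodes.
    """
    base = _BASE_SHAPE.get(shape, shape)
    g = geometry if shape not in CORE_SHELL_SHAPES else _outer_geometry(shape, geometry)
    if base == "sphere":
        return DEFAULT_QUAD_ORDER
    if base == "cylinder":
        dmax, dmin = max(g["length"] / 2.0, g["radius"]), min(g["length"] / 2.0, g["radius"])
    else:
        dmax, dmin = max(g["r_polar"], g["r_equatorial"]), min(g["r_polar"], g["r_equatorial"])
    order = int(np.ceil(64 + 1.2 * q_max * (dmax - dmin)))
    return int(np.clip(order, DEFAULT_QUAD_ORDER, _MAX_QUAD_ORDER))


def orientational_average(
    shape: str,
    geometry: dict[str, float],
    slds,
    q_grid,
    order: int | None = None,
    check_convergence: bool = False,
) -> np.ndarray:
    """⟨|F(q, alpha)|²⟩ over isotropic orientations, per q-grid point.

    Integrates |F|² sin(alpha) d(alpha) over [0, π/2] via Gauss-Legendre in
    u = cos(alpha).  Isotropic shapes (sphere family) bypass the quadrature.
    Returned values are ≥ 0 and bounded by the zero-angle value
    (contrast-weighted volume squared).
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if shape in _ISOTROPIC:
        amp = oriented_amplitude(shape, geometry, slds, q_grid, 0.0)
        return amp**2

    if order is None:
        order = _auto_order(shape, geometry, float(q_grid.max()))
    u, w = np.polynomial.legendre.leggauss(order)
    # map [-1, 1] -> [0, 1] in u = cos(alpha)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    alpha = np.arccos(u)
    amp = oriented_amplitude(shape, geometry, slds, q_grid[None, :], alpha[:, None])
    p = w @ amp**2

    if check_convergence:
        p2 = orientational_average(shape, geometry, slds, q_grid, order=2 * order)
        scale = np.max(np.abs(p2)) + 1e-300
        if np.max(np.abs(p - p2)) / scale > 1e-4:
            warnings.warn(
                f"orientational quadrature (order {order}) not converged for {shape}",
                RuntimeWarning,
                stacklevel=2,
            )
    return p


# ---------------------------------------------------------------------------
# polydispersity and absolute intensity
# ---------------------------------------------------------------------------

def _pd_nodes(pd: float, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Size-scale nodes and weights for a ±3σ-truncated Gaussian.

    Gauss-Legendre nodes on the truncated interval, weighted by the Gaussian
    density and renormalised.  If the lower tail would cross zero size the
    interval is clipped there and the weights renormalised (with a warning).
    """
    lo = 1.0 - PD_TRUNCATION_NSIGMA * pd
    hi = 1.0 + PD_TRUNCATION_NSIGMA * pd
    if lo <= 0.0:
        warnings.warn(
            "polydispersity places mass at negative sizes; distribution "
            "truncated at zero and renormalised",
            RuntimeWarning,
            stacklevel=3,
        )
        lo = 1e-3
    x, w = np.polynomial.legendre.leggauss(n_points)
    s = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    weights = w * _norm.pdf(s, loc=1.0, scale=pd)
    weights = weights / weights.sum()
    return s, weights


def polydisperse_intensity(
    model: ParticleModel,
    q_grid,
    n_pd_points: int = DEFAULT_PD_POINTS,
    order: int | None = None,
) -> np.ndarray:
    """Absolute scattered intensity I(q) in cm⁻¹ for one particle population.

    I(q) = 1e-4 · φ · ⟨|F(q)|²⟩ / ⟨V⟩, the size average taken over a Gaussian
    distribution of the overall size (all lengths scaled together) truncated
    at ±3σ.  φ is the volume fraction; the 1e-4 constant converts
    (1e-6 Å⁻²)²·Å³ to cm⁻¹.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    slds = model.effective_slds()
    if model.polydispersity == 0.0:
        p = orientational_average(model.shape, model.geometry, slds, q_grid, order=order)
        vol = shape_volume(model.shape, model.geometry, outer=model.is_core_shell)
        return _CM_CONV * model.volume_fraction * p / vol

    scales, weights = _pd_nodes(model.polydispersity, n_pd_points)
    p_avg = np.zeros_like(q_grid)
    v_avg = 0.0
    for s, w in zip(scales, weights):
        geom = {k: v * s for k, v in model.geometry.items()}
        p_avg += w * orientational_average(model.shape, geom, slds, q_grid, order=order)
        v_avg += w * shape_volume(model.shape, geom, outer=model.is_core_shell)
    return _CM_CONV * model.volume_fraction * p_avg / v_avg
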