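"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's analytic kernels: the Debye-formula
oracle computes P(q) from quasi-random interior points of a particle, and the
polydispersity oracle averages the analytic sphere intensity over explicit
Monte-Carlo size samples.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm, qmc


def _sobol(n: int, dim: int, seed: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n need not be a power of two here
        return qmc.Sobol(dim, seed=seed, scramble=True).random(n)


def _ball_points(n: int, seed: int) -> np.ndarray:
    """Quasi-random points filling the unit ball (smooth Sobol transform)."""
    s = _sobol(n, 4, seed)
    g = norm.ppf(np.clip(s[:, :3], 1e-12, 1 - 1e-12))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return g * (s[:, 3] ** (1.0 / 3.0))[:, None]


def sample_interior_points(shape: str, geometry: dict, slds, n: int, seed: int):
    """Quasi-random points in the particle's outer volume with local contrast.

    Returns (points (n,3), contrast weights (n,), outer volume).
    """
    sld_core, sld_shell, sld_solvent = slds
    if shape == "sphere":
        pts = _ball_points(n, seed) * geometry["radius"]
        return pts, np.full(n, sld_core - sld_solvent), 4 * np.pi / 3 * geometry["radius"] ** 3
    if shape == "cylinder":
        r, length = geometry["radius"], geometry["length"]
        s = _sobol(n, 3, seed)
        rad = r * np.sqrt(s[:, 0])
        theta = 2 * np.pi * s[:, 1]
        z = length * (s[:, 2] - 0.5)
        pts = np.column_stack([rad * np.cos(theta), rad * np.sin(theta), z])
        return pts, np.full(n, sld_core - sld_solvent), np.pi * r**2 * length
    if shape in ("prolate_ellipsoid", "oblate_ellipsoid"):
        rp, re = geometry["r_polar"], geometry["r_equatorial"]
        pts = _ball_points(n, seed) * [re, re, rp]
        return pts, np.full(n, sld_core - sld_solvent), 4 * np.pi / 3 * rp * re**2
    if shape == "core_shell_sphere":
        rc, t = geometry["radius"], geometry["shell_thickness"]
        pts = _ball_points(n, seed) * (rc + t)
        inside = np.linalg.norm(pts, axis=1) <= rc
        w = np.where(inside, sld_core - sld_solvent, sld_shell - sld_solvent)
        return pts, w, 4 * np.pi / 3 * (rc + t) ** 3
    if shape == "core_shell_oblate":
        rp, re, t = geometry["r_polar"], geometry["r_equatorial"], geometry["shell_thickness"]
        pts = _ball_points(n, seed) * [re + t, re + t, rp + t]
        inside = (pts[:, 0] / re) ** 2 + (pts[:, 1] / re) ** 2 + (pts[:, 2] / rp) ** 2 <= 1.0
        w = np.where(inside, sld_core - sld_solvent, sld_shell - sld_solvent)
        return pts, w, 4 * np.pi / 3 * (rp + t) * (re + t) ** 2
    raise ValueError(shape)


def debye_pq(shape: str, geometry: dict, slds, q, n_points: int = 8192,
             seed: int = 0, n_bins: int = 4096):
    """Debye-formula P(q) = ⟨|F|²⟩ in (contrast·volume)² units.

    Pairwise distances are binned; P(q) = (V/n)² Σ_ij w_i w_j sinc(q r_ij),
    including the i = j terms (distance zero).
    """
    pts, w, volume = sample_interior_points(shape, geometry, slds, n_points, seed)
    d_max = 2.0 * np.max(np.linalg.norm(pts, axis=1)) + 1e-9
    hist = np.zeros(n_bins + 1)
    scale = n_bins / d_max
    chunk = 2048
    for i in range(0, n_points, chunk):
        d = cdist(pts[i : i + chunk], pts)
        idx = np.minimum((d * scale).astype(np.int64), n_bins)
        weights = w[i : i + chunk, None] * w[None, :]
        hist += np.bincount(idx.ravel(), weights=weights.ravel(), minlength=n_bins + 1)
    hist = hist[:n_bins]
    centers = (np.arange(n_bins) + 0.5) * d_max / n_bins
    q = np.asarray(q, dtype=float)
    pq = np.array([(hist * np.sinc(qq * centers / np.pi)).sum() for qq in q])
    return pq * (volume / n_points) ** 2


def truncated_gaussian_sizes(mean: float, rel_sigma: float, n: int,
                             rng: np.random.Generator, n_sigma: float = 3.0) -> np.ndarray:
    """Rejection-sample a Gaussian truncated at ±n_sigma relative widths and zero."""
    out = np.empty(0)
    lo, hi = max(1e-3, 1.0 - n_sigma * rel_sigma), 1.0 + n_sigma * rel_sigma
    while out.size < n:
        draw = rng.normal(1.0, rel_sigma, 2 * n)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return mean * out[:n]


def analytic_sphere_phi(x: np.ndarray) -> np.ndarray:
    """Sphere shape function 3[sin x - x cos x]/x³ (safe at 0)."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    out[nz] = 3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return out
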