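"""Synthetic dataset construction: parameter sampling, dataset builds, I/O.

The generator emulates dilute aqueous nanoparticle suspensions measured on the
two built-in laboratory configurations.  Four dataset builds are supported:

* ``DS_X`` / ``DS_N`` — every curve rendered on a single configuration;
* ``DS_mix`` — each noiseless curve assigned to exactly one of two
  configurations, an exact half/half split;
* ``DS_all`` — each noiseless curve rendered in both configurations (2x size).

Curves from the shorter-range NanoInXider device are capped at
q_max = 0.1511 Å⁻¹ and linearly oversampled onto a fixed-length grid so that
every stored curve has the same input length J = 890.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import __version__ as _pkg_version
from .form_factors import SHAPES, Curve, ParticleModel, ValidationError
from .instrument import InstrumentConfig, builtin_config, simulate_measurement

# --- sampler parameter ranges (Å unless noted) -----------------------------
# One constants block so the ranges can be revised in a single place.
SPHERE_RADIUS_RANGE = (10.0, 1000.0)          # log-uniform
CYLINDER_RADIUS_RANGE = (10.0, 300.0)         # log-uniform
CYLINDER_MAX_LENGTH = 5000.0                  # length log-uniform [4R, this]
ELLIPSOID_R_EQ_RANGE = (10.0, 400.0)          # log-uniform reference radius
ASPECT_RATIO_MAX = 6.0                        # elongation in (1, 6]
SHELL_FRACTION_RANGE = (0.10, 0.50)           # shell thickness / smallest core dim
SLD_CORE_RANGE = (12.0, 120.0)                # log-uniform, 1e-6 Å⁻² (silica..gold)
SLD_SHELL_RANGE = (11.0, 60.0)                # log-uniform
SLD_SOLVENT = 9.47                            # water
MIN_CORE_SHELL_CONTRAST = 2.0                 # |core - shell| floor
MIN_SHELL_SOLVENT_CONTRAST = 1.0
VOLUME_FRACTION_RANGE = (1e-4, 5e-3)          # log-uniform
POLYDISPERSITY_RANGE = (0.0, 0.2)             # uniform

TARGET_J = 890                 # fixed classifier input length
Q_CAP = 1511e-4                # Å⁻¹, cap applied to wide-range configs

_CONFIG_STREAM_INDEX = {"Xeuss1800HR": 0, "NanoInXiderHR": 1}


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameters(shape: str, rng: np.random.Generator) -> ParticleModel:
    """Draw one random particle population of the given shape class.

    Sizes are log-uniform (scale-free coverage of the 1-100 nm range),
    elongation ratios uniform in (1, 6], shell thickness 10-50% of the
    smallest core dimension, polydispersity uniform in [0, 0.2].
    """
    if shape not in SHAPES:
        raise ValidationError(f"unknown shape {shape!r}")
    base_cs = shape.startswith("core_shell") or shape == "hollow_sphere"

    geometry: dict[str, float] = {}
    if shape in ("sphere", "core_shell_sphere", "hollow_sphere"):
        geometry["radius"] = _log_uniform(rng, *SPHERE_RADIUS_RANGE)
        smallest = geometry["radius"]
    elif shape in ("cylinder", "core_shell_cylinder"):
        r = _log_uniform(rng, *CYLINDER_RADIUS_RANGE)
        geometry["radius"] = r
        geometry["length"] = _log_uniform(rng, 4.0 * r, CYLINDER_MAX_LENGTH)
        smallest = r
    else:  # ellipsoids
        r_eq = _log_uniform(rng, *ELLIPSOID_R_EQ_RANGE)
        ratio = rng.uniform(1.0, ASPECT_RATIO_MAX)
        while ratio == 1.0:  # open interval (1, 6]
            ratio = rng.uniform(1.0, ASPECT_RATIO_MAX)
        if shape in ("prolate_ellipsoid", "core_shell_prolate"):
            geometry["r_polar"], geometry["r_equatorial"] = r_eq * ratio, r_eq
        else:
            geometry["r_polar"], geometry["r_equatorial"] = r_eq / ratio, r_eq
        smallest = min(geometry["r_polar"], geometry["r_equatorial"])
    if base_cs:
        geometry["shell_thickness"] = rng.uniform(*SHELL_FRACTION_RANGE) * smallest

    sld_core = _log_uniform(rng, *SLD_CORE_RANGE)
    sld_shell = _log_uniform(rng, *SLD_SHELL_RANGE)
    while (
        abs(sld_shell - sld_core) < MIN_CORE_SHELL_CONTRAST
        or abs(sld_shell - SLD_SOLVENT) < MIN_SHELL_SOLVENT_CONTRAST
    ):
        sld_shell = _log_uniform(rng, *SLD_SHELL_RANGE)

    return ParticleModel(
        shape=shape,
        geometry=geometry,
        sld_core=sld_core,
        sld_shell=sld_shell,
        sld_solvent=SLD_SOLVENT,
        volume_fraction=_log_uniform(rng, *VOLUME_FRACTION_RANGE),
        polydispersity=rng.uniform(*POLYDISPERSITY_RANGE),
    )


@dataclass
class Dataset:
    """N labelled curves on fixed-length (possibly per-curve) q grids."""

    intensities: np.ndarray          # (N, J) cm⁻¹
    q_grids: np.ndarray              # (N, J) Å⁻¹
    labels: np.ndarray               # (N,) int, index into SHAPES
    config_ids: list[str]
    sigmas: np.ndarray | None = None
    params: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.q_grids = np.asarray(self.q_grids, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.intensities.shape != self.q_grids.shape:
            raise ValidationError("intensities and q_grids shapes differ")
        if len(self.labels) != self.intensities.shape[0]:
            raise ValidationError("labels length mismatch")

    @property
    def n_curves(self) -> int:
        return self.intensities.shape[0]

    @property
    def input_length(self) -> int:
        return self.intensities.shape[1]

    def subset(self, mask) -> "Dataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return Dataset(
            self.intensities[idx],
            self.q_grids[idx],
            self.labels[idx],
            [self.config_ids[i] for i in idx],
            None if self.sigmas is None else self.sigmas[idx],
            [self.params[i] for i in idx] if self.params else [],
            dict(self.provenance),
        )

    def exclude_shapes(self, shapes) -> "Dataset":
        """Drop the given shape classes (e.g. cylinders for Franke spaces)."""
        bad = {SHAPES.index(s) for s in shapes}
        return self.subset(~np.isin(self.labels, list(bad)))


def _model_to_params(model: ParticleModel) -> dict:
    return {
        "shape": model.shape,
        "geometry": dict(model.geometry),
        "sld_core": model.sld_core,
        "sld_shell": model.sld_shell,
        "sld_solvent": model.sld_solvent,
        "volume_fraction": model.volume_fraction,
        "polydispersity": model.polydispersity,
    }


def resample_to_grid(curve: Curve, target_grid) -> Curve:
    """Linear interpolation of intensity (and sigma) onto a new q grid.

    The target grid must lie within the source span; extrapolation is refused.
    """
    target_grid = np.asarray(target_grid, dtype=float)
    if target_grid[0] < curve.q[0] - 1e-12 or target_grid[-1] > curve.q[-1] + 1e-12:
        raise ValidationError(
            f"target grid [{target_grid[0]:g}, {target_grid[-1]:g}] extends outside "
            f"source span [{curve.q[0]:g}, {curve.q[-1]:g}]"
        )
    intensity = np.interp(target_grid, curve.q, curve.intensity)
    sigma = None if curve.sigma is None else np.interp(target_grid, curve.q, curve.sigma)
    return Curve(target_grid.copy(), intensity, sigma, curve.config_id)


def _render(model, config, noise_seed, noiseless, target_j, q_cap):
    """Simulate one curve and bring it onto the fixed-length input grid."""
    curve = simulate_measurement(model, config, seed=noise_seed, noiseless=noiseless)
    native = config.n_points == target_j and config.q_max <= q_cap + 1e-12
    if native:
        return curve
    keep = curve.q <= q_cap
    capped = Curve(curve.q[keep], curve.intensity[keep],
                   None if curve.sigma is None else curve.sigma[keep], curve.config_id)
    grid = np.linspace(capped.q[0], min(q_cap, capped.q[-1]), target_j)
    return resample_to_grid(capped, grid)


def build_dataset(
    configs,
    n_per_class: int,
    seed: int,
    mode: str = "single",
    noiseless: bool = False,
    shapes=SHAPES,
    target_j: int = TARGET_J,
    q_cap: float = Q_CAP,
) -> Dataset:
    """Build a balanced labelled dataset.

    Parameters
    ----------
    configs : sequence of str or InstrumentConfig
        One configuration for ``mode='single'``; two for ``'mix'``/``'all'``.
    mode : {'single', 'mix', 'all'}
        'mix' assigns each noiseless curve to one configuration by
        deterministic alternation after a seeded shuffle (exact half/half);
        'all' renders every noiseless curve in every configuration.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    configs = list(configs)
    if not configs:
        raise ValidationError("empty configuration list")
    configs = [c if isinstance(c, InstrumentConfig) else builtin_config(c) for c in configs]
    if mode == "single" and len(configs) != 1:
        raise ValidationError("mode='single' takes exactly one configuration")
    if mode in ("mix", "all") and len(configs) < 2:
        raise ValidationError(f"mode={mode!r} needs at least two configurations")
    if mode not in ("single", "mix", "all"):
        raise ValidationError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    models: list[ParticleModel] = []
    labels: list[int] = []
    for ci, shape in enumerate(shapes):
        for _ in range(n_per_class):
            models.append(sample_parameters(shape, rng))
            labels.append(SHAPES.index(shape))
    n_models = len(models)

    # (model index, config) pairs
    if mode == "all":
        jobs = [(i, cfg) for i in range(n_models) for cfg in configs]
    elif mode == "mix":
        order = rng.permutation(n_models)
        assign = np.empty(n_models, dtype=int)
        assign[order] = np.arange(n_models) % len(configs)
        jobs = [(i, configs[assign[i]]) for i in range(n_models)]
    else:
        jobs = [(i, configs[0]) for i in range(n_models)]

    intensities = np.empty((len(jobs), target_j))
    q_grids = np.empty((len(jobs), target_j))
    sigmas = np.empty((len(jobs), target_j))
    out_labels = np.empty(len(jobs), dtype=int)
    config_ids: list[str] = []
    params: list[dict] = []
    for row, (i, cfg) in enumerate(jobs):
        stream = _CONFIG_STREAM_INDEX.get(cfg.name, 7)
        noise_seed = np.random.SeedSequence((seed, i, stream))
        curve = _render(models[i], cfg, noise_seed, noiseless, target_j, q_cap)
        intensities[row] = curve.intensity
        q_grids[row] = curve.q
        sigmas[row] = 0.0 if curve.sigma is None else curve.sigma
        out_labels[row] = labels[i]
        config_ids.append(cfg.name)
        params.append(_model_to_params(models[i]))

    return Dataset(
        intensities,
        q_grids,
        out_labels,
        config_ids,
        sigmas,
        params,
        provenance={
            "seed": int(seed),
            "mode": mode,
            "n_per_class": int(n_per_class),
            "noiseless": bool(noiseless),
            "configs": [c.name for c in configs],
            "generator_version": _pkg_version,
        },
    )


def truncate_low_q(dataset: Dataset, q_cut: float = 0.005) -> Dataset:
    """Drop all bins with q <= q_cut (artifact rejection for real data).

    The retained length is the largest common suffix over all curves, so the
    matrix stays rectangular; ``q_cut = 0`` is the identity.
    """
    if q_cut <= 0:
        return dataset.subset(np.arange(dataset.n_curves))
    if q_cut >= dataset.q_grids.max():
        raise ValidationError(f"q_cut {q_cut} is above the maximum grid q")
    starts = (dataset.q_grids <= q_cut).sum(axis=1)
    j_new = dataset.input_length - int(starts.max())
    if j_new < 2:
        raise ValidationError(f"q_cut {q_cut} leaves fewer than 2 bins")
    out = dataset.subset(np.arange(dataset.n_curves))
    out.intensities = dataset.intensities[:, -j_new:]
    out.q_grids = dataset.q_grids[:, -j_new:]
    if dataset.sigmas is not None:
        out.sigmas = dataset.sigmas[:, -j_new:]
    return out


# ---------------------------------------------------------------------------
# curve and archive I/O
# ---------------------------------------------------------------------------

class CurveParseError(ValueError):
    """Malformed ASCII curve file; message carries the offending line number."""


def write_curve(curve: Curve, path) -> None:
    """3-column ASCII: q [Å⁻¹], I [cm⁻¹], sigma [cm⁻¹], '#' header lines."""
    with open(path, "w") as fh:
        fh.write("# saxsshape curve\n")
        if curve.config_id:
            fh.write(f"# config: {curve.config_id}\n")
        fh.write("# q[1/A]  I[1/cm]  sigma[1/cm]\n")
        sigma = np.zeros_like(curve.q) if curve.sigma is None else curve.sigma
        for qj, ij, sj in zip(curve.q, curve.intensity, sigma):
            fh.write(f"{qj:.8e} {ij:.8e} {sj:.8e}\n")


def read_curve(path) -> Curve:
    """Parse a 3-column (or 2-column) ASCII curve; '#' lines and blanks skipped."""
    q, intensity, sigma = [], [], []
    config_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if "config:" in stripped:
                    config_id = stripped.split("config:", 1)[1].strip()
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise CurveParseError(f"{path}: line {lineno}: expected >= 2 columns")
            try:
                values = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise CurveParseError(f"{path}: line {lineno}: {exc}") from None
            q.append(values[0])
            intensity.append(values[1])
            sigma.append(values[2] if len(values) > 2 else 0.0)
    if not q:
        raise CurveParseError(f"{path}: no data rows found")
    return Curve(np.array(q), np.array(intensity), np.array(sigma), config_id)


def save_dataset(dataset: Dataset, path) -> None:
    """Write the dataset archive (HDF5: intensities, q, labels, configs, params)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("intensities", data=dataset.intensities)
        fh.create_dataset("q", data=dataset.q_grids)
        fh.create_dataset("labels", data=dataset.labels)
        if dataset.sigmas is not None:
            fh.create_dataset("sigmas", data=dataset.sigmas)
        fh.create_dataset(
            "config_ids", data=np.array(dataset.config_ids, dtype=h5py.string_dtype())
        )
        fh.create_dataset(
            "params",
            data=np.array([json.dumps(p) for p in dataset.params], dtype=h5py.string_dtype()),
        )
        fh.attrs["provenance"] = json.dumps(dataset.provenance)
        fh.attrs["shapes"] = json.dumps(list(SHAPES))


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as fh:
        return Dataset(
            fh["intensities"][()],
            fh["q"][()],
            fh["labels"][()],
            [s.decode() for s in fh["config_ids"][()]],
            fh["sigmas"][()] if "sigmas" in fh else None,
            [json.loads(s) for s in fh["params"][()]],
            json.loads(fh.attrs["provenance"]),
        )
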