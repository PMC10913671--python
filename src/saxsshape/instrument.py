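"""Laboratory-instrument simulation: q-grids, beam smearing, counting noise.

Two built-in Xenocs device configurations are provided (Xeuss1800HR,
NanoInXiderHR).  A perfect model intensity becomes a realistic measurement by
Gaussian beam smearing followed by Poisson counting noise at the device's
transmitted flux and counting time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .form_factors import Curve, ParticleModel, ValidationError, polydisperse_intensity

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Counts calibration: the per-bin effective solid-angle factor is fixed per
# configuration so that a flat water-like background of 0.016 cm⁻¹ collects
# ~200 counts per bin over a 20 min exposure.
_WATER_I = 0.016  # cm⁻¹
_WATER_COUNTS = 200.0


@dataclass
class InstrumentConfig:
    """Geometry and statistics of one device configuration.

    q values in Å⁻¹, distances in mm, wavelength in Å, flux in photons/s,
    counting time in s.
    """

    name: str
    sample_detector_distance: float
    wavelength: float
    q_min: float
    q_max: float
    delta_q: float
    beam_fwhm: float
    transmitted_flux: float
    counting_time: float
    n_points: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.q_min < self.q_max:
            raise ValidationError("q_min must be < q_max")
        if self.delta_q <= 0:
            raise ValidationError("delta_q must be > 0")
        if self.transmitted_flux <= 0 or self.counting_time <= 0:
            raise ValidationError("flux and counting time must be > 0")
        implied = (self.q_max - self.q_min) / self.delta_q + 1.0
        if abs(implied - self.n_points) > 1.0:
            raise ValidationError(
                f"grid inconsistent: (q_max-q_min)/delta_q+1 = {implied:.2f} "
                f"but n_points = {self.n_points}"
            )

    @property
    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_points)

    @property
    def solid_angle_factor(self) -> float:
        """Per-bin counts per (cm⁻¹ · photon): counts = I·flux·time·k."""
        return _WATER_COUNTS / (_WATER_I * self.transmitted_flux * self.counting_time)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(**d)


_BUILTINS: dict[str, dict] = {
    "Xeuss1800HR": dict(
        name="Xeuss1800HR",
        sample_detector_distance=1800.0,
        wavelength=1.54,
        q_min=0.85e-4,
        q_max=1511e-4,
        # 890-point grid; the step rounds to the nominal 1.7e-4 Å⁻¹
        delta_q=(1511e-4 - 0.85e-4) / 889,
        beam_fwhm=0.0016,
        transmitted_flux=3.43e6,
        counting_time=1200.0,
        n_points=890,
        metadata={
            "detector": "Dectris Eiger1M",
            "nominal_q_range": [0.0031, 0.1493],
            "source": "Cu",
        },
    ),
    "NanoInXiderHR": dict(
        name="NanoInXiderHR",
        sample_detector_distance=938.0,
        wavelength=1.54,
        q_min=3.74e-4,
        q_max=4527e-4,
        delta_q=(4527e-4 - 3.74e-4) / 603,
        beam_fwhm=0.0024,
        transmitted_flux=7.22e6,
        counting_time=1200.0,
        n_points=604,
        metadata={
            "detector": "Dectris Eiger1M",
            "nominal_q_range": [0.0019, 0.4452],
            "source": "Cu",
        },
    ),
}


def builtin_config(name: str) -> InstrumentConfig:
    """Return one of the built-in device configurations by name."""
    try:
        spec = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown configuration {name!r}; available: {', '.join(sorted(_BUILTINS))}"
        ) from None
    return InstrumentConfig(**json.loads(json.dumps(spec)))


def smear(curve: Curve, beam_fwhm: float) -> Curve:
    """Convolve the intensity with the Gaussian beam profile of given FWHM.

    Requires a uniform q grid; edges use reflect padding so the integrated
    intensity is approximately conserved at the Guinier end.  ``beam_fwhm=0``
    is the identity.
    """
    if beam_fwhm < 0:
        raise ValidationError("beam_fwhm must be >= 0")
    if beam_fwhm == 0:
        return Curve(curve.q.copy(), curve.intensity.copy(), None if curve.sigma is None else curve.sigma.copy(), curve.config_id)
    dq = np.diff(curve.q)
    if not np.allclose(dq, dq[0], rtol=1e-6):
        raise ValidationError("smear requires a uniform q grid")
    sigma_bins = beam_fwhm * _FWHM_TO_SIGMA / dq[0]
    smeared = gaussian_filter1d(curve.intensity, sigma_bins, mode="reflect")
    return Curve(curve.q.copy(), smeared, None if curve.sigma is None else curve.sigma.copy(), curve.config_id)


def add_counting_noise(curve: Curve, config: InstrumentConfig, seed) -> Curve:
    """Apply per-bin Poisson counting statistics of the device.

    Expected counts per bin are λ_j = I_j · flux · time · k with k the
    configuration's solid-angle factor; the returned intensity is
    counts/(flux·time·k) and sigma = sqrt(counts)/(flux·time·k).
    """
    rng = np.random.default_rng(seed)
    denom = config.transmitted_flux * config.counting_time * config.solid_angle_factor
    lam = np.clip(curve.intensity, 0.0, None) * denom
    counts = rng.poisson(lam).astype(float)
    return Curve(curve.q.copy(), counts / denom, np.sqrt(counts) / denom, curve.config_id)


def simulate_measurement(
    model: ParticleModel,
    config: InstrumentConfig,
    seed=None,
    noiseless: bool = False,
) -> Curve:
    """Full measurement chain: model intensity → smear → counting noise.

    With ``noiseless=True`` the smeared curve is returned with sigma = 0.
    Reproducible: the same (model, config, seed) yields an identical curve.
    """
    ideal = Curve(config.q_grid, polydisperse_intensity(model, config.q_grid), config_id=config.name)
    smeared = smear(ideal, config.beam_fwhm)
    if noiseless:
        smeared.sigma = np.zeros_like(smeared.intensity)
        return smeared
    return add_counting_noise(smeared, config, seed)
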