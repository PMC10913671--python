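"""Curve preprocessing operators and their left-to-right composition.

Five operators act on intensity matrices ``X`` of shape (N, J) with per-curve
q grids ``Q`` of the same shape:

* ``TH``   — thresholding at 1e-15 cm⁻¹ (clamps noise-induced negatives);
* ``LOG``  — elementwise natural logarithm (requires TH earlier in the chain);
* ``STD``  — per-bin standardisation; statistics are fitted once on the
  training set and frozen;
* ``IntN`` — division by the Porod-type invariant ∫ I q² dq (trapezoid on the
  native grid), removing contrast/volume-fraction scale;
* ``QLOG`` — resampling onto a log-spaced q grid with preserved endpoints and
  unchanged length.

A chain is written left-to-right: ``["TH", "IntN", "LOG", "STD", "QLOG"]``
applies TH first.  That chain is the registered preset ``"best"``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .form_factors import ValidationError

DEFAULT_THRESHOLD = 1e-15  # cm⁻¹

OPERATOR_TAGS = ("TH", "LOG", "STD", "IntN", "QLOG")

PRESETS: dict[str, list[str]] = {
    "identity": [],
    "best": ["TH", "IntN", "LOG", "STD", "QLOG"],
    "th-log-std": ["TH", "LOG", "STD"],
    "th-log-std-qlog": ["TH", "LOG", "STD", "QLOG"],
}


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def th(x, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Clamp intensities from below: I_j <- max(I_j, threshold).  Idempotent."""
    return np.maximum(np.asarray(x, dtype=float), threshold)


def log_op(x) -> np.ndarray:
    """Elementwise natural log; refuses non-positive input."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("LOG requires positive intensities; apply TH first")
    return np.log(x)


def std_fit(x) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and standard deviation over the curves of a (training) set."""
    x = _as_matrix(x)
    return x.mean(axis=0), x.std(axis=0)


def std_apply(x, stats) -> np.ndarray:
    """(I_j - mean_j)/std_j with frozen statistics; zero-std bins are centred only."""
    mean, std = stats
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != mean.shape[0]:
        raise ValidationError(
            f"STD statistics length {mean.shape[0]} does not match curve length {x.shape[-1]}"
        )
    scale = np.where(std > 0, std, 1.0)
    if np.any(std == 0):
        warnings.warn("constant bins found: centred but not scaled", RuntimeWarning, stacklevel=2)
    return (x - mean) / scale


def intn(x, q) -> np.ndarray:
    """Normalise each curve by its invariant ∫ I q² dq (trapezoid rule)."""
    x = _as_matrix(np.asarray(x, dtype=float))
    q = _as_matrix(np.asarray(q, dtype=float))
    q = np.broadcast_to(q, x.shape)
    integral = np.trapezoid(x * q**2, q, axis=1)
    if np.any(integral <= 0):
        raise ValidationError("IntN: non-positive invariant integral")
    return (x.T / integral).T


def qlog(x, q) -> tuple[np.ndarray, np.ndarray]:
    """Resample onto a log-spaced grid with identical endpoints and length."""
    x = _as_matrix(np.asarray(x, dtype=float))
    q = np.broadcast_to(_as_matrix(np.asarray(q, dtype=float)), x.shape)
    if np.any(q[:, 0] <= 0):
        raise ValidationError("QLOG requires q_0 > 0 (truncate the grid first)")
    j = x.shape[1]
    new_q = np.empty_like(q)
    new_x = np.empty_like(x)
    for i in range(x.shape[0]):
        grid = np.geomspace(q[i, 0], q[i, -1], j)
        grid[0], grid[-1] = q[i, 0], q[i, -1]  # exact endpoints
        new_q[i] = grid
        new_x[i] = np.interp(grid, q[i], x[i])
    return new_x, new_q


class Preprocessor:
    """A frozen left-to-right chain of preprocessing operators.

    ``fit`` learns the STD statistics (if present) by running the chain on the
    training set; ``transform`` replays the chain with frozen state.  The
    chain is validated at construction: LOG needs a TH earlier, and IntN must
    see linear-scale intensities (i.e. precede LOG).
    """

    def __init__(self, spec, threshold: float = DEFAULT_THRESHOLD):
        if isinstance(spec, str):
            try:
                spec = PRESETS[spec]
            except KeyError:
                raise ValidationError(
                    f"unknown preset {spec!r}; available: {', '.join(PRESETS)}"
                ) from None
        self.spec = list(spec)
        self.threshold = threshold
        self._std_stats: tuple[np.ndarray, np.ndarray] | None = None
        for tag in self.spec:
            if tag not in OPERATOR_TAGS:
                raise ValidationError(f"unknown operator tag {tag!r}")
        if "LOG" in self.spec:
            if "TH" not in self.spec or self.spec.index("TH") > self.spec.index("LOG"):
                raise ValidationError("LOG requires TH earlier in the chain")
        if "IntN" in self.spec and "LOG" in self.spec:
            if self.spec.index("IntN") > self.spec.index("LOG"):
                raise ValidationError("IntN must receive linear-scale intensities (place before LOG)")

    @property
    def fitted(self) -> bool:
        return "STD" not in self.spec or self._std_stats is not None

    def _run(self, x, q, fitting: bool):
        x = _as_matrix(np.array(x, dtype=float, copy=True))
        q = np.broadcast_to(_as_matrix(np.asarray(q, dtype=float)), x.shape).copy()
        for tag in self.spec:
            if tag == "TH":
                x = th(x, self.threshold)
            elif tag == "LOG":
                x = log_op(x)
            elif tag == "IntN":
                x = intn(x, q)
            elif tag == "QLOG":
                x, q = qlog(x, q)
            elif tag == "STD":
                if fitting:
                    self._std_stats = std_fit(x)
                if self._std_stats is None:
                    raise ValidationError("STD statistics not fitted; call fit first")
                x = std_apply(x, self._std_stats)
        return x, q

    def fit(self, x, q) -> "Preprocessor":
        self._run(x, q, fitting=True)
        return self

    def fit_transform(self, x, q):
        return self._run(x, q, fitting=True)

    def transform(self, x, q):
        if not self.fitted:
            raise ValidationError("STD statistics not fitted; call fit first")
        return self._run(x, q, fitting=False)

    def state_dict(self) -> dict:
        state = {"spec": self.spec, "threshold": self.threshold}
        if self._std_stats is not None:
            state["std_mean"] = self._std_stats[0].tolist()
            state["std_std"] = self._std_stats[1].tolist()
        return state

    @classmethod
    def from_state(cls, state: dict) -> "Preprocessor":
        obj = cls(state["spec"], state.get("threshold", DEFAULT_THRESHOLD))
        if "std_mean" in state:
            obj._std_stats = (np.array(state["std_mean"]), np.array(state["std_std"]))
        return obj


def compose(spec, threshold: float = DEFAULT_THRESHOLD) -> Preprocessor:
    """Build a preprocessing pipeline from a tag list or preset name."""
    return Preprocessor(spec, threshold=threshold)
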