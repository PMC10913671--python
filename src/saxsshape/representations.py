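"""Latent-space transforms for SAXS curves.

Four families of representation are provided on top of the preprocessed
intensity space (dimension J = 890 by default):

* Guinier/Kratky features ("Franke spaces"): the automated Guinier fit gives
  Rg and I(0); the normalised apparent-volume profile V' is evaluated at 5 or
  200 qRg points in [3, 7] and concatenated with Rg (6 or 201 features).
  Not applicable to cylinder-like shapes whose longest dimension exceeds the
  measurable range.
* PCA keeping 90% of the variance (latent dimension fitted from the data).
* A supervised 1D CNN encoder (latent dimension 256) trained with a softmax
  head on the shape labels; the encoder is detachable and reusable with any
  classifier.
* An optional convolutional auto-encoder (latent dimension 200).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from . import nn
from .form_factors import ValidationError

GUINIER_QRG_MAX = 1.3
FRANKE_QRG_RANGE = (3.0, 7.0)
CNN_LATENT_DIM = 256
CAE_LATENT_DIM = 200
Q_CHANNEL_SCALE = 1511e-4  # q values divided by the common q_max cap


class NoGuinierRegionError(ValueError):
    """No q-window with acceptable Guinier linearity exists on this curve."""


@dataclass
class GuinierFit:
    rg: float          # Å
    i0: float          # cm⁻¹, zero-angle intercept
    window: tuple[int, int]
    r_squared: float


def estimate_rg(q, intensity, min_points: int = 8, min_r2: float = 0.98) -> GuinierFit:
    """Automated Guinier fit: Rg from the low-q slope of ln I vs q².

    Starting from a small set of candidate window origins, the window is
    grown while the self-consistency condition q·Rg <= 1.3 holds; the fit
    with the best linearity (R²) wins.  Raises
    :class:`NoGuinierRegionError` when no window passes, e.g. for very long
    cylinders whose gyration radius exceeds the measurable range.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    pos = intensity > 0
    if q[0] <= 0:
        pos &= q > 0
    q, intensity = q[pos], intensity[pos]
    if q.size < min_points:
        raise NoGuinierRegionError("too few positive intensity points")
    x, y = q**2, np.log(intensity)

    best: GuinierFit | None = None
    for start in (0, 2, 5, 10, 20):
        if start + min_points > q.size:
            break
        end = start + min_points
        fit = None
        while end <= q.size:
            slope, intercept = np.polyfit(x[start:end], y[start:end], 1)
            if slope >= 0:
                break
            rg = float(np.sqrt(-3.0 * slope))
            if q[end - 1] * rg > GUINIER_QRG_MAX:
                break
            resid = y[start:end] - (slope * x[start:end] + intercept)
            tss = float(np.sum((y[start:end] - y[start:end].mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
            fit = GuinierFit(rg, float(np.exp(intercept)), (start, end), r2)
            end += max(1, (end - start) // 4)
        if fit is not None and fit.r_squared >= min_r2:
            if best is None or fit.r_squared > best.r_squared:
                best = fit
    if best is None:
        raise NoGuinierRegionError(
            f"no Guinier window with q·Rg <= {GUINIER_QRG_MAX} and R² >= {min_r2}"
        )
    return best


def franke_features(q, intensity, n_points: int = 5) -> np.ndarray:
    """Kratky-integral feature vector of length ``n_points + 1``.

    V'(x) = 2π² I(0) / [Rg³ ∫₀^{x/Rg} q² I(q) dq] — a dimensionless
    normalised apparent volume — evaluated at ``n_points`` qRg values linearly
    spaced in [3, 7], concatenated with Rg.  I(0) and Rg come from the
    automated Guinier fit; the truncated invariant uses the trapezoid rule
    with the Guinier extrapolation covering the [0, q_min] gap.
    """
    if n_points not in (5, 200):
        raise ValidationError("n_points must be 5 or 200")
    fit = estimate_rg(q, intensity)
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    pos = (intensity > 0) & (q > 0)
    q, intensity = q[pos], intensity[pos]

    # extend the integrand to q=0 with the Guinier model to avoid losing the
    # [0, q_min] contribution for large particles
    q_head = np.linspace(0.0, q[0], 16, endpoint=False)
    i_head = fit.i0 * np.exp(-(q_head**2) * fit.rg**2 / 3.0)
    q_full = np.concatenate([q_head, q])
    i_full = np.concatenate([i_head, intensity])
    integrand = i_full * q_full**2
    cumulative = np.concatenate([[0.0], np.cumsum(np.diff(q_full) * (integrand[1:] + integrand[:-1]) / 2.0)])

    x_values = np.linspace(*FRANKE_QRG_RANGE, n_points)
    q_upper = np.clip(x_values / fit.rg, q_full[0], q_full[-1])
    truncated = np.interp(q_upper, q_full, cumulative)
    if np.any(truncated <= 0):
        raise NoGuinierRegionError("non-positive truncated invariant")
    v_prime = 2.0 * np.pi**2 * fit.i0 / (fit.rg**3 * truncated)
    return np.concatenate([v_prime, [fit.rg]])


class PCA90:
    """PCA keeping a fixed fraction of variance (default 90%)."""

    def __init__(self, variance_kept: float = 0.90):
        self.variance_kept = variance_kept
        self._pca: _SkPCA | None = None

    def fit(self, x: np.ndarray) -> "PCA90":
        self._pca = _SkPCA(n_components=self.variance_kept, svd_solver="full")
        self._pca.fit(x)
        return self

    @property
    def latent_dim(self) -> int:
        if self._pca is None:
            raise ValidationError("PCA not fitted")
        return int(self._pca.n_components_)

    @property
    def explained_variance(self) -> float:
        return float(self._pca.explained_variance_ratio_.sum())

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise ValidationError("PCA not fitted")
        return self._pca.transform(x)


# ---------------------------------------------------------------------------
# supervised CNN encoder
# ---------------------------------------------------------------------------

def _min_input_length() -> int:
    # two conv-k7 pairs and two pool-6 stages must leave >= 1 position
    return ((1 * 6 + 12) * 6) + 12  # 120


class CNNClassifier:
    """1D CNN encoder (latent dim 256) with a 9-way softmax perceptron head.

    Architecture: conv64k7 - conv64k7 - pool6 - dropout0.25 - conv64k7 -
    conv256k7 - pool6 - dropout0.25 - global max pool (256), then one dense
    softmax layer.  Input is (N, J) intensities, or (N, 2, J) with the q grid
    as a second channel in ``input_mode='Iq'``.  Trained with Adam on
    categorical cross-entropy; inference is deterministic (dropout off).
    """

    def __init__(self, input_len: int, input_mode: str = "I", n_classes: int = 9, seed: int = 0):
        if input_len < _min_input_length():
            raise ValidationError(
                f"input length {input_len} too short for two pool-6 stages "
                f"(need >= {_min_input_length()})"
            )
        if input_mode not in ("I", "Iq"):
            raise ValidationError("input_mode must be 'I' or 'Iq'")
        self.input_len = input_len
        self.input_mode = input_mode
        self.n_classes = n_classes
        self.seed = seed
        c_in = 1 if input_mode == "I" else 2
        rng = np.random.default_rng(seed)
        self.encoder = nn.Sequential(
            [
                nn.Conv1D(c_in, 64, 7, rng=rng),
                nn.Conv1D(64, 64, 7, rng=rng),
                nn.MaxPool1D(6),
                nn.Dropout(0.25),
                nn.Conv1D(64, 64, 7, rng=rng),
                nn.Conv1D(64, 256, 7, rng=rng),
                nn.MaxPool1D(6),
                nn.Dropout(0.25),
                nn.GlobalMaxPool(),
            ]
        )
        self.head = nn.Dense(CNN_LATENT_DIM, n_classes, rng=rng)
        self.network = nn.Sequential(self.encoder.layers + [self.head])
        self.loss_history: list[float] = []

    @property
    def latent_dim(self) -> int:
        return CNN_LATENT_DIM

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters

    def _assemble(self, x: np.ndarray, q: np.ndarray | None) -> np.ndarray:
        """(N, J) intensities [+ q grids] -> (N, J, channels) float32."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            if self.input_mode == "I":
                x = x[:, :, None]
            else:
                if q is None:
                    raise ValidationError("input_mode 'Iq' needs the q grids")
                qc = (np.asarray(q, dtype=np.float32) / Q_CHANNEL_SCALE)
                qc = np.broadcast_to(qc if qc.ndim == 2 else qc[None, :], x.shape)
                x = np.stack([x, qc], axis=2)
        if x.shape[1] != self.input_len:
            raise ValidationError(f"expected input length {self.input_len}, got {x.shape[1]}")
        return x

    def fit(self, x, y, q=None, epochs: int = 50, batch_size: int = 128, lr: float = 1e-3,
            validation_fraction: float = 0.0, patience: int = 10):
        """Train with Adam on categorical cross-entropy.

        With ``validation_fraction > 0`` a stratified slice of the training
        set is held out, training stops once its loss has not improved for
        ``patience`` epochs, and the best-validation weights are restored.
        """
        xt = self._assemble(x, q)
        y = np.asarray(y, dtype=int)
        if validation_fraction <= 0.0:
            self.loss_history += nn.train_network(
                self.network, xt, y,
                lambda logits, yy: nn.softmax_cross_entropy(logits, yy),
                epochs=epochs, batch_size=batch_size, lr=lr, seed=self.seed,
            )
            return self

        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(y))
        n_val = max(1, int(len(y) * validation_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_tr, y_tr = xt[tr_idx], y[tr_idx]
        opt = nn.Adam(self.network.parameters(), lr=lr)
        best_loss, best_weights, stale = np.inf, None, 0
        n = len(tr_idx)
        for epoch in range(epochs):
            epoch_order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = epoch_order[start : start + batch_size]
                out = self.network.forward(x_tr[idx], train=True, rng=rng)
                loss, grad = nn.softmax_cross_entropy(out, y_tr[idx])
                if not np.isfinite(loss):
                    raise nn.TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                self.network.backward(grad)
                opt.step(self.network.gradients())
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
            logits = self.network.forward(xt[val_idx])
            val_loss, _ = nn.softmax_cross_entropy(logits, y[val_idx])
            if val_loss < best_loss - 1e-4:
                best_loss, best_weights, stale = val_loss, self.get_weights(), 0
            else:
                stale += 1
                if stale >= patience:
                    break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self

    def encode(self, x, q=None, batch_size: int = 256) -> np.ndarray:
        """Latent 256-vector per curve (deterministic, dropout disabled)."""
        xt = self._assemble(x, q)
        out = [self.encoder.forward(xt[s : s + batch_size]) for s in range(0, xt.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def predict_proba(self, x, q=None, batch_size: int = 256) -> np.ndarray:
        xt = self._assemble(x, q)
        out = [
            nn.softmax(self.network.forward(xt[s : s + batch_size]))
            for s in range(0, xt.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x, q=None) -> np.ndarray:
        return self.predict_proba(x, q).argmax(axis=1)

    # --- persistence -----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.network.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.network.parameters(), weights):
            p[...] = w


def cnn_build(input_len: int, input_mode: str = "I", n_classes: int = 9, seed: int = 0) -> CNNClassifier:
    """Untrained encoder + softmax head with the fixed published architecture."""
    return CNNClassifier(input_len, input_mode, n_classes, seed)


def cnn_parameter_count(input_len: int, input_mode: str = "I", n_classes: int = 9) -> int:
    """Closed-form parameter count of the architecture (independent of data)."""
    c_in = 1 if input_mode == "I" else 2
    conv = lambda ci, co, k: ci * k * co + co
    return (
        conv(c_in, 64, 7)
        + conv(64, 64, 7)
        + conv(64, 64, 7)
        + conv(64, 256, 7)
        + (256 * n_classes + n_classes)
    )


# ---------------------------------------------------------------------------
# convolutional auto-encoder (optional, experimental)
# ---------------------------------------------------------------------------

class ConvAutoencoder:
    """Unsupervised conv encoder/decoder; encoder output is the latent space.

    The decoder mirrors the encoder with nearest-neighbour upsampling.  The
    input is cropped to a multiple of 36 so the two pool-6 stages invert
    exactly.  Trained with Adam on MSE.
    """

    def __init__(self, input_len: int, latent_dim: int = CAE_LATENT_DIM, seed: int = 0):
        self.crop = (input_len // 36) * 36
        if self.crop < 36:
            raise ValidationError("input too short for the auto-encoder")
        self.latent_dim = latent_dim
        self.seed = seed
        l2 = self.crop // 36
        rng = np.random.default_rng(seed)
        self.encoder = nn.Sequential(
            [
                nn.Conv1D(1, 32, 7, padding="same", rng=rng),
                nn.MaxPool1D(6),
                nn.Conv1D(32, 32, 7, padding="same", rng=rng),
                nn.MaxPool1D(6),
                nn.Flatten(),
                nn.Dense(32 * l2, latent_dim, rng=rng),
            ]
        )
        self.decoder = nn.Sequential(
            [
                nn.Dense(latent_dim, 32 * l2, relu=True, rng=rng),
                nn.Reshape(l2, 32),
                nn.Upsample1D(6),
                nn.Conv1D(32, 32, 7, padding="same", rng=rng),
                nn.Upsample1D(6),
                nn.Conv1D(32, 1, 7, relu=False, padding="same", rng=rng),
            ]
        )
        self.network = nn.Sequential(self.encoder.layers + self.decoder.layers)
        self.loss_history: list[float] = []

    def _crop(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        return x[:, : self.crop, None]

    def fit(self, x, epochs: int = 30, batch_size: int = 64, lr: float = 1e-3):
        xt = self._crop(x)
        self.loss_history += nn.train_network(
            self.network, xt, xt, nn.mse_loss,
            epochs=epochs, batch_size=batch_size, lr=lr, seed=self.seed,
        )
        return self

    def transform(self, x) -> np.ndarray:
        return self.encoder.forward(self._crop(x))

    def reconstruct(self, x) -> np.ndarray:
        return self.network.forward(self._crop(x))[:, :, 0]

    def reconstruction_mse(self, x) -> float:
        xt = self._crop(x)[:, :, 0]
        return float(np.mean((self.reconstruct(x) - xt) ** 2))


def cae_build_train(x, latent_dim: int = CAE_LATENT_DIM, seed: int = 0,
                    epochs: int = 30, batch_size: int = 64, lr: float = 1e-3) -> ConvAutoencoder:
    cae = ConvAutoencoder(np.asarray(x).shape[1], latent_dim, seed)
    cae.fit(x, epochs=epochs, batch_size=batch_size, lr=lr)
    return cae
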