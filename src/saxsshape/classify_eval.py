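"""Classifiers, cross-validation benchmark, transfer matrix and scoring.

A *method* is the triple (preprocessing chain, representation, classifier).
Benchmarking follows a repeated stratified protocol: every repeat re-draws
the fold split and re-seeds all learners; preprocessing statistics and
representations (STD, PCA, CAE, CNN) are fitted strictly inside the training
folds.  Methods are compared with a two-sided Wilcoxon rank-sum test on their
per-repeat accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ranksums
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

from .dataset import Dataset
from .form_factors import SHAPES, ValidationError
from .preprocessing import Preprocessor
from .representations import (
    CNNClassifier,
    ConvAutoencoder,
    PCA90,
    franke_features,
)

CLASSIFIERS = ("KNN", "RF", "XGB", "PL")
REPRESENTATIONS = ("identity", "franke5", "franke200", "pca90", "cae", "cnn")

#: shapes excluded from Franke-space experiments (no meaningful Rg)
CYLINDER_LIKE = ("cylinder", "core_shell_cylinder")

# default hyper-parameters; exposed through MethodSpec.hyperparameters
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "KNN": {"n_neighbors": 5},
    "RF": {"n_estimators": 500},
    "XGB": {"n_estimators": 500, "max_depth": 6, "learning_rate": 0.1},
    "PL": {},
}

# training-budget knobs for the neural representations
DEFAULT_TRAIN_OPTS = {
    "cnn_epochs": 50,
    "cae_epochs": 30,
    "batch_size": 128,
    "lr": 1e-3,
    "cnn_val_fraction": 0.0,   # > 0 enables early stopping on validation loss
    "cnn_patience": 10,
}


@dataclass
class MethodSpec:
    """One benchmarked method: preprocessing ° representation ° classifier."""

    preprocess: list[str] | str = "best"
    representation: str = "identity"
    classifier: str = "RF"
    hyperparameters: dict = field(default_factory=dict)
    input_mode: str = "I"

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValidationError(f"unknown representation {self.representation!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        if self.classifier == "PL" and self.representation != "cnn":
            raise ValidationError("the perceptron layer (PL) is only valid with the CNN representation")

    def name(self) -> str:
        return f"{self.representation}+{self.classifier}"


def make_classifier(name: str, hyperparameters: dict, seed: int):
    hp = {**DEFAULT_HYPERPARAMETERS[name], **hyperparameters}
    if name == "KNN":
        return KNeighborsClassifier(metric="euclidean", **hp)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if name == "XGB":
        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0, **hp
        )
    raise ValidationError(f"unknown classifier {name!r}")


class FittedMethod:
    """A trained (preprocessing, representation, classifier) triple."""

    def __init__(self, spec: MethodSpec, preproc: Preprocessor, rep, clf, classes: np.ndarray):
        self.spec = spec
        self.preproc = preproc
        self.rep = rep
        self.clf = clf
        self.classes = classes

    def _latent(self, x, q):
        xp, qp = self.preproc.transform(x, q)
        kind = self.spec.representation
        if kind == "identity":
            return xp
        if kind == "cnn":
            return self.rep.encode(xp, qp)
        if kind == "pca90":
            return self.rep.transform(xp)
        if kind == "cae":
            return self.rep.transform(xp)
        if kind in ("franke5", "franke200"):
            n = 5 if kind == "franke5" else 200
            return np.array([franke_features(qi, xi, n) for qi, xi in zip(qp, xp)])
        raise ValidationError(kind)

    def predict(self, x, q) -> np.ndarray:
        if self.spec.classifier == "PL":
            xp, qp = self.preproc.transform(x, q)
            return self.classes[self.rep.predict(xp, qp)]
        latent = self._latent(x, q)
        if not np.all(np.isfinite(latent)):
            raise ValidationError(
                f"non-finite features from representation {self.spec.representation!r}"
            )
        return self.clf.predict(latent)

    def predict_proba(self, x, q) -> np.ndarray:
        """Probabilities over the 9 shape classes (columns ordered by label id)."""
        n_classes = len(SHAPES)
        if self.spec.classifier == "PL":
            xp, qp = self.preproc.transform(x, q)
            raw = self.rep.predict_proba(xp, qp)
            cols = self.classes
        else:
            latent = self._latent(x, q)
            if self.spec.classifier == "KNN" or hasattr(self.clf, "predict_proba"):
                raw = self.clf.predict_proba(latent)
            else:
                pred = self.clf.predict(latent)
                raw = np.eye(len(self.classes))[np.searchsorted(self.classes, pred)]
            cols = self.clf.classes_
        out = np.zeros((raw.shape[0], n_classes))
        out[:, np.asarray(cols, dtype=int)] = raw
        return out


def train_method(
    spec: MethodSpec,
    x_train: np.ndarray,
    q_train: np.ndarray,
    y_train: np.ndarray,
    seed: int,
    train_opts: dict | None = None,
) -> FittedMethod:
    """Fit preprocessing, representation and classifier on a training set."""
    opts = {**DEFAULT_TRAIN_OPTS, **(train_opts or {})}
    if not np.all(np.isfinite(x_train)):
        raise ValidationError("non-finite intensities in training data")
    preproc = Preprocessor(spec.preprocess)
    xp, qp = preproc.fit_transform(x_train, q_train)

    classes = np.unique(y_train)
    rep = None
    latent = xp
    if spec.representation == "cnn":
        y_idx = np.searchsorted(classes, y_train)
        rep = CNNClassifier(xp.shape[1], spec.input_mode, n_classes=len(classes), seed=seed)
        rep.fit(xp, y_idx, q=qp, epochs=opts["cnn_epochs"], batch_size=opts["batch_size"],
                lr=opts["lr"], validation_fraction=opts["cnn_val_fraction"],
                patience=opts["cnn_patience"])
        latent = rep.encode(xp, qp)
    elif spec.representation == "pca90":
        rep = PCA90().fit(xp)
        latent = rep.transform(xp)
    elif spec.representation == "cae":
        rep = ConvAutoencoder(xp.shape[1], seed=seed)
        rep.fit(xp, epochs=opts["cae_epochs"], batch_size=opts["batch_size"], lr=opts["lr"])
        latent = rep.transform(xp)
    elif spec.representation in ("franke5", "franke200"):
        n = 5 if spec.representation == "franke5" else 200
        latent = np.array([franke_features(qi, xi, n) for qi, xi in zip(qp, xp)])

    clf = None
    if spec.classifier != "PL":
        if not np.all(np.isfinite(latent)):
            raise ValidationError(
                f"non-finite features from representation {spec.representation!r}"
            )
        clf = make_classifier(spec.classifier, spec.hyperparameters, seed)
        clf.fit(latent, y_train)
    return FittedMethod(spec, preproc, rep, clf, classes)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Benchmark result: per-repeat accuracies plus pooled confusion."""

    method: str
    accuracies: np.ndarray             # one value per repeat
    confusion: np.ndarray              # row-normalised, classes x classes
    per_class_recall: dict[str, float]
    n_repeats: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    def summary(self) -> str:
        return (
            f"{self.method}: {100 * self.mean_accuracy:.1f}% "
            f"± {300 * self.std_accuracy:.1f} (3σ, {self.n_repeats} repeats)"
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accuracies": self.accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion": self.confusion.tolist(),
            "per_class_recall": self.per_class_recall,
            "n_repeats": self.n_repeats,
        }


def confusion_report(y_true, y_pred, class_names=None) -> tuple[np.ndarray, dict[str, float]]:
    """Row-normalised confusion matrix (rows sum to 1) and per-class recall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(y_true)
    mat = _sk_confusion(y_true, y_pred, labels=labels).astype(float)
    rows = mat.sum(axis=1, keepdims=True)
    mat = np.divide(mat, rows, out=np.zeros_like(mat), where=rows > 0)
    if class_names is None:
        class_names = [SHAPES[i] if 0 <= i < len(SHAPES) else str(i) for i in labels]
    recall = {name: float(mat[i, i]) for i, name in enumerate(class_names)}
    return mat, recall


def cross_validate(
    spec: MethodSpec,
    dataset: Dataset,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    train_opts: dict | None = None,
    folds_per_repeat: int | None = None,
) -> EvalReport:
    """Repeated stratified k-fold benchmark of one method.

    Each repeat re-draws the fold split with derived seed ``seed + r`` and
    reports the mean test accuracy over its folds.  ``folds_per_repeat``
    optionally evaluates only the first m folds of each repeat (a compute
    budget knob for the neural representations; the split is still k-fold
    stratified).
    """
    if spec.representation in ("franke5", "franke200"):
        dataset = dataset.exclude_shapes(CYLINDER_LIKE)
    y = dataset.labels
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        raise ValidationError(f"every class needs at least k={k} members")
    accuracies = []
    all_true, all_pred = [], []
    for r in range(repeats):
        rep_seed = (seed + r) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        fold_accs = []
        for f, (tr, te) in enumerate(skf.split(dataset.intensities, y)):
            if folds_per_repeat is not None and f >= folds_per_repeat:
                break
            fitted = train_method(
                spec, dataset.intensities[tr], dataset.q_grids[tr], y[tr],
                seed=rep_seed, train_opts=train_opts,
            )
            pred = fitted.predict(dataset.intensities[te], dataset.q_grids[te])
            fold_accs.append(float(np.mean(pred == y[te])))
            all_true.append(y[te])
            all_pred.append(pred)
        accuracies.append(float(np.mean(fold_accs)))
    mat, recall = confusion_report(np.concatenate(all_true), np.concatenate(all_pred))
    return EvalReport(spec.name(), np.array(accuracies), mat, recall, repeats)


def compare_wilcoxon(accuracies_a, accuracies_b, alpha: float = 0.01) -> str:
    """Two-sided Wilcoxon rank-sum verdict: 'better', 'worse' or 'indistinguishable'."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("repeat vectors must have equal length")
    if np.all(a == b) or (a.std() == 0 and b.std() == 0 and a[0] == b[0]):
        return "indistinguishable"
    stat, p = ranksums(a, b)
    if not np.isfinite(p) or p >= alpha:
        return "indistinguishable"
    return "better" if a.mean() > b.mean() else "worse"


def transfer_matrix(
    spec: MethodSpec,
    train_sets: dict[str, Dataset],
    test_sets: dict[str, Dataset],
    repeats: int = 5,
    seed: int = 0,
    train_opts: dict | None = None,
) -> dict[str, dict[str, float]]:
    """Train on each dataset build, test on held-out data from each configuration.

    Returns ``{train_name: {test_name: mean accuracy}}`` — the rows/columns of
    the cross-configuration transfer table.  All datasets must share the same
    input length.
    """
    lengths = {ds.input_length for ds in list(train_sets.values()) + list(test_sets.values())}
    if len(lengths) != 1:
        raise ValidationError(
            f"input length mismatch across datasets ({sorted(lengths)}); resample_to_grid first"
        )
    table: dict[str, dict[str, float]] = {}
    for train_name, train_ds in train_sets.items():
        accs: dict[str, list[float]] = {t: [] for t in test_sets}
        for r in range(repeats):
            fitted = train_method(
                spec, train_ds.intensities, train_ds.q_grids, train_ds.labels,
                seed=(seed + r) % (2**31 - 1), train_opts=train_opts,
            )
            for test_name, test_ds in test_sets.items():
                pred = fitted.predict(test_ds.intensities, test_ds.q_grids)
                accs[test_name].append(float(np.mean(pred == test_ds.labels)))
        table[train_name] = {t: float(np.mean(v)) for t, v in accs.items()}
    return table


# ---------------------------------------------------------------------------
# real-data scoring
# ---------------------------------------------------------------------------

# Symmetric map of "informative" confusions: geometrically adjacent form
# factors whose confusion still tells the user something useful.  Pairs
# involving the sphere/prolate/oblate triangle and the shelled family follow
# the published protocol; the remaining classes are extended by the same
# similarity logic (homogeneous near-shapes together, shelled near-shapes
# together; the cylinder's nearest homogeneous neighbour is the prolate).
INFORMATIVE_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("sphere", "prolate_ellipsoid"),
        ("sphere", "oblate_ellipsoid"),
        ("prolate_ellipsoid", "oblate_ellipsoid"),
        ("core_shell_sphere", "core_shell_prolate"),
        ("core_shell_sphere", "core_shell_oblate"),
        ("core_shell_sphere", "hollow_sphere"),
        ("core_shell_prolate", "core_shell_oblate"),
        ("hollow_sphere", "core_shell_prolate"),
        ("hollow_sphere", "core_shell_oblate"),
        ("cylinder", "prolate_ellipsoid"),
        ("core_shell_cylinder", "core_shell_prolate"),
    ]
)


@dataclass
class RealScore:
    """Per-sample contributions in {-1, 0, +1} and their total."""

    contributions: list[int]
    total: int
    per_sample_frequencies: list[dict[str, float]] | None = None

    def to_dict(self) -> dict:
        return {
            "contributions": self.contributions,
            "total": self.total,
            "per_sample_frequencies": self.per_sample_frequencies,
        }


def score_one(predicted: str, truth: str) -> int:
    """+1 exact, 0 informative (similar form factor), -1 otherwise."""
    for label in (predicted, truth):
        if label not in SHAPES:
            raise ValidationError(f"unknown shape label {label!r}")
    if predicted == truth:
        return 1
    if frozenset((predicted, truth)) in INFORMATIVE_PAIRS:
        return 0
    return -1


def real_data_score(predictions, true_labels, frequencies=None) -> RealScore:
    """Total score over a labelled sample set (+n all correct, -n all wrong)."""
    predictions = list(predictions)
    true_labels = list(true_labels)
    if len(predictions) != len(true_labels):
        raise ValidationError("predictions and labels differ in length")
    contributions = [score_one(p, t) for p, t in zip(predictions, true_labels)]
    return RealScore(contributions, int(sum(contributions)), frequencies)


def score_sessions(session_predictions: list[list[str]], true_labels) -> dict:
    """Score each training session and report per-sample prediction frequencies.

    ``session_predictions[s][i]`` is session s's predicted shape for sample i.
    """
    true_labels = list(true_labels)
    totals = [real_data_score(preds, true_labels).total for preds in session_predictions]
    n_samples = len(true_labels)
    freqs: list[dict[str, float]] = []
    for i in range(n_samples):
        votes = [preds[i] for preds in session_predictions]
        freqs.append({s: votes.count(s) / len(votes) for s in set(votes)})
    return {
        "score_mean": float(np.mean(totals)),
        "score_std": float(np.std(totals)),
        "session_scores": totals,
        "per_sample_frequencies": freqs,
    }
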