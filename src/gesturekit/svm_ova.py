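"""Soft-margin kernel SVM in a one-against-all multiclass wrapper.

Three kernel families are supported:

* quadratic:   K(u, v) = (gamma * <u, v> + coef0)^2
* polynomial:  K(u, v) = (gamma * <u, v> + coef0)^degree
* rbf:         K(u, v) = exp(-gamma * ||u - v||^2)

The quadratic kernel is the polynomial family fixed at degree 2.  One binary
soft-margin machine is trained per class (that class against all others); a
test point receives the label of the machine with the largest real-valued
decision score, ties broken by class order.  The binary quadratic programs are
solved with scikit-learn's libsvm backend; the fitted machines are then
reduced to plain support-vector / dual-coefficient / intercept data so that
prediction runs through this module's own kernel code and models serialise to
JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .exceptions import TrainingError, ValidationError
from .features import FeatureVector, Normalizer, stack_features

KERNEL_FAMILIES: tuple[str, ...] = ("quadratic", "polynomial", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family with its parameters and the soft-margin constant.

    This is the object the Cuckoo Search optimizer tunes: the family choice,
    gamma (inner-product scale / RBF width), coef0 and degree (polynomial
    families), and C (box constraint).
    """

    family: str = "rbf"
    degree: int = 2
    gamma: float = 1.0
    coef0: float = 0.0
    c_soft_margin: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if self.family == "quadratic" and self.degree != 2:
            object.__setattr__(self, "degree", 2)
        if self.family == "polynomial" and (int(self.degree) != self.degree or self.degree < 2):
            raise ValidationError(f"polynomial degree must be an integer >= 2; got {self.degree}")
        for name in ("gamma", "c_soft_margin"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite; got {v}")
        if not np.isfinite(self.coef0):
            raise ValidationError(f"coef0 must be finite; got {self.coef0}")

    @property
    def effective_degree(self) -> int:
        return 2 if self.family == "quadratic" else int(self.degree)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "degree": self.effective_degree,
            "gamma": self.gamma,
            "coef0": self.coef0,
            "c_soft_margin": self.c_soft_margin,
        }


def kernel_matrix(spec: KernelSpec, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = k(U[i], V[j]) for the given KernelSpec."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[1] != V.shape[1]:
        raise ValidationError(f"dimension mismatch: {U.shape[1]} vs {V.shape[1]}")
    if spec.family == "rbf":
        sq = (
            np.sum(U * U, axis=1)[:, None]
            + np.sum(V * V, axis=1)[None, :]
            - 2.0 * U @ V.T
        )
        return np.exp(-spec.gamma * np.maximum(sq, 0.0))
    base = spec.gamma * (U @ V.T) + spec.coef0
    return base ** spec.effective_degree


def kernel_eval(spec: KernelSpec, u, v) -> float:
    """Scalar kernel evaluation k(u, v)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValidationError(f"dimension mismatch: {u.size} vs {v.size}")
    return float(kernel_matrix(spec, u[None, :], v[None, :])[0, 0])


@dataclass
class BinaryMachine:
    """One fitted class-vs-rest decision function in plain-data form.

    decision(x) = sum_i dual_coef[i] * k(sv[i], x) + intercept, positive
    meaning "this class".
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float

    def decision(self, X: np.ndarray, spec: KernelSpec) -> np.ndarray:
        K = kernel_matrix(spec, np.atleast_2d(X), self.support_vectors)
        return K @ self.dual_coef + self.intercept

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]


@dataclass
class TrainedOvaModel:
    """A one-against-all multiclass model: K binary machines plus bookkeeping."""

    class_labels: tuple[str, ...]
    binary_machines: list[BinaryMachine]
    kernel: KernelSpec
    normalizer: Normalizer | None = None

    @property
    def sv_count_per_class(self) -> list[int]:
        return [m.n_support for m in self.binary_machines]

    @property
    def n_features(self) -> int:
        return self.binary_machines[0].support_vectors.shape[1]


def _coerce_xy(
    X: Sequence[FeatureVector] | np.ndarray, y: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    if y is None:
        return stack_features(list(X))  # type: ignore[arg-type]
    return np.atleast_2d(np.asarray(X, dtype=float)), np.asarray(y)


def train_ova(
    X: Sequence[FeatureVector] | np.ndarray,
    spec: KernelSpec,
    y: Sequence[str] | None = None,
    normalizer: Normalizer | None = None,
    class_weighted: bool = False,
) -> TrainedOvaModel:
    """Train one soft-margin binary SVM per class (class vs all others).

    ``X`` may be a list of :class:`FeatureVector` (labels carried inside) or a
    numeric matrix with ``y`` given separately.  Class order follows first
    appearance in the training data, which makes training deterministic for a
    fixed input order.  ``class_weighted=True`` applies inverse-prevalence
    weights to offset the 1:(K-1) imbalance of the relabelled subproblems
    (off by default).
    """
    Xm, ya = _coerce_xy(X, y)
    if not np.all(np.isfinite(Xm)):
        raise ValidationError("training features must be finite")
    labels = tuple(dict.fromkeys(ya.tolist()))  # first-appearance order
    if len(labels) < 2:
        raise ValidationError(f"need >= 2 classes to train; got {labels}")
    if normalizer is not None:
        Xm = normalizer.apply(Xm)

    machines: list[BinaryMachine] = []
    for label in labels:
        y_bin = (ya == label).astype(int)
        clf = SVC(
            C=spec.c_soft_margin,
            kernel="rbf" if spec.family == "rbf" else "poly",
            degree=spec.effective_degree,
            gamma=spec.gamma,
            coef0=spec.coef0,
            class_weight="balanced" if class_weighted else None,
            cache_size=200,
            # bound the solver on degenerate kernels (e.g. a near-constant
            # Gram matrix with a large box constraint iterates indefinitely);
            # well-posed problems at this scale converge orders of magnitude
            # sooner, so the cap never binds for them
            max_iter=1_000_000,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(Xm, y_bin)
        except Exception as exc:  # pragma: no cover - libsvm rarely raises
            raise TrainingError(f"binary SVM for class {label!r} failed: {exc}") from exc
        # libsvm's decision is oriented toward classes_[1]; flip if 1 came second
        sign = 1.0 if clf.classes_[1] == 1 else -1.0
        machines.append(
            BinaryMachine(
                support_vectors=clf.support_vectors_.copy(),
                dual_coef=sign * clf.dual_coef_.ravel().copy(),
                intercept=sign * float(clf.intercept_[0]),
            )
        )
    return TrainedOvaModel(
        class_labels=labels, binary_machines=machines, kernel=spec, normalizer=normalizer
    )


def decision_matrix(model: TrainedOvaModel, X: np.ndarray) -> np.ndarray:
    """Per-class decision scores, shape (n_samples, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"model expects {model.n_features} features; got {X.shape[1]}"
        )
    if model.normalizer is not None:
        X = model.normalizer.apply(X)
    return np.column_stack([m.decision(X, model.kernel) for m in model.binary_machines])


def predict(model: TrainedOvaModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels: argmax of binary decision scores, first class wins ties."""
    scores = decision_matrix(model, X)
    idx = np.argmax(scores, axis=1)
    return np.array(model.class_labels)[idx]


def multiclass_rate(model: TrainedOvaModel, X: np.ndarray, y: Sequence[str]) -> float:
    """Multiclass accuracy on a labelled test set, in percent."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValidationError("empty test set")
    return 100.0 * float(np.mean(predict(model, X) == y))


def per_class_binary_rate(
    model: TrainedOvaModel, X: np.ndarray, y: Sequence[str]
) -> np.ndarray:
    """Per-class one-vs-rest accuracy of each binary machine, in percent.

    For class k: the fraction of test samples for which sign(decision_k) >= 0
    agrees with (label == k).
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValidationError("empty test set")
    scores = decision_matrix(model, X)
    rates = np.empty(len(model.class_labels))
    for k, label in enumerate(model.class_labels):
        pred_k = scores[:, k] >= 0
        rates[k] = 100.0 * np.mean(pred_k == (y == label))
    return rates


def per_class_recall(model: TrainedOvaModel, X: np.ndarray, y: Sequence[str]) -> np.ndarray:
    """Per-class recall of the multiclass prediction, in percent.

    The alternative reading of a per-gesture rate; NaN-free only when every
    class is present in the test set.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValidationError("empty test set")
    preds = predict(model, X)
    out = np.empty(len(model.class_labels))
    for k, label in enumerate(model.class_labels):
        mask = y == label
        out[k] = 100.0 * np.mean(preds[mask] == label) if mask.any() else np.nan
    return out


def total_sv_count(model: TrainedOvaModel) -> int:
    """Total support vectors summed over the binary machines."""
    return int(sum(model.sv_count_per_class))


def mean_sv_per_class(model: TrainedOvaModel) -> float:
    """Average support-vector count per class."""
    return total_sv_count(model) / len(model.class_labels)


def save_model(model: TrainedOvaModel, path: str | Path) -> None:
    """Serialise a trained model to JSON (kernel spec, labels, machines)."""
    payload = {
        "kernel": model.kernel.to_dict(),
        "class_labels": list(model.class_labels),
        "machines": [
            {
                "support_vectors": m.support_vectors.tolist(),
                "dual_coef": m.dual_coef.tolist(),
                "intercept": m.intercept,
            }
            for m in model.binary_machines
        ],
        "normalizer": None
        if model.normalizer is None
        else {"mean": model.normalizer.mean.tolist(), "sd": model.normalizer.sd.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> TrainedOvaModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    k = payload["kernel"]
    spec = KernelSpec(
        family=k["family"],
        degree=int(k["degree"]),
        gamma=k["gamma"],
        coef0=k["coef0"],
        c_soft_margin=k["c_soft_margin"],
    )
    machines = [
        BinaryMachine(
            support_vectors=np.asarray(m["support_vectors"], dtype=float),
            dual_coef=np.asarray(m["dual_coef"], dtype=float),
            intercept=float(m["intercept"]),
        )
        for m in payload["machines"]
    ]
    norm = payload.get("normalizer")
    normalizer = (
        None
        if norm is None
        else Normalizer(mean=np.asarray(norm["mean"]), sd=np.asarray(norm["sd"]))
    )
    return TrainedOvaModel(
        class_labels=tuple(payload["class_labels"]),
        binary_machines=machines,
        kernel=spec,
        normalizer=normalizer,
    )
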