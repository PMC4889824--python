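"""Benchmark procedure: splits, cross-validated fitness, kernel baselines, and
the Cuckoo-Search-optimised run.

The procedure mirrors a standard model-selection protocol for myoelectric
classifiers: the segment dataset is split at random into main training and
testing halves (stratified by gesture); candidate kernels are scored by
10-fold cross-validated multiclass rate on the training side, with the total
support-vector count breaking exact ties; the winning kernel is refit on the
whole training side and generalisation is measured on the held-out test side.
Baselines run each kernel family at declared default parameters on the same
splits.

Reported per cell (feature set x kernel): per-gesture one-vs-rest binary
rates on the test set (mean over repeats), their arithmetic mean, the SD of
the mean rate across repeats, the multiclass accuracy, and the mean
support-vector count per class.  Per-class recall of the multiclass
prediction is available as an alternative per-gesture rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cuckoo import CsConfig, SearchSpace, cs_optimize, default_svm_search_space
from .exceptions import ValidationError
from .features import FEATURE_NAMES, FeatureConfig, resolve_config
from .semg_data import GESTURE_LABELS, Segment
from .svm_ova import (
    KernelSpec,
    mean_sv_per_class,
    multiclass_rate,
    per_class_binary_rate,
    per_class_recall,
    total_sv_count,
    train_ova,
)

DEFAULT_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("MAV",),
    ("WL",),
    ("MAV", "WL", "WAMP"),
    ("MAV", "WL", "SSC"),
)

_KERNEL_INDEX = ("quadratic", "polynomial", "rbf")


@dataclass(frozen=True)
class ExperimentConfig:
    """Benchmark layout and sampling parameters."""

    feature_sets: tuple[tuple[str, ...], ...] = DEFAULT_FEATURE_SETS
    kernels_baseline: tuple[str, ...] = _KERNEL_INDEX
    test_fraction: float = 0.5
    n_repeats: int = 10
    cv_folds: int = 10
    rate_mode: str = "ova_binary"  # or "multiclass_recall"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.rate_mode not in ("ova_binary", "multiclass_recall"):
            raise ValidationError(f"unknown rate_mode {self.rate_mode!r}")
        names = [" + ".join(fs) for fs in self.feature_sets]
        if len(set(names)) != len(names):
            raise ValidationError("feature-set names must be unique")


def spec_from_params(params: dict) -> KernelSpec:
    """Decode a search-space parameter dict into a KernelSpec."""
    family = _KERNEL_INDEX[int(params["kernel"])]
    return KernelSpec(
        family=family,
        degree=int(params.get("degree", 2)) if family != "quadratic" else 2,
        gamma=float(params["gamma"]),
        coef0=float(params.get("coef0", 0.0)) if family != "rbf" else 0.0,
        c_soft_margin=float(params["c_soft_margin"]),
    )


def default_baseline_spec(family: str, X: np.ndarray) -> KernelSpec:
    """Declared default parameters for an unoptimised kernel baseline.

    gamma follows the common 1 / (d * var(X)) scaling; polynomial baselines
    use degree 3 with coef0 = 1 (the quadratic family is degree 2 by
    definition); C = 1.
    """
    var = float(X.var())
    gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return KernelSpec(
        family=family,
        degree=3 if family == "polynomial" else 2,
        gamma=gamma,
        coef0=1.0 if family != "rbf" else 0.0,
        c_soft_margin=1.0,
    )


def split_train_test(
    labels: Sequence[str], test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train_idx, test_idx).

    Class proportions are preserved to within one sample per class.  Classes
    too small to appear on both sides raise a ValidationError naming them.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test_fraction must be in (0, 1)")
    y = np.asarray(labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in dict.fromkeys(y.tolist()):
        idx = np.flatnonzero(y == label)
        if idx.size < 2:
            raise ValidationError(f"class {label!r} has {idx.size} sample(s); need >= 2 to split")
        idx = rng.permutation(idx)
        n_test = int(round(idx.size * test_fraction))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def cv_rate(
    X: np.ndarray,
    y: Sequence[str],
    spec: KernelSpec,
    folds: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Stratified k-fold cross-validated multiclass rate (%) plus the total
    support-vector count of a final fit on all the data.

    Fold assignment is drawn from ``rng``, so repeated calls re-sample folds
    (the fitness is mildly stochastic by design).  If some class has fewer
    members than ``folds``, the fold count degrades to that class size.
    """
    y = np.asarray(y)
    if folds > y.size:
        raise ValidationError(f"folds={folds} exceeds n={y.size}")
    _, counts = np.unique(y, return_counts=True)
    folds_eff = int(min(folds, counts.min()))
    if folds_eff < 2:
        raise ValidationError("smallest class has < 2 members; cannot cross-validate")
    seed = int(rng.integers(2**31)) if rng is not None else 0
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    fold_rates = []
    for tr, te in skf.split(X, y):
        model = train_ova(X[tr], spec, y=y[tr])
        fold_rates.append(multiclass_rate(model, X[te], y[te]))
    final = train_ova(X, spec, y=y)
    return float(np.mean(fold_rates)), total_sv_count(final)


@dataclass
class ReportCell:
    """One benchmark table cell: a feature set under one kernel (or CS)."""

    feature_set: tuple[str, ...]
    kernel: str
    per_gesture: dict[str, float]
    mean_rate: float
    sd_mean_rate: float
    multiclass_rate: float
    mean_sv_per_class: float
    kernel_specs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature_set": " + ".join(self.feature_set),
            "kernel": self.kernel,
            "per_gesture": self.per_gesture,
            "mean_rate": self.mean_rate,
            "sd_mean_rate": self.sd_mean_rate,
            "multiclass_rate": self.multiclass_rate,
            "mean_sv_per_class": self.mean_sv_per_class,
            "kernel_specs": self.kernel_specs,
        }


@dataclass
class ExperimentReport:
    """Collected benchmark cells with table writers."""

    gesture_order: tuple[str, ...]
    cells: list[ReportCell]

    def cell(self, feature_set: tuple[str, ...], kernel: str) -> ReportCell:
        for c in self.cells:
            if c.feature_set == tuple(feature_set) and c.kernel == kernel:
                return c
        raise KeyError((feature_set, kernel))

    def to_dict(self) -> dict:
        return {
            "gesture_order": list(self.gesture_order),
            "cells": [c.to_dict() for c in self.cells],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        """One Markdown table per kernel, rows = feature sets, columns =
        per-gesture rates plus their mean."""
        lines: list[str] = []
        kernels = list(dict.fromkeys(c.kernel for c in self.cells))
        header = "| Features used | " + " | ".join(self.gesture_order) + " | Mean |"
        rule = "|" + "---|" * (len(self.gesture_order) + 2)
        for kernel in kernels:
            lines.append(f"### Kernel: {kernel}")
            lines.append(header)
            lines.append(rule)
            for c in self.cells:
                if c.kernel != kernel:
                    continue
                rates = " | ".join(f"{c.per_gesture[g]:.2f}" for g in self.gesture_order)
                lines.append(
                    f"| {' + '.join(c.feature_set)} | {rates} | {c.mean_rate:.2f} |"
                )
            lines.append("")
        return "\n".join(lines)


def _full_feature_matrices(
    train_segs: list[Segment], test_segs: list[Segment]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Extract all four features (thresholds resolved on train) for both sides."""
    base_cfg = resolve_config(FeatureConfig(feature_set=FEATURE_NAMES), train_segs)
    from .features import extract_features  # local to avoid cycle at import time

    def mat(segs: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
        vecs = [extract_features(s, base_cfg) for s in segs]
        return np.vstack([v.values for v in vecs]), np.array([v.label for v in vecs])

    Xtr, ytr = mat(train_segs)
    Xte, yte = mat(test_segs)
    n_channels = train_segs[0].window.shape[1]
    return Xtr, ytr, Xte, yte, n_channels


def _select_columns(X: np.ndarray, feature_set: tuple[str, ...], n_channels: int) -> np.ndarray:
    cols = [
        c * len(FEATURE_NAMES) + FEATURE_NAMES.index(f)
        for c in range(n_channels)
        for f in feature_set
    ]
    return X[:, cols]


def _aggregate_cell(
    feature_set: tuple[str, ...],
    kernel_name: str,
    gesture_order: tuple[str, ...],
    per_repeat_gesture: list[dict[str, float]],
    per_repeat_multiclass: list[float],
    per_repeat_sv: list[float],
    kernel_specs: list[dict],
) -> ReportCell:
    per_gesture = {
        g: float(np.mean([r[g] for r in per_repeat_gesture])) for g in gesture_order
    }
    mean_per_repeat = [
        float(np.mean([r[g] for g in gesture_order])) for r in per_repeat_gesture
    ]
    return ReportCell(
        feature_set=tuple(feature_set),
        kernel=kernel_name,
        per_gesture=per_gesture,
        mean_rate=float(np.mean(mean_per_repeat)),
        sd_mean_rate=float(np.std(mean_per_repeat, ddof=0)),
        multiclass_rate=float(np.mean(per_repeat_multiclass)),
        mean_sv_per_class=float(np.mean(per_repeat_sv)),
        kernel_specs=kernel_specs,
    )


def _gesture_rates(model, Xte, yte, mode: str) -> dict[str, float]:
    fn = per_class_binary_rate if mode == "ova_binary" else per_class_recall
    rates = fn(model, Xte, yte)
    return {label: float(r) for label, r in zip(model.class_labels, rates)}


def run_baseline_grid(segments: Sequence[Segment], cfg: ExperimentConfig) -> ExperimentReport:
    """Benchmark every feature set under each kernel family at default
    parameters, over ``n_repeats`` fresh stratified splits."""
    segments = list(segments)
    gesture_order = tuple(g for g in GESTURE_LABELS if any(s.label == g for s in segments))
    if not gesture_order:
        gesture_order = tuple(dict.fromkeys(s.label for s in segments))
    labels = [s.label for s in segments]
    rng = np.random.default_rng(cfg.rng_seed)

    acc: dict[tuple, dict[str, list]] = {}
    for _ in range(cfg.n_repeats):
        tr_idx, te_idx = split_train_test(labels, cfg.test_fraction, rng)
        train_segs = [segments[i] for i in tr_idx]
        test_segs = [segments[i] for i in te_idx]
        Xtr_full, ytr, Xte_full, yte, n_ch = _full_feature_matrices(train_segs, test_segs)
        for fs in cfg.feature_sets:
            Xtr = _select_columns(Xtr_full, fs, n_ch)
            Xte = _select_columns(Xte_full, fs, n_ch)
            for kernel in cfg.kernels_baseline:
                spec = default_baseline_spec(kernel, Xtr)
                model = train_ova(Xtr, spec, y=ytr)
                rec = acc.setdefault(
                    (tuple(fs), kernel), {"gesture": [], "multi": [], "sv": [], "specs": []}
                )
                rec["gesture"].append(_gesture_rates(model, Xte, yte, cfg.rate_mode))
                rec["multi"].append(multiclass_rate(model, Xte, yte))
                rec["sv"].append(mean_sv_per_class(model))
                rec["specs"].append(spec.to_dict())

    cells = [
        _aggregate_cell(fs, kernel, gesture_order, rec["gesture"], rec["multi"],
                        rec["sv"], [rec["specs"][0]])
        for (fs, kernel), rec in acc.items()
    ]
    return ExperimentReport(gesture_order=gesture_order, cells=cells)


def run_cs_experiment(
    segments: Sequence[Segment],
    cfg: ExperimentConfig,
    cs_cfg: CsConfig,
    feature_set: tuple[str, ...] = ("MAV",),
    space: SearchSpace | None = None,
) -> ReportCell:
    """Cuckoo-Search-optimised run on one feature set.

    Per repeat: stratified split; CS maximises the training side's k-fold CV
    rate (support-vector count breaking ties), with fold assignments re-drawn
    from the fitness RNG stream at every evaluation; the winning kernel spec
    is refit on the whole training side and scored on the test side.
    """
    segments = list(segments)
    space = space or default_svm_search_space()
    gesture_order = tuple(g for g in GESTURE_LABELS if any(s.label == g for s in segments))
    if not gesture_order:
        gesture_order = tuple(dict.fromkeys(s.label for s in segments))
    labels = [s.label for s in segments]
    rng = np.random.default_rng(cfg.rng_seed)

    per_gesture, per_multi, per_sv, specs = [], [], [], []
    for _ in range(cfg.n_repeats):
        tr_idx, te_idx = split_train_test(labels, cfg.test_fraction, rng)
        train_segs = [segments[i] for i in tr_idx]
        test_segs = [segments[i] for i in te_idx]
        Xtr_full, ytr, Xte_full, yte, n_ch = _full_feature_matrices(train_segs, test_segs)
        Xtr = _select_columns(Xtr_full, feature_set, n_ch)
        Xte = _select_columns(Xte_full, feature_set, n_ch)

        fitness_rng = np.random.default_rng(int(rng.integers(2**31)))

        def fitness(params: dict) -> tuple[float, float]:
            spec = spec_from_params(params)
            rate, sv = cv_rate(Xtr, ytr, spec, folds=cfg.cv_folds, rng=fitness_rng)
            return rate, float(sv)

        run_cfg = CsConfig(
            n_nests=cs_cfg.n_nests,
            pa_abandon=cs_cfg.pa_abandon,
            max_iterations=cs_cfg.max_iterations,
            levy_alpha=cs_cfg.levy_alpha,
            step_scale=cs_cfg.step_scale,
            rng_seed=int(rng.integers(2**31)),
        )
        result = cs_optimize(fitness, space, run_cfg)
        best_spec = spec_from_params(result.best_params)
        model = train_ova(Xtr, best_spec, y=ytr)
        per_gesture.append(_gesture_rates(model, Xte, yte, cfg.rate_mode))
        per_multi.append(multiclass_rate(model, Xte, yte))
        per_sv.append(mean_sv_per_class(model))
        specs.append(best_spec.to_dict())

    return _aggregate_cell(
        tuple(feature_set), "CS-optimised", gesture_order,
        per_gesture, per_multi, per_sv, specs,
    )
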