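"""Evaluation protocol: stratified k-fold accuracy, ITR, window sweeps.

The workbench reproduces the offline protocol of a collaborative SSVEP
study at simulator scale: trials are featurized per analysis window,
fused per mode, classified with the transfer-learning pipeline under
stratified shuffled 10-fold cross-validation, and summarized as mean
accuracy and information transfer rate (ITR) per (mode, window) cell.

Every fold's model is fine-tuned from one shared pretrained checkpoint
whose source domain is simulated independently of the target group, so
no test trial ever influences pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import BandSpec, FeatureEpoch, featurize
from .fusion import align_group_trials, fuse
from .nn.architectures import build
from .simulate import RawEpoch, SimulationConfig, simulate_group
from .training import TrainConfig, TransferPipeline, pretrain

__all__ = [
    "EvalReport",
    "itr",
    "kfold_evaluate",
    "featurize_group",
    "group_dataset",
    "source_dataset",
    "evaluate_mode",
    "time_window_sweep",
    "compare_modes",
    "DEFAULT_WINDOWS",
]

#: Analysis windows of the standard sweep, seconds.
DEFAULT_WINDOWS = (3.0, 2.8, 2.6, 2.4, 2.2, 2.0, 1.8, 1.6)


@dataclass
class EvalReport:
    """Cross-validated result for one (mode, window) cell."""

    mode: str
    window_s: float
    fold_accuracies: list[float]
    mean_accuracy: float
    itr_bits_per_min: float
    n_subjects: int
    seed: int

    def __post_init__(self) -> None:
        if not all(0.0 <= a <= 1.0 for a in self.fold_accuracies):
            raise ValueError("fold accuracies must lie in [0, 1]")
        if self.itr_bits_per_min < 0:
            raise ValueError("ITR must be non-negative")


def itr(accuracy: float, n_classes: int = 4, selection_time: float = 3.0) -> float:
    """Information transfer rate in bits per minute (Wolpaw definition).

    bits/selection = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)),
    with the P in {0, 1} limits taken by continuity, scaled by 60/T
    selections per minute and floored at zero.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if selection_time <= 0:
        raise ValueError("selection_time must be positive")
    p, n = accuracy, n_classes
    bits = np.log2(n)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(max(0.0, bits) * 60.0 / selection_time)


def kfold_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    pipeline_factory: Callable[[], TransferPipeline],
    k: int = 10,
    seed: int = 0,
    mode: str = "single",
    window_s: float = 3.0,
    n_subjects: int = 1,
    include_rest_s: float = 0.0,
) -> EvalReport:
    """Stratified, shuffled k-fold cross-validation of a fit/predict pipeline.

    Each fold trains a fresh pipeline (typically fine-tuning from a shared
    pretrained checkpoint) on the training split and scores accuracy on
    the held-out split. ITR is computed from the mean accuracy with the
    analysis window (plus optional rest time) as the selection time.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"need >= {k} examples per class for {k}-fold CV; class counts "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_accuracies = []
    for train_idx, test_idx in splitter.split(X, y):
        pipe = pipeline_factory()
        pipe.fit(X[train_idx], y[train_idx])
        pred = pipe.predict(X[test_idx])
        fold_accuracies.append(float(np.mean(pred == y[test_idx])))
    mean_acc = float(np.mean(fold_accuracies))
    return EvalReport(
        mode=mode,
        window_s=window_s,
        fold_accuracies=fold_accuracies,
        mean_accuracy=mean_acc,
        itr_bits_per_min=itr(mean_acc, len(classes), window_s + include_rest_s),
        n_subjects=n_subjects,
        seed=seed,
    )


# ------------------------------------------------------------------ dataset assembly

def featurize_group(
    group: Sequence[Sequence[RawEpoch]],
    window_s: float | None = None,
    band: BandSpec | None = None,
) -> list[list[FeatureEpoch]]:
    """Run the full feature pipeline on every trial of every subject."""
    return [[featurize(ep, window_s=window_s, band=band) for ep in subj] for subj in group]


def group_dataset(
    feature_group: Sequence[Sequence[FeatureEpoch]], mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the target-domain (X, y) arrays for one fusion mode.

    ``single`` pools every subject's epochs as independent examples;
    the fusion modes align trials across subjects and fuse each tuple.
    """
    if mode == "single":
        feats = [f for subj in feature_group for f in subj]
        X = np.stack([f.values for f in feats])
        y = np.array([f.class_index for f in feats])
        return X, y
    tuples = align_group_trials(feature_group)
    fused = [fuse(t, mode) for t in tuples]
    X = np.stack([f.values for f in fused])
    y = np.array([f.class_index for f in fused])
    return X, y


def source_dataset(
    mode: str,
    n_group_subjects: int,
    sim_config: SimulationConfig,
    n_source_subjects: int = 6,
    trials_per_class: int = 12,
    seed: int = 0,
    window_s: float | None = None,
    band: BandSpec | None = None,
    combinations_per_trial: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate and featurize an independent source domain for pretraining.

    For ``single`` and ``average`` the source examples are individual
    subjects' epochs (the averaging mode reuses the single-person
    network). For ``parallel``/``serial`` each trial is fused across
    ``combinations_per_trial`` random combinations of source subjects —
    which subjects are combined does not matter for the resulting
    classifier, so combinations are drawn freely to enlarge the source
    set.
    """
    group = simulate_group(sim_config, n_source_subjects, trials_per_class, seed=seed)
    feats = featurize_group(group, window_s=window_s, band=band)
    if mode in ("single", "average"):
        return group_dataset(feats, "single")
    if n_source_subjects < n_group_subjects:
        raise ValueError(
            f"need >= {n_group_subjects} source subjects to fuse, got {n_source_subjects}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    n_trials = len(feats[0])
    fused_X, fused_y = [], []
    for k in range(n_trials):
        for _ in range(combinations_per_trial):
            members = rng.choice(n_source_subjects, size=n_group_subjects, replace=False)
            f = fuse([feats[m][k] for m in members], mode)
            fused_X.append(f.values)
            fused_y.append(f.class_index)
    return np.stack(fused_X), np.array(fused_y)


# ------------------------------------------------------------------ orchestration

def evaluate_mode(
    group: Sequence[Sequence[RawEpoch]],
    mode: str,
    window_s: float,
    seed: int = 0,
    k: int = 10,
    sim_config: SimulationConfig | None = None,
    band: BandSpec | None = None,
    n_source_subjects: int = 6,
    source_trials_per_class: int = 12,
    combinations_per_trial: int = 3,
    pretrain_config: TrainConfig | None = None,
    finetune_config: TrainConfig | None = None,
    include_rest_s: float = 0.0,
) -> EvalReport:
    """Pretrain once, then k-fold evaluate one fusion mode at one window.

    ``single`` mode evaluates each subject separately and averages the
    fold accuracies across subjects, mirroring the per-subject-average
    baseline that fused modes are compared against.
    """
    sim_config = sim_config or SimulationConfig()
    n_subjects = len(group)
    feats = featurize_group(group, window_s=window_s, band=band)
    bins = feats[0][0].n_bins
    arch = build(mode, n_subjects=max(n_subjects, 2) if mode != "single" else 1, bins=bins)

    src_X, src_y = source_dataset(
        mode,
        n_subjects,
        sim_config,
        n_source_subjects=n_source_subjects,
        trials_per_class=source_trials_per_class,
        seed=seed + 1000,
        window_s=window_s,
        band=band,
        combinations_per_trial=combinations_per_trial,
    )
    pre_cfg = pretrain_config or TrainConfig.for_pretrain(seed=seed)
    fin_cfg = finetune_config or TrainConfig.for_finetune(seed=seed)
    base_model = pretrain(arch, src_X, src_y, pre_cfg)
    factory = lambda: TransferPipeline(base_model, fin_cfg)

    if mode == "single":
        per_subject = []
        for subj_feats in feats:
            X, y = group_dataset([subj_feats], "single")
            per_subject.append(
                kfold_evaluate(
                    X, y, factory, k=k, seed=seed, mode=mode, window_s=window_s,
                    n_subjects=1, include_rest_s=include_rest_s,
                )
            )
        fold_acc = np.mean([r.fold_accuracies for r in per_subject], axis=0).tolist()
        mean_acc = float(np.mean(fold_acc))
        return EvalReport(
            mode=mode,
            window_s=window_s,
            fold_accuracies=fold_acc,
            mean_accuracy=mean_acc,
            itr_bits_per_min=itr(mean_acc, sim_config.n_classes, window_s + include_rest_s),
            n_subjects=n_subjects,
            seed=seed,
        )
    X, y = group_dataset(feats, mode)
    report = kfold_evaluate(
        X, y, factory, k=k, seed=seed, mode=mode, window_s=window_s,
        n_subjects=n_subjects, include_rest_s=include_rest_s,
    )
    return report


def time_window_sweep(
    group: Sequence[Sequence[RawEpoch]],
    modes: Sequence[str] = ("single", "parallel", "serial", "average"),
    windows: Sequence[float] = DEFAULT_WINDOWS,
    seed: int = 0,
    **kwargs,
) -> list[EvalReport]:
    """Evaluate every mode at every analysis window.

    Features, bin counts and network input geometry are recomputed per
    window; extra keyword arguments are forwarded to
    :func:`evaluate_mode`.
    """
    reports = []
    for window_s in windows:
        for mode in modes:
            reports.append(evaluate_mode(group, mode, window_s, seed=seed, **kwargs))
    return reports


def compare_modes(reports: Sequence[EvalReport]) -> dict:
    """Aggregate sweep reports into mode x window tables plus overall means.

    Returns ``{"accuracy": DataFrame, "itr": DataFrame, "overall": Series}``
    where the overall column averages each mode's accuracy across its
    windows (the "total classification accuracy" summary).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    seen = {}
    for r in reports:
        key = (r.mode, r.window_s)
        if key in seen:
            raise ValueError(f"duplicate report for mode={r.mode}, window={r.window_s}")
        seen[key] = r
    windows_by_mode = {}
    for mode, window in seen:
        windows_by_mode.setdefault(mode, set()).add(window)
    window_sets = set(frozenset(v) for v in windows_by_mode.values())
    if len(window_sets) != 1:
        raise ValueError(f"modes cover inconsistent window sets: {windows_by_mode}")
    rows = [
        {
            "mode": r.mode,
            "window_s": r.window_s,
            "accuracy": r.mean_accuracy,
            "itr_bits_per_min": r.itr_bits_per_min,
        }
        for r in seen.values()
    ]
    df = pd.DataFrame(rows)
    acc = df.pivot(index="mode", columns="window_s", values="accuracy").sort_index(axis=1, ascending=False)
    itr_table = df.pivot(index="mode", columns="window_s", values="itr_bits_per_min").sort_index(axis=1, ascending=False)
    overall = acc.mean(axis=1).rename("overall_accuracy")
    return {"accuracy": acc, "itr": itr_table, "overall": overall}
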