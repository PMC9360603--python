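"""Canned synthetic-data experiments exercising the full pipeline.

These are the package's standard desk-scale studies: simulator fidelity
checks, the high-SNR single-person transfer-learning benchmark, the
fusion-benefit window sweep (two-person parallel fusion vs. the
single-person baseline), and the paired transfer-vs-scratch comparison.
Problem sizes are deliberately modest — a few subjects, a few dozen
trials, shortened training schedules — so a full run completes in
minutes on one CPU while preserving the qualitative structure of a
full-scale study (see docs/methods.md for the exact conditions).
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .evaluate import (
    DEFAULT_WINDOWS,
    featurize_group,
    group_dataset,
    itr,
    kfold_evaluate,
    source_dataset,
)
from .features import featurize
from .nn.architectures import build
from .simulate import (
    SimulationConfig,
    SubjectProfile,
    estimate_snr_db,
    simulate_group,
    simulate_subject_dataset,
    simulate_trial,
)
from .training import TrainConfig, TransferPipeline, finetune, pretrain, train_from_scratch

__all__ = [
    "simulator_fidelity",
    "single_person_benchmark",
    "fusion_benefit_sweep",
    "transfer_benefit",
    "MODERATE_SNR_DB",
]

#: SNR (dB) of the "moderate difficulty" study condition: single-person
#: accuracy spans the mid-range across the window sweep, the regime in
#: which multi-subject collaboration has room to help.
MODERATE_SNR_DB = -18.0


def simulator_fidelity(
    n_epochs: int = 100, snr_db: float = 20.0, seed: int = 0
) -> dict[str, float]:
    """Spectral fidelity and SNR calibration of the signal generator.

    Simulates ``n_epochs`` high-SNR trials cycling through the four
    targets, and reports (a) the fraction whose band-limited spectral
    argmax at Oz falls on the stimulation frequency (within one bin) and
    (b) the mean absolute difference between configured and measured
    SNR in dB.
    """
    config = SimulationConfig(snr_db=snr_db)
    hits = 0
    snr_errors = []
    for i in range(n_epochs):
        cls = i % config.n_classes
        epoch = simulate_trial(config, cls, seed=seed + i)
        snr_errors.append(abs(estimate_snr_db(epoch, config) - snr_db))
        feats = featurize(epoch, window_s=None, normalize=False)
        peak = feats.freq_axis[int(np.argmax(feats.values[1]))]
        df = feats.freq_axis[1] - feats.freq_axis[0]
        if abs(peak - config.stim_freqs[cls]) <= df / 2 + 1e-9:
            hits += 1
    return {
        "peak_hit_rate": hits / n_epochs,
        "snr_mean_abs_error_db": float(np.mean(snr_errors)),
    }


def single_person_benchmark(
    seed: int = 0,
    snr_db: float = 15.0,
    n_subjects: int = 8,
    trials_per_class: int = 12,
    window_s: float = 3.0,
    k: int = 10,
    pretrain_epochs: int = 80,
    finetune_epochs: int = 40,
) -> dict[str, float]:
    """High-SNR single-person transfer-learning benchmark.

    Simulates ``n_subjects`` subjects; the first ``n_subjects - 2`` form
    the source domain (pretraining, full protocol: Adam, lr 1e-3, 80
    epochs, batch 16), the last two are target subjects evaluated with
    stratified 10-fold cross-validation, each fold fine-tuned (lr 1e-4,
    40 epochs, shallow convs frozen) from the shared checkpoint.
    """
    config = SimulationConfig(snr_db=snr_db)
    group = simulate_group(config, n_subjects, trials_per_class, seed=seed)
    feats = featurize_group(group, window_s=window_s)
    bins = feats[0][0].n_bins

    src_X, src_y = group_dataset(feats[: n_subjects - 2], "single")
    arch = build("single", bins=bins)
    base = pretrain(arch, src_X, src_y, TrainConfig.for_pretrain(seed=seed, epochs=pretrain_epochs))
    fin_cfg = TrainConfig.for_finetune(seed=seed, epochs=finetune_epochs)

    accs = []
    for subj_feats in feats[n_subjects - 2 :]:
        X, y = group_dataset([subj_feats], "single")
        report = kfold_evaluate(
            X, y, lambda: TransferPipeline(base, fin_cfg), k=k, seed=seed,
            mode="single", window_s=window_s,
        )
        accs.append(report.mean_accuracy)
    mean_acc = float(np.mean(accs))
    return {
        "mean_accuracy": mean_acc,
        "itr_bits_per_min": itr(mean_acc, config.n_classes, window_s),
        "per_subject": accs,
    }


def _split_fit_score(
    base_model, X: np.ndarray, y: np.ndarray, fin_cfg: TrainConfig, seed: int
) -> float:
    """Stratified half split, fine-tune on train half, accuracy on test half."""
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=0.5, stratify=y, random_state=seed)
    pipe = TransferPipeline(base_model, fin_cfg).fit(X[tr], y[tr])
    return float(np.mean(pipe.predict(X[te]) == y[te]))


def fusion_benefit_sweep(
    windows: tuple[float, ...] = DEFAULT_WINDOWS,
    n_seeds: int = 10,
    seed: int = 0,
    snr_db: float = MODERATE_SNR_DB,
    trials_per_class: int = 8,
    n_source_subjects: int = 4,
    source_trials_per_class: int = 8,
    combinations_per_trial: int = 3,
    pretrain_epochs: int = 24,
    finetune_epochs: int = 12,
) -> pd.DataFrame:
    """Two-person parallel fusion vs. single-person baseline across windows.

    For every analysis window, both networks are pretrained once on an
    independent source domain; then for each of ``n_seeds`` replicate
    seeds a fresh two-subject target group is simulated, fine-tuned on a
    stratified half of its trials and scored on the other half. Single
    accuracy is the mean of the two members' individual scores.

    Returns a tidy DataFrame with columns window_s / seed / single /
    parallel.
    """
    config = SimulationConfig(snr_db=snr_db)
    fin_cfg = TrainConfig.for_finetune(seed=seed, epochs=finetune_epochs)
    rows = []
    for window_s in windows:
        bins = featurize(
            simulate_trial(config, 0, seed=seed), window_s=window_s
        ).n_bins
        bases = {}
        for mode in ("single", "parallel"):
            src_X, src_y = source_dataset(
                mode, 2, config,
                n_source_subjects=n_source_subjects,
                trials_per_class=source_trials_per_class,
                seed=seed + 1000, window_s=window_s,
                combinations_per_trial=combinations_per_trial,
            )
            arch = build(mode, n_subjects=2, bins=bins)
            bases[mode] = pretrain(
                arch, src_X, src_y,
                TrainConfig.for_pretrain(seed=seed, epochs=pretrain_epochs),
            )
        for rep in range(n_seeds):
            rep_seed = seed + 100 + rep
            group = simulate_group(config, 2, trials_per_class, seed=rep_seed)
            feats = featurize_group(group, window_s=window_s)
            single_accs = [
                _split_fit_score(
                    bases["single"], *group_dataset([sf], "single"), fin_cfg, rep_seed
                )
                for sf in feats
            ]
            par_acc = _split_fit_score(
                bases["parallel"], *group_dataset(feats, "parallel"), fin_cfg, rep_seed
            )
            rows.append(
                {
                    "window_s": window_s,
                    "seed": rep_seed,
                    "single": float(np.mean(single_accs)),
                    "parallel": par_acc,
                }
            )
    return pd.DataFrame(rows)


def transfer_benefit(
    n_seeds: int = 10,
    seed: int = 0,
    snr_db: float = MODERATE_SNR_DB,
    target_trials_per_class: int = 6,
    n_source_subjects: int = 6,
    source_trials_per_class: int = 8,
    window_s: float = 3.0,
    pretrain_epochs: int = 40,
    finetune_epochs: int = 40,
) -> pd.DataFrame:
    """Paired comparison: pretrain + fine-tune vs. training from scratch.

    One single-person network is pretrained on an independent source
    group. For each replicate seed a fresh target subject contributes
    ``4 * target_trials_per_class`` training trials (<= 24 by default)
    plus an equally sized held-out test set; the pretrained model is
    fine-tuned on the training trials (deep layers only) while the
    baseline trains the same architecture from random initialization on
    the same trials for the same number of epochs at the pretraining
    learning rate.
    """
    config = SimulationConfig(snr_db=snr_db)
    bins = featurize(simulate_trial(config, 0, seed=seed), window_s=window_s).n_bins
    arch = build("single", bins=bins)
    src_X, src_y = source_dataset(
        "single", 1, config, n_source_subjects=n_source_subjects,
        trials_per_class=source_trials_per_class, seed=seed + 1000, window_s=window_s,
    )
    base = pretrain(arch, src_X, src_y, TrainConfig.for_pretrain(seed=seed, epochs=pretrain_epochs))
    fin_cfg = TrainConfig.for_finetune(seed=seed, epochs=finetune_epochs)

    rows = []
    for rep in range(n_seeds):
        rep_seed = seed + 200 + rep
        profile = SubjectProfile(subject_id=f"T{rep}")
        train_eps = simulate_subject_dataset(
            config, profile, target_trials_per_class, seed=rep_seed
        )
        test_eps = simulate_subject_dataset(
            config, profile, target_trials_per_class, seed=rep_seed + 5000
        )
        Xtr, ytr = group_dataset([[featurize(e, window_s=window_s) for e in train_eps]], "single")
        Xte, yte = group_dataset([[featurize(e, window_s=window_s) for e in test_eps]], "single")

        tl_model = finetune(copy.deepcopy(base), Xtr, ytr, fin_cfg)
        tl_acc = float(np.mean(tl_model.predict(Xte) == yte))

        scratch = train_from_scratch(
            arch, Xtr, ytr,
            TrainConfig.for_pretrain(seed=rep_seed, epochs=finetune_epochs),
        )
        scratch_acc = float(np.mean(scratch.predict(Xte) == yte))
        rows.append({"seed": rep_seed, "transfer": tl_acc, "scratch": scratch_acc})
    return pd.DataFrame(rows)
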