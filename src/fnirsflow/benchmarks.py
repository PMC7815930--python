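"""Seeded end-to-end benchmark runs on the synthetic study conditions.

These functions reproduce, from scratch, the quantities the toolkit is
validated on: cross-validated decoding accuracy on high-SNR synthetic
sessions, a permutation-null (shuffled-label) chance control, and t-map
false-positive / detection calibration.  Problem sizes are chosen so a full
validation pass completes in minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import scipy.stats

from .decoder import NetworkSpec, TrainConfig, TrialTensor, augment_windows
from .evaluation import cross_validate
from .hemodynamics import DEFAULT_FS, preprocess
from .mapping_viz import expected_response, robust_t, tmap
from .paradigm import SessionSpec, build_schedule, epoch_windows, paper_session
from .synthetic_data import SimConfig, simulate_hemo, simulate_session

__all__ = [
    "RECOVERY_SPEC", "RECOVERY_TRAIN",
    "study_tensors", "decoding_recovery", "shuffled_label_control",
    "tmap_null_fpr", "tmap_detection_rate",
]

#: Architecture and optimizer settings for the recovery benchmark: the
#: single-conv-layer variant is ample for the default high-SNR generator and
#: keeps an 8-fold run around twenty seconds.
RECOVERY_SPEC = NetworkSpec(variant="CNN1-a")
RECOVERY_TRAIN = TrainConfig(epochs=50, batch_size=16, learning_rate=0.001)


def study_tensors(sim_seed: int, windows_per_trial: int = 20,
                  window_len: int = 128, fs: float = DEFAULT_FS) -> list[TrialTensor]:
    """Simulate the 12-trial session and cut augmented decoder samples.

    Sliding windows are spread over each full video phase (per-duration
    stride) and capped per trial, giving balanced classes regardless of the
    15/30/60 s duration mix.
    """
    schedule, hemo, _ = simulate_session(SimConfig(seed=sim_seed), fs=fs)
    hemo = preprocess(hemo)
    tensors: list[TrialTensor] = []
    for w in epoch_windows(schedule, fs):
        stride = max(1, (w.length - window_len) // max(windows_per_trial - 1, 1))
        tensors += augment_windows(hemo, [w], window_len, stride,
                                   max_per_trial=windows_per_trial)
    return tensors


def decoding_recovery(seed: int, replicates: int = 3, k: int = 8) -> list[float]:
    """Mean 8-fold CV accuracy (%) per replicate on default high-SNR sessions."""
    means = []
    for r in range(replicates):
        tensors = study_tensors(seed + r)
        cfg = replace(RECOVERY_TRAIN, seed=seed + r)
        means.append(cross_validate(tensors, RECOVERY_SPEC, cfg, k=k).mean)
    return means


def shuffled_label_control(seed: int, runs: int = 10, k: int = 8) -> list[float]:
    """Permutation-null CV accuracies (%): labels permuted across windows.

    Under the null the labels are exchangeable across windows, so each window
    is its own fold group; the distribution of means concentrates at chance
    (33.3% for three balanced classes).
    """
    means = []
    for r in range(runs):
        tensors = study_tensors(seed + 101 + r, windows_per_trial=6)
        rng = np.random.default_rng(seed + 501 + r)
        labels = [t.label for t in tensors]
        perm = rng.permutation(len(labels))
        shuffled = [TrialTensor(t.matrix, labels[perm[i]], i)
                    for i, t in enumerate(tensors)]
        cfg = replace(RECOVERY_TRAIN, epochs=15, seed=seed + r)
        means.append(cross_validate(shuffled, RECOVERY_SPEC, cfg, k=k).mean)
    return means


def tmap_null_fpr(seed: int, n_samples: int = 200, replicates: int = 500,
                  alpha: float = 0.05) -> float:
    """Fraction of white-noise series whose robust t exceeds the one-tailed
    critical value against a realistic expected-response regressor."""
    reg = expected_response(build_schedule(paper_session()), fs=DEFAULT_FS)
    x = reg.values[1800:1800 + n_samples]  # spans a video response
    t_crit = scipy.stats.t.ppf(1 - alpha, n_samples - 1)
    rng = np.random.default_rng(seed)
    hits = sum(robust_t(rng.normal(size=n_samples), x).t_value > t_crit
               for _ in range(replicates))
    return hits / replicates


def tmap_detection_rate(seed: int, replicates: int = 50,
                        alpha: float = 0.05) -> float:
    """Fraction of simulated sessions in which every injected active channel
    (1-3, unit peak amplitude) is flagged by the t-map."""
    session = SessionSpec((paper_session().sections[0],))
    labels = ["like"] * sum(len(s.trials) for s in session.sections)
    schedule = build_schedule(session, labels=labels)
    detected = 0
    for r in range(replicates):
        cfg = SimConfig(seed=seed + r, class_amplitudes={"like": 1.0},
                        active_channels_per_class={"like": (1, 2, 3)})
        hemo, _ = simulate_hemo(schedule, labels, cfg, fs=DEFAULT_FS)
        hemo = preprocess(hemo)
        reg = expected_response(schedule, fs=DEFAULT_FS, n_samples=hemo.n_samples)
        tm = tmap(hemo, reg, alpha=alpha)
        active = set(np.array(tm.channel_ids)[tm.active])
        detected += {1, 2, 3} <= active
    return detected / replicates
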