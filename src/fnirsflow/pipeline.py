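"""End-to-end orchestration: simulate/convert -> preprocess -> tensorize ->
train/evaluate -> t-map / PCA, with every artifact stamped by config hash and
seed.  Single-threaded reruns of the same config are bit-identical."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import PipelineConfig, config_hash
from .decoder import NetworkSpec, TrainConfig, augment_windows, tensorize, train
from .evaluation import cross_validate, pairwise_classify
from .hemodynamics import (ExtinctionMatrix, GeometryConfig, HemoSeries,
                           detrend, lowpass, mbll, optical_density, preprocess)
from .mapping_viz import expected_response, feature_pca, tmap
from .paradigm import (PREFERENCES, Section, SessionSpec, StimulusVideo,
                       TrialSpec, build_schedule, epoch_windows, table3_m_samples)
from .synthetic_data import SimConfig, simulate_hemo, simulate_optical

__all__ = ["run_pipeline", "session_from_config", "sim_config_from", "PipelineError"]

log = logging.getLogger("fnirsflow")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return wrapped
    return deco


def session_from_config(cfg: PipelineConfig) -> SessionSpec:
    p = cfg.paradigm
    sections = []
    for brand in p.brands:
        trials = tuple(
            TrialSpec(StimulusVideo(brand=brand, duration_s=d),
                      notification_s=p.notification_s,
                      rating_s=p.rating_s, rest_s=p.rest_s)
            for _ in range(p.repeats_per_section)
            for d in p.durations_s
        )
        sections.append(Section(p.initial_rest_s, trials))
    return SessionSpec(tuple(sections))


def _labels_for(cfg: PipelineConfig, n_trials: int) -> list[str]:
    if cfg.paradigm.labels is not None:
        return list(cfg.paradigm.labels)
    from .synthetic_data import default_labels
    return default_labels(n_trials)


def sim_config_from(cfg: PipelineConfig) -> SimConfig:
    s = cfg.simulation
    return SimConfig(
        class_amplitudes=dict(s.class_amplitudes),
        active_channels_per_class={c: tuple(s.active_channels) for c in PREFERENCES},
        sine_noise={0.03: s.vlf_amp, 0.2: s.respiration_amp, 0.8: s.cardiac_amp},
        white_sd=s.white_sd, drift_slope=s.drift_slope,
        hbr_coupling=s.hbr_coupling, seed=cfg.seed,
    )


def _geometry(cfg: PipelineConfig) -> GeometryConfig:
    g = cfg.geometry
    return GeometryConfig(g.source_detector_distance_cm, (g.dpf_690, g.dpf_830))


def _extinction(cfg: PipelineConfig) -> ExtinctionMatrix:
    e = cfg.extinction
    return ExtinctionMatrix(e.eps_hbo_690, e.eps_hbr_690, e.eps_hbo_830, e.eps_hbr_830)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run the configured synthetic end-to-end analysis; returns artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stamp = {"config_hash": config_hash(cfg), "seed": cfg.seed,
             "numpy": np.__version__, "python": platform.python_version()}
    log.info("run %s seed=%d", stamp["config_hash"], cfg.seed)

    # -- simulate ----------------------------------------------------------
    session = _stage("paradigm")(session_from_config)(cfg)
    n_trials = sum(len(s.trials) for s in session.sections)
    labels = _labels_for(cfg, n_trials)
    schedule = _stage("paradigm")(build_schedule)(session, labels=labels)
    sim = sim_config_from(cfg)
    hemo, label_table = _stage("simulate")(simulate_hemo)(schedule, labels, sim, fs=cfg.fs)
    fio.write_schedule_tsv(schedule, out / "schedule.tsv")
    fio.write_labels_tsv(label_table, out / "labels.tsv")
    fio.write_hemo_csv(hemo, out / "hemo_raw.csv")

    if cfg.simulation.roundtrip_optical:
        rec = _stage("simulate")(simulate_optical)(hemo, _geometry(cfg), _extinction(cfg))
        fio.write_intensity_csv(rec, out / "intensity.csv")
        od = _stage("convert")(optical_density)(rec, None)
        hemo = _stage("convert")(mbll)(od, _geometry(cfg), _extinction(cfg), fs=rec.fs,
                                       channel_ids=rec.channel_ids)

    # -- preprocess --------------------------------------------------------
    f = cfg.filter

    def _preprocess(h: HemoSeries) -> HemoSeries:
        return preprocess(h, order=f.order, fc_hz=f.fc_hz, detrend_method=f.detrend)

    hemo_pp = _stage("preprocess")(_preprocess)(hemo)
    fio.write_hemo_csv(hemo_pp, out / "hemo_preprocessed.csv")

    # -- tensorize ---------------------------------------------------------
    def _tensors():
        windows = epoch_windows(schedule, cfg.fs, m_samples="auto")
        if cfg.epochs.m_samples == "table3":
            # truncate each epoch to the printed per-duration length
            by_trial = {ev.trial_index: ev.duration_s
                        for ev in schedule if ev.kind == "video"}
            windows = [replace(w, length=table3_m_samples(by_trial[w.trial_index]))
                       for w in windows]
        elif cfg.epochs.m_samples != "auto":
            windows = epoch_windows(schedule, cfg.fs, m_samples=int(cfg.epochs.m_samples))
        if cfg.epochs.window_len is not None:
            return augment_windows(hemo_pp, windows, cfg.epochs.window_len,
                                   cfg.epochs.stride,
                                   max_per_trial=cfg.epochs.max_windows_per_trial)
        lengths = {w.length for w in windows}
        if len(lengths) > 1:
            raise ValueError(
                f"mixed epoch lengths {sorted(lengths)}: set epochs.m_samples or "
                f"epochs.window_len to a fixed sample count")
        return tensorize(hemo_pp, windows)

    tensors = _stage("tensorize")(_tensors)()

    # -- train / evaluate --------------------------------------------------
    spec = NetworkSpec(variant=cfg.network.variant,
                       compat_table3=cfg.network.compat_table3,
                       dropout_rate=cfg.network.dropout_rate)
    tc = TrainConfig(epochs=cfg.train.epochs, batch_size=cfg.train.batch_size,
                     learning_rate=cfg.train.learning_rate,
                     adam_beta1=cfg.train.adam_beta1, adam_beta2=cfg.train.adam_beta2,
                     adam_eps=cfg.train.adam_eps, seed=cfg.seed)
    if cfg.evaluation.pair is not None:
        report = _stage("evaluate")(pairwise_classify)(
            tensors, tuple(cfg.evaluation.pair), spec, tc, k=cfg.evaluation.k)
    else:
        report = _stage("evaluate")(cross_validate)(
            tensors, spec, tc, k=cfg.evaluation.k, normalize=cfg.evaluation.normalize)
    pd.DataFrame({"fold": np.arange(1, len(report.per_fold) + 1),
                  "accuracy_percent": report.per_fold}).to_csv(
        out / "cv_report.tsv", sep="\t", index=False, lineterminator="\n")
    summary = {**stamp, "mean_accuracy_percent": report.mean,
               "sd_accuracy_percent": report.sd, "classes": list(report.classes),
               "n_samples": len(tensors), "k": cfg.evaluation.k,
               "variant": spec.variant}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # -- t-map -------------------------------------------------------------
    def _tmap():
        reg = expected_response(schedule, fs=cfg.fs, n_samples=hemo_pp.n_samples)
        return tmap(hemo_pp, reg, alpha=cfg.tmap.alpha)

    tm = _stage("tmap")(_tmap)()
    pd.DataFrame({"channel": tm.channel_ids, "t_value": tm.t_values,
                  "active": tm.active.astype(int)}).to_csv(
        out / "tmap.tsv", sep="\t", index=False, float_format="%.10g",
        lineterminator="\n")

    # -- feature PCA -------------------------------------------------------
    def _pca():
        spec3 = spec if spec.n_classes == len(report.classes) else \
            replace(spec, n_classes=len(report.classes))
        fitted = train(tensors if cfg.evaluation.pair is None
                       else [t for t in tensors if t.label in report.classes],
                       spec3, tc, classes=report.classes)
        feats = fitted.model.features(np.stack([t.matrix for t in tensors
                                                if t.label in report.classes]))
        proj = feature_pca(feats)
        return proj

    proj = _stage("visualize")(_pca)()
    kept = [t for t in tensors if t.label in report.classes]
    pd.DataFrame({"pc1": proj.scores[:, 0], "pc2": proj.scores[:, 1],
                  "label": [t.label for t in kept],
                  "trial_index": [t.trial_index for t in kept]}).to_csv(
        out / "pca_scores.tsv", sep="\t", index=False, float_format="%.10g",
        lineterminator="\n")

    return {"out_dir": str(out), **stamp,
            "mean_accuracy_percent": report.mean,
            "artifacts": sorted(p.name for p in out.iterdir())}
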