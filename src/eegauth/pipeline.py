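"""End-to-end pipeline wiring and configuration.

``PipelineConfig`` gathers every stage's tunables in one schema-validated
document (unknown keys are rejected) whose hash is embedded in all output
artifacts for provenance. ``fit_pipeline`` fits the full chain — preprocess,
segment, band-power features, MI selection, scaler, classifier — on training
recordings; ``predict_segments`` scores new recordings end-to-end; and
``run_identification`` / ``run_chance`` reproduce the chronological-split
identification framework and the label-shuffle chance-level analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import authenticate as auth
from . import classify, evaluate, features, preprocess, select
from .synth import SimConfig, generate_dataset


class PipelineConfig(BaseModel):
    """All pipeline tunables; defaults are the reference recipe."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    # synthetic data
    n_users: int = 8
    n_channels: int = 8
    fs: float = 256.0
    n_runs: int = 7
    n_train_runs: int = 3
    run_duration: float = 60.0
    separation: float = 0.5
    noise_sd: float = 1.0
    erp_enabled: bool = False
    erp_rate: float = 0.5
    # preprocessing
    low_hz: float = 1.0
    high_hz: float = 50.0
    use_ica: bool = False
    ica_components: int = 6
    kurtosis_threshold: float = 8.0
    window: int = 512
    stride: int = 256
    # selection
    q: int = 10
    n_bins: int = 10
    # classifier
    classifier: str = "ffnn"
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    dropout_rate: float = 0.2
    # authentication
    theta: float = 0.5
    require_claimed_match: bool = True
    # randomness
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.classifier not in ("ffnn",) + classify.BASELINE_KINDS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        if not (1 <= self.n_train_runs < self.n_runs):
            raise ValueError("need 1 <= n_train_runs < n_runs")
        return self

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_users=self.n_users, n_channels=self.n_channels, fs=self.fs,
            n_runs=self.n_runs, n_train_runs=self.n_train_runs,
            run_duration=self.run_duration, separation=self.separation,
            noise_sd=self.noise_sd, erp_enabled=self.erp_enabled,
            erp_rate=self.erp_rate, seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


@dataclass
class PipelineModel:
    """The fitted chain: everything needed to score raw recordings."""

    config: PipelineConfig
    selection: select.SelectionResult
    scaler: features.ScalerStats
    model: classify.TrainedModel


def preprocess_and_segment(recordings, config: PipelineConfig) -> preprocess.SegmentSet:
    cleaned = [
        preprocess.preprocess_recording(
            r, low_hz=config.low_hz, high_hz=config.high_hz,
            use_ica=config.use_ica, ica_components=config.ica_components,
            kurtosis_threshold=config.kurtosis_threshold)
        for r in recordings
    ]
    return preprocess.segment(cleaned, window=config.window, stride=config.stride)


def _train_classifier(values, labels, config: PipelineConfig) -> classify.TrainedModel:
    if config.classifier == "ffnn":
        ffnn_cfg = classify.FfnnConfig(
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            dropout_rate=config.dropout_rate, seed=config.seed)
        return classify.train_ffnn(values, labels, ffnn_cfg)
    return classify.train_baseline(config.classifier, values, labels)


def fit_pipeline(train_recordings, config: PipelineConfig) -> PipelineModel:
    """Fit selection, scaler and classifier on training recordings only."""
    segs = preprocess_and_segment(train_recordings, config)
    feats = features.extract_features(segs)
    selection, reduced = select.select_top_q(feats, q=config.q,
                                             n_bins=config.n_bins)
    scaler = features.fit_scaler(reduced)
    values = features.apply_scaler(reduced, scaler)
    model = _train_classifier(values, reduced.labels, config)
    return PipelineModel(config=config, selection=selection, scaler=scaler,
                         model=model)


def transform_features(pm: PipelineModel, feats: features.FeatureMatrix) -> np.ndarray:
    reduced = select.apply_selection(feats, pm.selection)
    return features.apply_scaler(reduced, pm.scaler)


def predict_segments(pm: PipelineModel, recordings) -> classify.PredictionSet:
    """Score raw recordings end-to-end with a fitted pipeline."""
    segs = preprocess_and_segment(recordings, pm.config)
    feats = features.extract_features(segs)
    return classify.predict(pm.model, transform_features(pm, feats))


def run_identification(dataset, config: PipelineConfig | None = None) -> dict:
    """Chronological-split identification: train on runs 1..n_train_runs of
    every user, evaluate per-segment classification on the remaining runs."""
    config = config or PipelineConfig()
    train = [r for r in dataset.recordings if r.run_index <= config.n_train_runs]
    test = [r for r in dataset.recordings if r.run_index > config.n_train_runs]
    pm = fit_pipeline(train, config)
    preds = predict_segments(pm, test)
    segs = preprocess_and_segment(test, config)
    labels = segs.labels
    users = sorted({r.user_id for r in dataset.recordings})
    cm = evaluate.confusion_matrix(labels, preds.predicted_labels,
                                   k=len(users), class_labels=np.asarray(users))
    report = evaluate.macro_metrics(cm)
    return {
        "provenance": config.provenance(),
        "classifier": config.classifier,
        "n_train_segments": int(sum(
            (r.n_samples - config.window) // config.stride + 1 for r in train)),
        "n_test_segments": int(labels.size),
        "confusion_matrix": cm.counts.tolist(),
        "class_labels": [int(u) for u in users],
        "metrics": {
            "accuracy": report.accuracy,
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
            "specificity": report.specificity,
            "overall_accuracy": report.overall_accuracy,
        },
        "pipeline_model": pm,
    }


def run_lopo(dataset, config: PipelineConfig | None = None,
             thetas=None) -> dict:
    """LOPO authentication evaluation with a threshold sweep."""
    config = config or PipelineConfig()
    trials = auth.lopo_evaluate(dataset, config, theta=config.theta,
                                require_claimed_match=config.require_claimed_match)
    scores = [t.score for t in trials]
    genuine = [t.is_genuine for t in trials]
    rates = evaluate.far_frr([t.decision for t in trials], genuine)
    if thetas is None:
        thetas = np.linspace(0.05, 1.0, 20)
    sweep = evaluate.far_frr_curve(scores, genuine, thetas)
    curves = evaluate.roc_det_curves(list(zip(scores, genuine)))
    return {
        "provenance": config.provenance(),
        "theta": config.theta,
        "n_trials": len(trials),
        "n_genuine": int(np.sum(genuine)),
        "n_imposter": int(len(trials) - np.sum(genuine)),
        "far": rates.far,
        "frr": rates.frr,
        "auc": curves["auc"],
        "eer": curves["eer"],
        "sweep": sweep.curve,
        "trials": trials,
    }


def run_chance(dataset, config: PipelineConfig | None = None,
               n_shuffles: int = 100, fast_epochs: int | None = None) -> dict:
    """Empirical chance level for the identification task (label-shuffled
    retraining on the chronological split)."""
    config = config or PipelineConfig()
    train = [r for r in dataset.recordings if r.run_index <= config.n_train_runs]
    test = [r for r in dataset.recordings if r.run_index > config.n_train_runs]
    train_segs = preprocess_and_segment(train, config)
    test_segs = preprocess_and_segment(test, config)
    train_feats = features.extract_features(train_segs)
    test_feats = features.extract_features(test_segs)
    selection, train_red = select.select_top_q(train_feats, q=config.q,
                                               n_bins=config.n_bins)
    scaler = features.fit_scaler(train_red)
    train_x = features.apply_scaler(train_red, scaler)
    test_x = features.apply_scaler(select.apply_selection(test_feats, selection),
                                   scaler)
    ffnn_cfg = classify.FfnnConfig(
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, dropout_rate=config.dropout_rate,
        seed=config.seed)
    result = evaluate.chance_level(train_x, train_red.labels, test_x,
                                   test_feats.labels, config=ffnn_cfg,
                                   n_shuffles=n_shuffles, seed=config.seed,
                                   fast_epochs=fast_epochs)
    result["provenance"] = config.provenance()
    return result


def simulate(config: PipelineConfig | None = None):
    """Generate the synthetic campaign described by the config."""
    config = config or PipelineConfig()
    return generate_dataset(config.sim_config())
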