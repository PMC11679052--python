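"""File formats: recordings (CSV + JSON sidecar), feature tables (TSV),
segment stores (NPZ + JSON manifest), model directories, decision tables
(TSV) and report JSON. All JSON artifacts embed the pipeline config hash and
seed for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FfnnConfig, TrainedModel, _Mlp
from .features import BAND_NAMES, FeatureMatrix, ScalerStats
from .preprocess import SegmentSet
from .select import SelectionResult
from .synth import Recording

FORMAT_VERSION = 1


# ---------------------------------------------------------------- recordings

def write_recording(rec: Recording, csv_path: str | Path) -> None:
    """One CSV per recording (rows = samples, columns = channels, header =
    channel names) plus a JSON sidecar with fs / labels / events."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "version": FORMAT_VERSION,
        "fs": rec.fs,
        "user_id": rec.user_id,
        "run_index": rec.run_index,
        "event_times": rec.event_times,
        "channel_names": rec.channel_names,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {csv_path}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    if list(df.columns) != list(meta["channel_names"]):
        raise ValueError(
            f"{csv_path}: CSV header {list(df.columns)} does not match "
            f"sidecar channel_names {meta['channel_names']}")
    data = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"{csv_path}: non-finite value at channel {bad[0]}, sample {bad[1]}")
    return Recording(data=data, fs=meta["fs"],
                     channel_names=list(meta["channel_names"]),
                     user_id=meta["user_id"], run_index=meta["run_index"],
                     event_times=meta.get("event_times"))


def write_dataset(recordings: list[Recording], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out_dir / f"user{rec.user_id:02d}_run{rec.run_index:02d}.csv")


def read_dataset(in_dir: str | Path) -> list[Recording]:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("user*_run*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recording CSVs found under {in_dir}")
    return [read_recording(p) for p in paths]


# ------------------------------------------------------------------ segments

def write_segments(segs: SegmentSet, path: str | Path) -> None:
    """Packed binary store (NPZ) with a JSON manifest alongside."""
    path = Path(path)
    np.savez(path, segments=segs.segments, labels=segs.labels,
             user_id=segs.origin_user_ids, run_index=segs.origin_run_indices,
             start_sample=segs.origin_starts)
    manifest = {
        "version": FORMAT_VERSION,
        "fs": segs.fs,
        "n_segments": int(segs.n_segments),
        "n_channels": int(segs.segments.shape[1]),
        "window": int(segs.segments.shape[2]),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, sort_keys=True))


def read_segments(path: str | Path) -> SegmentSet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        return SegmentSet(segments=z["segments"], labels=z["labels"],
                          fs=manifest["fs"], origin_user_ids=z["user_id"],
                          origin_run_indices=z["run_index"],
                          origin_starts=z["start_sample"])


# ------------------------------------------------------------------ features

def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    """TSV with "ch<i>_<band>" columns, a label column and origin columns."""
    df = pd.DataFrame(fm.values, columns=fm.columns)
    df["label"] = fm.labels
    if fm.origin is not None:
        for key, vals in fm.origin.items():
            df[key] = vals
    df.to_csv(path, sep="\t", index=False)


def _canonical_order(columns: list[str]) -> list[str]:
    def key(name: str):
        ch, band = name.split("_", 1)
        return (int(ch[2:]), BAND_NAMES.index(band))
    return sorted(columns, key=key)


def read_features(path: str | Path) -> FeatureMatrix:
    """Reads a feature TSV, restoring the canonical (channel, band) column
    order from the header regardless of on-disk order."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("label", "user_id", "run_index", "start_sample")
                 if c in df.columns]
    if "label" not in meta_cols:
        raise ValueError(f"{path}: feature TSV lacks a 'label' column")
    feat_cols = [c for c in df.columns if c not in meta_cols]
    ordered = _canonical_order(feat_cols)
    origin = None
    if {"user_id", "run_index", "start_sample"} <= set(meta_cols):
        origin = {k: df[k].to_numpy() for k in ("user_id", "run_index",
                                                "start_sample")}
    return FeatureMatrix(values=df[ordered].to_numpy(dtype=float),
                         columns=ordered, labels=df["label"].to_numpy(),
                         origin=origin)


# ----------------------------------------------------------------- selection

def write_selection(sel: SelectionResult, path: str | Path) -> None:
    payload = {
        "version": FORMAT_VERSION,
        "mi_scores": sel.mi_scores.tolist(),
        "selected_indices": [int(i) for i in sel.selected_indices],
        "q": sel.q,
        "n_bins": sel.n_bins,
        "columns": sel.columns,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_selection(path: str | Path) -> SelectionResult:
    d = json.loads(Path(path).read_text())
    return SelectionResult(mi_scores=np.asarray(d["mi_scores"]),
                           selected_indices=np.asarray(d["selected_indices"]),
                           q=d["q"], n_bins=d["n_bins"], columns=d["columns"])


# -------------------------------------------------------------------- models

def save_model(pm, model_dir: str | Path) -> None:
    """Model directory: JSON config/manifest + parameter blob + scaler and
    selection JSON (pm is a pipeline.PipelineModel)."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    tm = pm.model
    manifest = {
        "version": FORMAT_VERSION,
        "kind": tm.kind,
        "class_labels": [int(c) for c in tm.class_labels],
        "input_size": tm.input_size,
        "pipeline_config": pm.config.model_dump(),
        "provenance": pm.config.provenance(),
    }
    (model_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))
    write_selection(pm.selection, model_dir / "selection.json")
    scaler = {
        "mean": pm.scaler.mean.tolist(),
        "scale": pm.scaler.scale.tolist(),
        "constant_columns": pm.scaler.constant_columns.tolist(),
    }
    (model_dir / "scaler.json").write_text(json.dumps(scaler, sort_keys=True))
    if tm.kind == "ffnn":
        net: _Mlp = tm.parameters
        arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(net.biases)}
        arrays["dropout"] = np.asarray(net.dropout)
        np.savez(model_dir / "parameters.npz", **arrays)
    else:
        import pickle
        (model_dir / "parameters.pkl").write_bytes(pickle.dumps(tm.parameters))


def load_model(model_dir: str | Path):
    from .pipeline import PipelineConfig, PipelineModel

    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    config = PipelineConfig(**manifest["pipeline_config"])
    selection = read_selection(model_dir / "selection.json")
    sc = json.loads((model_dir / "scaler.json").read_text())
    scaler = ScalerStats(mean=np.asarray(sc["mean"]),
                         scale=np.asarray(sc["scale"]),
                         constant_columns=np.asarray(sc["constant_columns"]))
    kind = manifest["kind"]
    if kind == "ffnn":
        with np.load(model_dir / "parameters.npz") as z:
            n_layers = sum(1 for k in z.files if k.startswith("w"))
            weights = [z[f"w{i}"] for i in range(n_layers)]
            biases = [z[f"b{i}"] for i in range(n_layers)]
            dropout = float(z["dropout"])
        sizes = [weights[0].shape[0]] + [w.shape[1] for w in weights]
        net = _Mlp(sizes, seed=0, dropout=dropout)
        net.weights, net.biases = weights, biases
        params = net
    else:
        import pickle
        params = pickle.loads((model_dir / "parameters.pkl").read_bytes())
    tm = TrainedModel(kind=kind, config={}, parameters=params,
                      class_labels=np.asarray(manifest["class_labels"]),
                      input_size=manifest["input_size"])
    return PipelineModel(config=config, selection=selection, scaler=scaler,
                         model=tm)


# ----------------------------------------------------------- trials, reports

def write_trials(trials, path: str | Path, provenance: dict | None = None) -> None:
    """Decision table TSV: fold, claimed, true_user, run, Nseg, v, Nv, beta,
    theta, verdict (+ is_genuine ground truth)."""
    rows = [{
        "fold": t.fold, "claimed": t.claimed_label, "true_user": t.true_user,
        "run": t.run_index, "Nseg": int(t.decision.vote_counts.sum()),
        "v": t.decision.majority_label, "Nv": t.decision.majority_count,
        "beta": t.decision.beta, "theta": t.decision.theta,
        "verdict": t.decision.verdict, "is_genuine": t.is_genuine,
    } for t in trials]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if provenance is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps({"version": FORMAT_VERSION, **provenance}, sort_keys=True))


def write_report(report: dict, path: str | Path) -> None:
    clean = {k: v for k, v in report.items()
             if k not in ("pipeline_model", "trials")}
    Path(path).write_text(json.dumps(clean, sort_keys=True, indent=1))
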