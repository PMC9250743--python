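"""Exercise model fitting, end-to-end scoring, and model persistence.

The *modeling stage* learns everything from unsegmented normal repetitions:
per-sphere-channel rotations (AZEQ), the phase extractor, per-channel
standardization + PCA bottleneck, and per-phase-bin error scaling.  The
*detection stage* runs a session through extract -> smooth -> CDTW -> segment
-> warp -> reconstruct -> invert -> error -> scale, yielding per-sample
phase-fluctuation scores and scaled reconstruction errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import cdtw, phase as phase_mod, recon
from .cdtw import CircularTemplate, Segment, WarpingPath
from .features import (
    DEFAULT_SCHEMA,
    ChannelSchema,
    FeatureSequence,
    SphereProjection,
    fit_sphere_rotation,
    project_sequence,
)
from .phase import PhaseHyperparams, PhaseNetwork, PhaseSequence

__all__ = [
    "PipelineConfig",
    "ExerciseModel",
    "AnomalyReport",
    "fit_exercise_model",
    "run_pipeline",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, with the study defaults."""

    template_n: int = 50
    smooth_window: int = 7
    var_threshold: float = 0.95
    phase_extractor: str = "pca"  # "pca" (deterministic) or "network"
    phase: PhaseHyperparams = field(default_factory=PhaseHyperparams)
    hmm_states: int = 10
    hmm_mixtures: int = 5
    hmm_window: int = 30
    hmm_stride: int = 1
    hmm_max_iter: int = 25
    grid_size: int = 50

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phase" in d and isinstance(d["phase"], dict):
            ph = dict(d["phase"])
            if "hidden" in ph:
                ph["hidden"] = tuple(ph["hidden"])
            d["phase"] = PhaseHyperparams(**ph)
        return cls(**d)


@dataclass
class ExerciseModel:
    """Everything learned from normal training movements."""

    schema: ChannelSchema
    config: PipelineConfig
    projections: dict[str, SphereProjection]
    phase_net: PhaseNetwork
    channel_models: dict[str, recon.ChannelModel]
    version: int = MODEL_FORMAT_VERSION

    @property
    def template(self) -> CircularTemplate:
        return CircularTemplate(self.config.template_n)


@dataclass
class AnomalyReport:
    """Per-sample anomaly scores and segmentation for one session."""

    phase_score: np.ndarray  # (T,) circular distance raw phase vs ACMP
    recon_scores: np.ndarray  # (T, n_channels) scaled reconstruction errors
    segments: list[Segment]
    bins: np.ndarray  # (T,) phase bin per sample
    raw_phase: PhaseSequence
    smoothed_phase: PhaseSequence
    path: WarpingPath
    channel_names: list[str]

    @property
    def acmp(self) -> np.ndarray:
        return self.path.acmp

    def __len__(self):
        return self.phase_score.size


def _check_schema(seq: FeatureSequence, model: ExerciseModel):
    if seq.schema.names != model.schema.names:
        raise ValueError(
            "session schema does not match the model schema: "
            f"{seq.schema.names} vs {model.schema.names}"
        )


def _segment_periods_with_runs(flat, path, template_n, schema):
    """Warp every segment (partials included) onto standard slots."""
    segments = cdtw.segment_periods(path)
    flat_slices = schema.flat_slices()
    periods = []
    for seg in segments:
        if len(seg) < 2:
            periods.append(None)
            continue
        sl = slice(seg.start, seg.end)
        round_index = int(np.median(path.rounds[sl]))
        periods.append(
            recon.warp_to_standard(
                flat[sl],
                path.run_lo[sl],
                path.run_hi[sl],
                path.i_mid[sl],
                round_index,
                template_n,
                flat_slices,
                start=seg.start,
                partial=seg.partial,
            )
        )
    return segments, periods


def _phase_and_path(model: ExerciseModel, flat: np.ndarray):
    raw = phase_mod.extract_phase(model.phase_net, flat)
    smoothed = phase_mod.smooth_phase(raw, model.config.smooth_window)
    table = cdtw.build_table(smoothed.angles, model.template)
    path = cdtw.traceback(table)
    return raw, smoothed, path


def fit_exercise_model(
    training_sessions: list[FeatureSequence],
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> ExerciseModel:
    """Model the movement norm from unsegmented normal sessions."""
    if not training_sessions:
        raise ValueError("need at least one training session")
    schema = training_sessions[0].schema

    projections = {}
    for ch in schema.sphere_channels:
        dirs = np.concatenate([s.channel(ch.name) for s in training_sessions])
        projections[ch.name] = fit_sphere_rotation(dirs)

    flats = [project_sequence(s, projections) for s in training_sessions]

    if config.phase_extractor == "network":
        net = phase_mod.train_phase_network(flats, config.phase, seed)
    elif config.phase_extractor == "pca":
        net = phase_mod.train_fallback_extractor(flats, config.phase, seed)
    else:
        raise ValueError(f"unknown phase extractor {config.phase_extractor!r}")
    net = phase_mod.calibrate_direction(net, np.concatenate(flats, axis=0))

    model = ExerciseModel(schema, config, projections, net, {})

    # segment the training sessions and collect full periods per channel
    n = config.template_n
    per_channel: dict[str, list[np.ndarray]] = {c.name: [] for c in schema}
    kept: list[tuple[int, recon.StandardPeriod]] = []  # (session idx, period)
    for s_idx, flat in enumerate(flats):
        _, _, path = _phase_and_path(model, flat)
        _, periods = _segment_periods_with_runs(flat, path, n, schema)
        for p in periods:
            if p is None or p.partial:
                continue
            kept.append((s_idx, p))
            for ch in schema:
                per_channel[ch.name].append(p.flat(ch.name))
    if len(kept) < 2:
        raise ValueError("training data yielded fewer than 2 full periods")

    for ch in schema:
        X = np.stack(per_channel[ch.name])
        model.channel_models[ch.name] = recon.fit_channel_model(
            X, ch, n, config.var_threshold
        )

    # per-bin error scaling from the training periods themselves
    bins_acc: dict[str, list[np.ndarray]] = {c.name: [] for c in schema}
    errs_acc: dict[str, list[np.ndarray]] = {c.name: [] for c in schema}
    for s_idx, p in kept:
        seq = training_sessions[s_idx]
        for ch in schema:
            cm = model.channel_models[ch.name]
            z = cm.standardize(p.flat(ch.name))
            zr = recon.reconstruct(z, cm.U_r)
            inv = recon.invert_chain(zr, cm, p.bins, projections.get(ch.name))
            orig = seq.channel(ch.name)[p.start : p.end]
            err = recon.reconstruction_error(orig, inv, ch.kind)
            bins_acc[ch.name].append(p.bins)
            errs_acc[ch.name].append(err)
    for ch in schema:
        model.channel_models[ch.name].error_scale = recon.fit_error_scale(
            np.concatenate(errs_acc[ch.name]), np.concatenate(bins_acc[ch.name]), n
        )
    return model


def run_pipeline(session: FeatureSequence, model: ExerciseModel) -> AnomalyReport:
    """Score one session against a trained model (deterministic)."""
    _check_schema(session, model)
    flat = project_sequence(session, model.projections)
    raw, smoothed, path = _phase_and_path(model, flat)
    phase_score = cdtw.phase_anomaly_score(raw.angles, path.acmp)

    n = model.config.template_n
    segments, periods = _segment_periods_with_runs(flat, path, n, model.schema)
    T = len(session)
    names = model.schema.names
    scores = np.zeros((T, len(names)))
    bins = np.zeros(T, dtype=int)
    for p in periods:
        if p is None:
            continue
        bins[p.start : p.end] = p.bins
        for k, ch in enumerate(model.schema):
            cm = model.channel_models[ch.name]
            z = cm.standardize(p.flat(ch.name))
            zr = recon.reconstruct(z, cm.U_r)
            inv = recon.invert_chain(zr, cm, p.bins, model.projections.get(ch.name))
            orig = session.channel(ch.name)[p.start : p.end]
            err = recon.reconstruction_error(orig, inv, ch.kind)
            scores[p.start : p.end, k] = recon.scale_errors(err, p.bins, cm.error_scale)
    return AnomalyReport(
        phase_score, scores, segments, bins, raw, smoothed, path, names
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: ExerciseModel, directory) -> None:
    """Write a model bundle: JSON metadata + npz arrays."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    net = model.phase_net
    meta = {
        "format_version": model.version,
        "schema": model.schema.to_dict(),
        "config": model.config.to_dict(),
        "phase_net": {
            "kind": net.kind,
            "window_len": net.window_len,
            "flip": net.flip,
            "train_seed": net.train_seed,
        },
        "channels": {
            name: {"n_components": cm.n_components}
            for name, cm in model.channel_models.items()
        },
    }
    arrays: dict[str, np.ndarray] = {
        "phase_feat_mean": net.feat_mean,
        "phase_feat_sd": net.feat_sd,
    }
    for name, proj in model.projections.items():
        arrays[f"rot__{name}"] = proj.rotation
    if net.kind == "network":
        for i, (W, b) in enumerate(zip(net.mlp.W, net.mlp.b)):
            arrays[f"mlp_W{i}"] = W
            arrays[f"mlp_b{i}"] = b
        meta["phase_net"]["n_layers"] = len(net.mlp.W)
    else:
        arrays["pca_mean"] = net.pca_mean
        arrays["pca_proj"] = net.pca_proj
    for name, cm in model.channel_models.items():
        arrays[f"ch_mean__{name}"] = cm.mean
        arrays[f"ch_sd__{name}"] = cm.sd
        arrays[f"ch_Ur__{name}"] = cm.U_r
        arrays[f"ch_ratio__{name}"] = cm.explained_ratio
        arrays[f"ch_scale__{name}"] = cm.error_scale
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(d / "arrays.npz", **arrays)


def load_model(directory) -> ExerciseModel:
    from pathlib import Path

    d = Path(directory)
    try:
        meta = json.loads((d / "model.json").read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ValueError(f"cannot read model metadata: {e}") from e
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')} != {MODEL_FORMAT_VERSION}"
        )
    arrays = np.load(d / "arrays.npz")
    schema = ChannelSchema.from_dict(meta["schema"])
    config = PipelineConfig.from_dict(meta["config"])
    pm = meta["phase_net"]
    if pm["kind"] == "network":
        mlp = phase_mod._MLP.__new__(phase_mod._MLP)
        L = pm["n_layers"]
        mlp.W = [arrays[f"mlp_W{i}"] for i in range(L)]
        mlp.b = [arrays[f"mlp_b{i}"] for i in range(L)]
        net = PhaseNetwork(
            kind="network",
            window_len=pm["window_len"],
            feat_mean=arrays["phase_feat_mean"],
            feat_sd=arrays["phase_feat_sd"],
            flip=pm["flip"],
            mlp=mlp,
            hyperparams=config.phase,
            train_seed=pm["train_seed"],
        )
    else:
        net = PhaseNetwork(
            kind="pca",
            window_len=pm["window_len"],
            feat_mean=arrays["phase_feat_mean"],
            feat_sd=arrays["phase_feat_sd"],
            flip=pm["flip"],
            pca_mean=arrays["pca_mean"],
            pca_proj=arrays["pca_proj"],
            hyperparams=config.phase,
            train_seed=pm["train_seed"],
        )
    projections = {
        ch.name: SphereProjection(arrays[f"rot__{ch.name}"])
        for ch in schema.sphere_channels
    }
    channel_models = {}
    for ch in schema:
        channel_models[ch.name] = recon.ChannelModel(
            ch,
            arrays[f"ch_mean__{ch.name}"],
            arrays[f"ch_sd__{ch.name}"],
            arrays[f"ch_Ur__{ch.name}"],
            arrays[f"ch_ratio__{ch.name}"],
            config.template_n,
            config.var_threshold,
            arrays[f"ch_scale__{ch.name}"],
        )
    return ExerciseModel(schema, config, projections, net, channel_models)
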