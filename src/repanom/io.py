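"""CSV/JSON/YAML formats for sessions, schemas and configs.

A session is a CSV with one row per frame and one column per channel
dimension (sphere channels expand to ``name__x/y/z``), plus a JSON sidecar
(`<stem>.meta.json`) declaring the channel schema, frame rate and — for
simulated sessions — ground-truth phase and labeled anomaly events.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ChannelSchema, DEFAULT_SCHEMA, FeatureSequence
from .pipeline import PipelineConfig
from .simulate import LabeledSession

__all__ = [
    "read_feature_csv",
    "write_feature_csv",
    "write_session",
    "read_session",
    "read_config",
    "write_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_feature_csv(seq: FeatureSequence, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(seq.samples, columns=seq.schema.column_names())
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {"schema": seq.schema.to_dict(), "frame_rate": seq.frame_rate}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_feature_csv(path, schema: ChannelSchema | None = None) -> FeatureSequence:
    """Read a feature CSV (+ sidecar).  Sphere channels must be within 1e-3
    of unit norm (they are renormalized); rows with missing values are
    rejected with their indices."""
    path = Path(path)
    frame_rate = 30.0
    if schema is None:
        side = _sidecar(path)
        if side.exists():
            meta = json.loads(side.read_text())
            schema = ChannelSchema.from_dict(meta["schema"])
            frame_rate = float(meta.get("frame_rate", frame_rate))
        else:
            schema = DEFAULT_SCHEMA
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty feature file")
    expected = schema.column_names()
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: header mismatch; expected {expected}, found {list(df.columns)}"
        )
    values = df.to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: NaN/missing cells in rows {bad.tolist()}")
    return FeatureSequence(values, schema, frame_rate)


def write_session(session: LabeledSession, path) -> None:
    """Session CSV plus sidecar with ground truth (phase, events, subject)."""
    write_feature_csv(
        session.features,
        path,
        extra_meta={
            "subject_id": session.subject_id,
            "true_phase": np.round(session.true_phase, 6).tolist(),
            "anomaly_events": [[int(s), int(e), t] for s, e, t in session.anomaly_events],
        },
    )


def read_session(path) -> LabeledSession:
    path = Path(path)
    feats = read_feature_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    phase = np.asarray(meta.get("true_phase", []), dtype=float)
    events = [(int(s), int(e), t) for s, e, t in meta.get("anomaly_events", [])]
    unwrapped = np.unwrap(phase, period=2 * np.pi) if phase.size else phase
    return LabeledSession(feats, phase, unwrapped, events, meta.get("subject_id", "?"))


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
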