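"""Readers/writers for the session, attitude, and label CSV schemas and the
JSON model archive.

CSV files may start with ``#``-prefixed comment lines; the writers embed
the producing seed/config hash there so every artifact records its
provenance.  Floats are written with fixed precision so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .imu import ATTITUDE_COLUMNS, SESSION_COLUMNS
from .pnn import PNNClassifier, Standardizer
from .rpnn import RPNNClassifier

FORMAT_VERSION = "1"
_FLOAT_FMT = "%.6f"


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance_line(meta: dict | None) -> str:
    meta = dict(meta or {})
    meta.setdefault("format_version", FORMAT_VERSION)
    return "# smartbrush " + json.dumps(meta, sort_keys=True, default=str)


def _write_csv(df: pd.DataFrame, path, meta: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_line(meta) + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _read_csv(path, required: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed beyond repair
        raise FormatError(f"cannot parse {name} file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{name} file {path} is missing required column(s): {', '.join(missing)}"
        )
    return df


def write_session(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    cols = SESSION_COLUMNS + (["label"] if "label" in frame.columns else [])
    _write_csv(frame[cols], path, meta)


def read_session(path) -> pd.DataFrame:
    return _read_csv(path, SESSION_COLUMNS, "session")


def write_attitude(frames: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_csv(frames, path, meta)


def read_attitude(path) -> pd.DataFrame:
    return _read_csv(path, ATTITUDE_COLUMNS, "attitude")


def write_labels(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_csv(df, path, meta)


def read_labels(path) -> pd.DataFrame:
    return _read_csv(path, ["t", "region"], "labels")


def save_model(model: RPNNClassifier, path, meta: dict | None = None) -> None:
    """Serialize a fitted RPNN to a JSON archive (patterns, widths, priors,
    standardization statistics, memory hyperparameters, metadata)."""
    pnn = model.pnn_
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "rpnn",
        "delta": model.delta,
        "k": model.k,
        "normalize_state": model.normalize_state,
        "user_id": getattr(model, "user_id", None),
        "meta": dict(meta or {}),
        "pnn": {
            "classes": np.asarray(pnn.classes_).tolist(),
            "patterns": pnn.patterns_.tolist(),
            "pattern_labels": pnn.pattern_labels_.tolist(),
            "sigma": pnn.sigma_.tolist(),
            "sigma_scale": pnn.sigma_scale,
            "priors": pnn.priors_.tolist(),
            "priors_mode": pnn.priors,
            "mean": pnn.scaler_.mean_.tolist(),
            "scale": pnn.scaler_.scale_.tolist(),
            "zero_variance": pnn.scaler_.zero_variance_.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


def load_model(path) -> RPNNClassifier:
    try:
        payload = json.loads(Path(path).read_text())
    except Exception as exc:
        raise FormatError(f"cannot parse model archive {path}: {exc}") from exc
    if payload.get("kind") != "rpnn":
        raise FormatError(f"{path} is not an rpnn model archive")
    p = payload["pnn"]
    pnn = PNNClassifier(priors=p.get("priors_mode", "frequency"))
    pnn.classes_ = np.asarray(p["classes"])
    pnn.patterns_ = np.asarray(p["patterns"], dtype=float)
    pnn.pattern_labels_ = np.asarray(p["pattern_labels"], dtype=int)
    pnn.sigma_ = np.asarray(p["sigma"], dtype=float)
    pnn.sigma_scale = float(p["sigma_scale"])
    pnn.priors_ = np.asarray(p["priors"], dtype=float)
    pnn.class_counts_ = np.bincount(pnn.pattern_labels_, minlength=len(pnn.classes_))
    scaler = Standardizer()
    scaler.mean_ = np.asarray(p["mean"], dtype=float)
    scaler.scale_ = np.asarray(p["scale"], dtype=float)
    scaler.zero_variance_ = np.asarray(p["zero_variance"], dtype=bool)
    pnn.scaler_ = scaler
    model = RPNNClassifier(
        delta=payload["delta"], k=payload["k"],
        normalize_state=payload.get("normalize_state", False),
    )
    model.pnn_ = pnn
    model.classes_ = pnn.classes_
    model.user_id = payload.get("user_id")
    return model


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
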