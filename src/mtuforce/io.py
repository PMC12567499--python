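"""Reading and writing recordings, models and reports (CSV + JSON only)."""
from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .bp import MlpParams
from .grid import ElectrodeGrid
from .preprocessing import SemgRecording

MODEL_FORMAT_VERSION = 1
RECORDING_FORMAT_VERSION = 1


def write_recording(
    recording: SemgRecording, csv_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write channels (and optional force) as CSV plus a JSON geometry sidecar.

    CSV columns are ``ch00, ch01, ...`` in row-major grid order, with a final
    ``force`` column when present; the sidecar records the sampling rate and
    grid geometry needed to reconstruct the recording.
    """
    n_ch = recording.n_channels
    cols = {f"ch{c:02d}": recording.samples[c] for c in range(n_ch)}
    if recording.force is not None:
        cols["force"] = recording.force
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {
        "format_version": RECORDING_FORMAT_VERSION,
        "fs_hz": recording.fs_hz,
        "grid": {
            "rows": recording.grid.rows,
            "cols": recording.grid.cols,
            "pitch_mm": recording.grid.pitch_mm,
        },
        "posture": recording.posture,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_recording(csv_path: str | Path, sidecar_path: str | Path) -> SemgRecording:
    """Read a recording written by :func:`write_recording`."""
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar JSON {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    grid = ElectrodeGrid(
        rows=meta["grid"]["rows"],
        cols=meta["grid"]["cols"],
        pitch_mm=meta["grid"]["pitch_mm"],
    )
    df = pd.read_csv(csv_path)
    if df.isna().any().any():
        raise ValueError(f"{csv_path} contains NaN cells")
    channel_cols = [c for c in df.columns if c.startswith("ch")]
    if len(channel_cols) != grid.n_electrodes:
        raise ValueError(
            f"CSV has {len(channel_cols)} channel columns but the grid sidecar "
            f"declares {grid.n_electrodes} electrodes"
        )
    force = df["force"].to_numpy() if "force" in df.columns else None
    return SemgRecording(
        samples=df[channel_cols].to_numpy().T,
        fs_hz=float(meta["fs_hz"]),
        grid=grid,
        force=force,
        posture=meta.get("posture"),
    )


def save_model(params: MlpParams, path: str | Path) -> None:
    """Serialize an MLP to JSON (exact float round trip via repr precision)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "layer_sizes": list(params.layer_sizes),
        "hidden_activation": params.hidden_activation,
        "output_activation": params.output_activation,
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> MlpParams:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return MlpParams(
        layer_sizes=list(doc["layer_sizes"]),
        weights=[np.asarray(w, float) for w in doc["weights"]],
        biases=[np.asarray(b, float) for b in doc["biases"]],
        hidden_activation=doc["hidden_activation"],
        output_activation=doc["output_activation"],
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")
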