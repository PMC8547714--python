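"""CSV and config file formats shared by all pipeline stages.

All tabular interchange is plain UTF-8 comma-delimited CSV with a
mandatory header ('.' decimal separator):

* stress traces:      ``time_s, stress_pa``
* dispersion curves:  ``frequency_hz, speed_m_per_s``
* waveform pairs:     ``time_s, v1, v2``  (+ sidecar with
  ``sampling_rate_hz`` and ``dx_m``)

Every writer can attach a JSON sidecar (``<file>.meta.json``) recording
the configuration and seed that produced the file, so any output can be
traced back to its generator settings.  Configs are flat key-value
files parsed with YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .dispersion import DispersionCurve, WaveformPair
from .fitting import StressTrace

__all__ = [
    "MissingColumnsError",
    "NonNumericDataError",
    "read_stress_trace",
    "write_stress_trace",
    "read_dispersion_curve",
    "write_dispersion_curve",
    "read_waveform_pair",
    "write_waveform_pair",
    "read_config",
    "write_record",
    "sidecar_path",
]


class MissingColumnsError(ValueError):
    """The CSV lacks one or more mandatory columns."""


class NonNumericDataError(ValueError):
    """A mandatory column contains cells that cannot be parsed as numbers."""


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def _load_columns(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise MissingColumnsError(
            f"{path}: missing mandatory column(s) {missing}; found {list(frame.columns)}"
        )
    out = {}
    for col in required:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.argmax((bad | frame[col].isna()).to_numpy()))
            raise NonNumericDataError(
                f"{path}: column {col!r} has a non-numeric or empty cell at data row {row}"
            )
        out[col] = values.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_sidecar(path: str | Path, metadata: Any | None) -> None:
    if metadata is None:
        return
    sidecar_path(path).write_text(
        json.dumps(_jsonable(metadata), indent=2, sort_keys=True) + "\n"
    )


def read_stress_trace(path: str | Path) -> StressTrace:
    """Read and validate a ``time_s, stress_pa`` CSV as a stress trace."""
    frame = _load_columns(path, ("time_s", "stress_pa"))
    return StressTrace(frame["time_s"].to_numpy(), frame["stress_pa"].to_numpy())


def write_stress_trace(
    path: str | Path, trace: StressTrace, metadata: Any | None = None
) -> None:
    pd.DataFrame({"time_s": trace.times, "stress_pa": trace.stresses}).to_csv(
        path, index=False
    )
    _write_sidecar(path, metadata)


def read_dispersion_curve(path: str | Path) -> DispersionCurve:
    """Read a ``frequency_hz, speed_m_per_s`` CSV as a dispersion curve."""
    frame = _load_columns(path, ("frequency_hz", "speed_m_per_s"))
    condition = None
    meta = sidecar_path(path)
    if meta.exists():
        condition = json.loads(meta.read_text()).get("condition")
    return DispersionCurve(
        frame["frequency_hz"].to_numpy(),
        frame["speed_m_per_s"].to_numpy(),
        condition,
    )


def write_dispersion_curve(
    path: str | Path, curve: DispersionCurve, metadata: Any | None = None
) -> None:
    pd.DataFrame(
        {"frequency_hz": curve.frequencies, "speed_m_per_s": curve.speeds}
    ).to_csv(path, index=False)
    if metadata is None and curve.condition is not None:
        metadata = {"condition": curve.condition}
    elif isinstance(metadata, dict) and curve.condition is not None:
        metadata = {"condition": curve.condition, **metadata}
    _write_sidecar(path, metadata)


def read_waveform_pair(path: str | Path) -> WaveformPair:
    """Read a ``time_s, v1, v2`` CSV; the mandatory JSON sidecar supplies
    ``sampling_rate_hz`` and ``dx_m``."""
    frame = _load_columns(path, ("time_s", "v1", "v2"))
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(
            f"{path}: waveform pairs need a sidecar {meta_file} with "
            "sampling_rate_hz and dx_m"
        )
    meta = json.loads(meta_file.read_text())
    for key in ("sampling_rate_hz", "dx_m"):
        if key not in meta:
            raise MissingColumnsError(f"{meta_file}: missing sidecar key {key!r}")
    return WaveformPair(
        frame["v1"].to_numpy(),
        frame["v2"].to_numpy(),
        float(meta["sampling_rate_hz"]),
        float(meta["dx_m"]),
    )


def write_waveform_pair(
    path: str | Path, pair: WaveformPair, metadata: Any | None = None
) -> None:
    times = np.arange(len(pair)) / pair.sampling_rate
    pd.DataFrame({"time_s": times, "v1": pair.v1, "v2": pair.v2}).to_csv(
        path, index=False
    )
    meta = {"sampling_rate_hz": pair.sampling_rate, "dx_m": pair.dx}
    if isinstance(metadata, dict):
        meta.update(_jsonable(metadata))
    elif metadata is not None:
        meta["config"] = _jsonable(metadata)
    _write_sidecar(path, meta)


def read_config(path: str | Path) -> dict[str, Any]:
    """Parse a flat key-value config file (YAML syntax)."""
    loaded = yaml.safe_load(Path(path).read_text())
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return loaded


def write_record(path: str | Path, record: Mapping[str, Any]) -> None:
    """Serialize a result record as sorted, indented JSON (deterministic
    bytes for identical content)."""
    Path(path).write_text(
        json.dumps(_jsonable(record), indent=2, sort_keys=True) + "\n"
    )
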