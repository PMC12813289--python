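"""File formats, configuration and provenance.

Stacks travel as multi-page grayscale TIFF with a TOML sidecar carrying the
frame rate; fps is mandatory metadata and is never guessed — a wrong frame
rate silently rescales every pumping rate, so a missing one is an error.
Traces, cohorts, labels and group tables are CSV; results are JSON with
fixed 6-significant-digit formatting so identical runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .pumping import ImageStack, IntensityTrace, MeasurementSet

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "UnsupportedFormatError",
    "MissingMetadataError",
    "RunConfig",
    "ProvenanceRecord",
    "read_stack",
    "write_stack",
    "read_trace_csv",
    "write_trace_csv",
    "read_groups_csv",
    "write_json",
    "toml_dumps",
]


class UnsupportedFormatError(ValueError):
    pass


class MissingMetadataError(ValueError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".toml")


def toml_dumps(doc: dict) -> str:
    """Minimal TOML writer for flat sections of scalars/lists."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return json.dumps(str(v))

    lines = []
    scalars = {k: v for k, v in doc.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in doc.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {fmt(v)}")
    for name, table in tables.items():
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in table.items():
            if isinstance(v, dict):  # one nesting level (e.g. presets.WT)
                lines.append(f"[{name}.{k}]")
                for kk, vv in v.items():
                    lines.append(f"{kk} = {fmt(vv)}")
            else:
                lines.append(f"{k} = {fmt(v)}")
    return "\n".join(lines) + "\n"


def write_stack(path, stack: ImageStack) -> None:
    """Write a multi-page grayscale TIFF plus a ``.tif.toml`` fps sidecar."""
    path = Path(path)
    frames = stack.frames
    if frames.max() <= 255 and np.allclose(frames, np.round(frames)):
        data = frames.astype(np.uint8)
    else:
        data = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"stack": {"fps": float(stack.fps)}}
    if stack.pixel_size_um is not None:
        meta["stack"]["pixel_size_um"] = float(stack.pixel_size_um)
    _sidecar(path).write_text(toml_dumps(meta))


def read_stack(path, fps_override: float | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF; fps from sidecar TOML or override."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            if page.samplesperpixel != 1:
                raise UnsupportedFormatError(
                    f"{path.name}: RGB/multichannel TIFF is not supported"
                )
            arr = tf.asarray()
    except UnsupportedFormatError:
        raise
    except Exception as exc:
        raise UnsupportedFormatError(f"{path.name}: not a readable TIFF ({exc})")
    if arr.ndim == 2:
        arr = arr[None, :, :]
    fps = fps_override
    pixel_size = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar, "rb") as fh:
            meta = tomllib.load(fh).get("stack", {})
        if fps is None:
            fps = meta.get("fps")
        pixel_size = meta.get("pixel_size_um")
    if fps is None:
        raise MissingMetadataError(
            f"{path.name}: no fps in sidecar and no --fps override; "
            "a frame rate is required to compute rates"
        )
    return ImageStack(frames=arr.astype(float), fps=float(fps),
                      pixel_size_um=pixel_size)


def write_trace_csv(path, trace: IntensityTrace) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(len(trace)), "intensity": trace.values}
    )
    df.to_csv(path, index=False, float_format="%.6g")
    Path(path).with_suffix(".csv.toml").write_text(
        toml_dumps({"trace": {"fps": float(trace.fps)}})
    )


def read_trace_csv(path, fps_override: float | None = None) -> IntensityTrace:
    df = pd.read_csv(path)
    fps = fps_override
    sidecar = Path(path).with_suffix(".csv.toml")
    if fps is None and sidecar.exists():
        with open(sidecar, "rb") as fh:
            fps = tomllib.load(fh).get("trace", {}).get("fps")
    if fps is None:
        raise MissingMetadataError(f"{Path(path).name}: fps metadata missing")
    return IntensityTrace(values=df["intensity"].to_numpy(float), fps=float(fps))


def read_groups_csv(path) -> dict[str, np.ndarray]:
    """Long-format (group, value) or wide CSV -> label -> values."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "group" in cols and "value" in cols:
        df.columns = cols
        return {
            str(g): sub["value"].to_numpy(float)
            for g, sub in df.groupby("group", sort=False)
        }
    return {str(c): df[c].dropna().to_numpy(float) for c in df.columns}


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(path, payload: dict) -> None:
    """JSON with floats at 6 significant digits for reproducible diffs."""
    Path(path).write_text(json.dumps(_round_floats(payload), indent=2) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline defaults; acquisition constants default to 5 frames/s."""

    fps: float = 5.0
    pixel_size_um: float | None = None
    prominence_fraction: float = 0.15
    min_separation_s: float = 2.0
    smooth_s: float = 1.0
    detrend_window_s: float = 0.0
    vesselness_scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh).get("run", {})
        kwargs = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        if "vesselness_scales" in kwargs:
            kwargs["vesselness_scales"] = tuple(kwargs["vesselness_scales"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ProvenanceRecord:
    tool_version: str
    config_hash: str
    input_digests: dict
    timestamp: str

    @classmethod
    def create(cls, config: RunConfig, inputs: dict | None = None):
        digests = {}
        for name, p in (inputs or {}).items():
            digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        from . import __version__

        return cls(
            tool_version=__version__,
            config_hash=config.config_hash(),
            input_digests=digests,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def as_dict(self) -> dict:
        return asdict(self)


def measurement_set_to_frame(ms: MeasurementSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "side": m.side,
                "day": m.day,
                "troughs": m.result.n_troughs,
                "frames": m.result.n_frames,
                "fps": m.result.fps,
                "rate": m.result.rate,
            }
            for m in ms.entries
        ]
    )
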