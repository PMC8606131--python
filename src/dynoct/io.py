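"""File formats and run configuration.

Stacks and volumes travel as TIFF + JSON sidecar pairs.  The sidecar is
authoritative for everything the pixels cannot carry: axis order
("YTZX" for stacks, "YZX" for volumes), the inter-frame separation
``dt_ms``, pixel pitches (µm) and units.  A stack TIFF holds one page
per frame, location-major then repeat; volumes are 32-bit float, one
page per slow-axis location.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from pydantic import BaseModel, Field

from .dynamics import DEFAULT_FIT_HI_MS, DEFAULT_FIT_LO_MS, Kernel
from .phantom import PhantomSpec
from .protocol import ScanProtocol
from .quantify import (
    DEFAULT_LIV_CUTOFF_DB2,
    DEFAULT_OCDS_CUTOFF_MS_INV,
    SpheroidQuant,
)
from .stack import DynamicsVolume, TimeSeriesStack

STACK_AXES = "YTZX"
VOLUME_AXES = "YZX"


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json") if p.suffix != ".json" else p


def _require(meta: dict[str, Any], key: str, path: Path) -> Any:
    if key not in meta:
        raise KeyError(f"sidecar {path} is missing required field {key!r}")
    return meta[key]


def write_stack(stack: TimeSeriesStack, path: str | Path,
                sidecar: str | Path | None = None) -> Path:
    """Write a stack as float32 TIFF pages (location-major, then repeat) + sidecar."""
    path = Path(path)
    ny, nt, nz, nx = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(ny * nt, nz, nx).astype(np.float32),
                     photometric="minisblack")
    side = _sidecar_path(sidecar or path)
    side.write_text(json.dumps({
        "axes": STACK_AXES,
        "shape": list(stack.data.shape),
        "dt_ms": stack.dt_ms,
        "n_repeats": nt,
        "x_pitch_um": stack.x_pitch_um,
        "y_pitch_um": stack.y_pitch_um,
        "z_pitch_um": stack.z_pitch_um,
        "units": {"intensity": "dB", "time": "ms", "space": "um"},
    }, indent=2))
    return side


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> TimeSeriesStack:
    path = Path(path)
    side = _sidecar_path(sidecar or path)
    meta = json.loads(side.read_text())
    shape = tuple(_require(meta, "shape", side))
    dt_ms = _require(meta, "dt_ms", side)
    pages = tifffile.imread(path)
    data = np.asarray(pages, dtype=np.float64).reshape(shape)
    return TimeSeriesStack(
        data=data,
        dt_ms=float(dt_ms),
        x_pitch_um=float(_require(meta, "x_pitch_um", side)),
        y_pitch_um=float(_require(meta, "y_pitch_um", side)),
        z_pitch_um=float(_require(meta, "z_pitch_um", side)),
    )


def write_volume(vol: DynamicsVolume, path: str | Path,
                 *, parameters: dict[str, Any] | None = None) -> Path:
    """Write a dynamics volume as float32 TIFF + sidecar; the co-registered
    mean intensity goes to ``<stem>_mean<suffix>``."""
    path = Path(path)
    tifffile.imwrite(path, vol.values.astype(np.float32), photometric="minisblack")
    mean_path = path.with_name(path.stem + "_mean" + path.suffix)
    tifffile.imwrite(mean_path, vol.mean_intensity_db.astype(np.float32),
                     photometric="minisblack")
    side = _sidecar_path(path)
    side.write_text(json.dumps({
        "axes": VOLUME_AXES,
        "shape": list(vol.values.shape),
        "metric": vol.metric,
        "units": vol.units,
        "x_pitch_um": vol.x_pitch_um,
        "y_pitch_um": vol.y_pitch_um,
        "z_pitch_um": vol.z_pitch_um,
        "mean_intensity_file": mean_path.name,
        "parameters": parameters or {},
    }, indent=2))
    return side


def read_volume(path: str | Path) -> DynamicsVolume:
    path = Path(path)
    side = _sidecar_path(path)
    meta = json.loads(side.read_text())
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    mean_file = path.with_name(_require(meta, "mean_intensity_file", side))
    mean = np.asarray(tifffile.imread(mean_file), dtype=np.float64)
    return DynamicsVolume(
        values=values.reshape(tuple(_require(meta, "shape", side))),
        metric=_require(meta, "metric", side),
        mean_intensity_db=mean.reshape(values.shape),
        x_pitch_um=float(_require(meta, "x_pitch_um", side)),
        y_pitch_um=float(_require(meta, "y_pitch_um", side)),
        z_pitch_um=float(_require(meta, "z_pitch_um", side)),
    )


def write_report(quant: SpheroidQuant, json_path: str | Path,
                 csv_path: str | Path | None = None,
                 *, label: str = "spheroid") -> None:
    """Quantification report as JSON and optionally one-row CSV."""
    record = {"label": label, **quant.to_dict()}
    Path(json_path).write_text(json.dumps(record, indent=2))
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(record))
            w.writeheader()
            w.writerow(record)


class RunConfig(BaseModel):
    """Fully-resolved configuration of one pipeline run."""

    protocol: ScanProtocol = ScanProtocol()
    phantom: PhantomSpec | None = None
    kernel: Kernel = Kernel()
    fit_lo_ms: float = DEFAULT_FIT_LO_MS
    fit_hi_ms: float = DEFAULT_FIT_HI_MS
    liv_cutoff_db2: float = DEFAULT_LIV_CUTOFF_DB2
    ocds_cutoff_ms_inv: float = DEFAULT_OCDS_CUTOFF_MS_INV
    intensity_threshold_db: float | None = None
    acf_method: str = "fft"
    rng_seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """RunConfig from a JSON or TOML file, validated before any computation."""
    p = Path(path)
    if p.suffix == ".toml":
        import tomllib
        data = tomllib.loads(p.read_text())
    else:
        data = json.loads(p.read_text())
    return RunConfig.model_validate(data)
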