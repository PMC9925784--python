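"""Disk formats: multi-page TIFF volumes with JSON sidecars, CSV tables,
and reproducibility manifests.

Volumes are written page-by-page along the depth (z) axis in ``(z, y, x)``
page order — the multi-page TIFF convention — while in memory they are
``(x, y, z)``.  Every volume gets a ``<name>.json`` sidecar recording voxel
pitch, origin, axis order and (for 16-bit writes) the linear scale/offset;
metadata never travels in pixel units.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .volumes import DeskewedVolume, IntensityVolume

SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def save_volume(path, volume, bitdepth: int | None = None) -> Path:
    """Write a volume as multi-page TIFF plus JSON sidecar.

    ``bitdepth=16`` rescales linearly onto [0, 65535] and records the
    scale/offset in the sidecar so the data round-trips to physical units;
    integer label volumes and float data are otherwise written verbatim.
    """
    path = Path(path)
    if isinstance(volume, IntensityVolume):
        values, pitch, origin, background = (
            volume.values, volume.voxel_pitch, volume.origin, volume.background,
        )
        kind = "intensity"
    elif isinstance(volume, DeskewedVolume):
        values, pitch, origin, background = (
            volume.values, volume.spacing, volume.origin, volume.background,
        )
        kind = "deskewed"
    else:
        raise DataError(f"cannot save object of type {type(volume).__name__}")

    meta = {
        "kind": kind,
        "voxel_pitch_um": list(pitch),
        "origin_um": list(np.asarray(origin, dtype=float)),
        "axis_order": "xyz",
        "page_order": "zyx",
        "background": float(background),
    }
    if bitdepth == 16:
        vmin = float(values.min()) if values.size else 0.0
        vmax = float(values.max()) if values.size else 1.0
        scale = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
        data = np.round((values - vmin) / scale).astype(np.uint16)
        meta["scale"] = scale
        meta["offset"] = vmin
        meta["dtype"] = "uint16"
    elif bitdepth is None:
        data = values
        meta["dtype"] = str(values.dtype)
    else:
        raise DataError(f"unsupported bitdepth {bitdepth!r} (use None or 16)")

    tifffile.imwrite(path, np.transpose(data, (2, 1, 0)), photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path, voxel_pitch_um=None):
    """Read a TIFF volume, recovering physical units from the sidecar.

    Without a sidecar the voxel pitch must be passed explicitly — units are
    never guessed.  Truncated or unreadable files raise a parse error naming
    the failing page.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif voxel_pitch_um is not None:
        meta = {
            "kind": "intensity",
            "voxel_pitch_um": list(np.atleast_1d(voxel_pitch_um).astype(float)),
            "origin_um": [0.0, 0.0, 0.0],
            "background": 0.0,
        }
    else:
        raise DataError(
            f"{path}: no metadata sidecar and no voxel pitch given; refusing to "
            "guess units"
        )

    try:
        with tifffile.TiffFile(path) as tif:
            try:
                data = tif.asarray()
            except Exception as whole_exc:
                # identify the failing page for a precise error message
                for p_idx, page in enumerate(tif.pages):
                    try:
                        page.asarray()
                    except Exception as exc:
                        raise DataError(
                            f"{path}: failed to read page {p_idx}: {exc}"
                        ) from exc
                raise DataError(f"{path}: unreadable TIFF: {whole_exc}") from whole_exc
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"{path}: unreadable TIFF: {exc}") from exc

    if data.ndim != 3:
        raise DataError(f"{path}: expected a 3D volume, got shape {data.shape}")
    values = np.transpose(data, (2, 1, 0))
    if meta.get("dtype") == "uint16" and "scale" in meta:
        values = values.astype(np.float32) * meta["scale"] + meta["offset"]

    pitch = meta["voxel_pitch_um"]
    pitch = tuple(pitch) if len(pitch) == 3 else float(pitch[0])
    origin = np.asarray(meta.get("origin_um", [0.0, 0.0, 0.0]), dtype=float)
    if meta.get("kind") == "deskewed":
        return DeskewedVolume(
            values=values, spacing=pitch, origin=origin,
            background=meta.get("background", 0.0),
        )
    if np.issubdtype(values.dtype, np.integer) and meta.get("kind") == "labels":
        return values, pitch, origin
    return IntensityVolume(
        values=values, voxel_pitch=pitch, origin=origin,
        background=meta.get("background", 0.0),
    )


def save_labels(path, labels: np.ndarray, voxel_pitch_um, layer_names, origin=(0, 0, 0)) -> Path:
    """Write an integer layer-label volume with its name table."""
    path = Path(path)
    tifffile.imwrite(
        path, np.transpose(np.asarray(labels), (2, 1, 0)), photometric="minisblack"
    )
    meta = {
        "kind": "labels",
        "voxel_pitch_um": list(np.repeat(float(voxel_pitch_um), 3)),
        "origin_um": list(np.asarray(origin, dtype=float)),
        "layer_names": list(layer_names),
        "axis_order": "xyz",
        "page_order": "zyx",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_labels(path):
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
    return (
        np.transpose(data, (2, 1, 0)),
        float(meta["voxel_pitch_um"][0]),
        tuple(meta["layer_names"]),
    )


def save_cells_csv(path, cells: pd.DataFrame) -> Path:
    path = Path(path)
    cells.to_csv(path, index=False)
    return path


def save_manifest(path, config: dict, seeds: dict) -> Path:
    """Record the run configuration hash and seeds for reproducibility."""
    path = Path(path)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds,
    }
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
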