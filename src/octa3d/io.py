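"""Volume I/O: multi-page TIFF and NIfTI with a JSON metadata sidecar.

TIFF stores one page per axial (Z) slice as 32-bit float; voxel size,
axis labels and an optional provenance hash travel in ``<file>.meta.json``.
NIfTI keeps the voxel size in the header zooms (stored in mm) and also
gets a sidecar for the axis labels.  Round-trips are lossless for
float32 data.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .volume import AXES, Volume3D, as_array

__all__ = ["read_volume", "write_volume"]

_NIFTI_EXT = (".nii", ".nii.gz")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_volume(volume, path, voxel_size_um=None, meta: dict | None = None) -> Path:
    """Write a volume as multi-page float32 TIFF or NIfTI (by extension)."""
    path = Path(path)
    if isinstance(volume, Volume3D):
        data = volume.data
        voxel = voxel_size_um or volume.voxel_size_um
        extra = {**volume.meta, **(meta or {})}
    else:
        data = np.asarray(volume)
        voxel = voxel_size_um or (5.0, 10.0, 10.0)
        extra = dict(meta or {})
    if data.ndim != 3:
        raise ValueError("can only write 3D volumes")

    name = path.name.lower()
    if name.endswith(_NIFTI_EXT):
        affine = np.diag([v / 1000.0 for v in voxel] + [1.0])  # um -> mm
        img = nib.Nifti1Image(np.asarray(data, np.float32), affine)
        img.header.set_zooms(tuple(v / 1000.0 for v in voxel))
        nib.save(img, str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.asarray(data, np.float32))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    sidecar = {"axes": AXES, "voxel_size_um": list(voxel), **extra}
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path) -> Volume3D:
    """Read a TIFF or NIfTI volume; validates shape and sidecar axis labels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    try:
        if name.endswith(_NIFTI_EXT):
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, np.float32)
            voxel = tuple(float(z) * 1000.0 for z in img.header.get_zooms()[:3])
        elif name.endswith((".tif", ".tiff")):
            data = tifffile.imread(path)
            voxel = None
        else:
            raise ValueError(f"unsupported volume format: {path.name}")
    except ValueError as exc:
        if "unsupported volume format" in str(exc):
            raise
        raise OSError(f"failed to read volume {path}: {exc}") from exc
    except Exception as exc:  # corrupt/truncated files -> explicit I/O error
        raise OSError(f"failed to read volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise OSError(f"{path} does not hold a 3D volume (ndim={data.ndim})")

    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        axes = meta.get("axes", AXES)
        if axes != AXES:
            raise OSError(f"{path}: sidecar axis order {axes!r} != {AXES!r}; "
                          "refusing to silently swap axes")
        if voxel is None and "voxel_size_um" in meta:
            voxel = tuple(meta["voxel_size_um"])
    if voxel is None:
        voxel = (5.0, 10.0, 10.0)
    return Volume3D(data=data, voxel_size_um=tuple(voxel),
                    meta={k: v for k, v in meta.items()
                          if k not in ("axes", "voxel_size_um")})
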