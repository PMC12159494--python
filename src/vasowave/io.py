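"""Movie, atlas and table I/O.

Movies travel as multi-page TIFF (one page per frame, 32-bit float)
with a sidecar JSON carrying the acquisition metadata, or as NIfTI-1
volumes with ``(x, y, t)`` axis order where the frame period is stored
in the header (``pixdim[3]``) so no sidecar is needed.  Atlases are
integer TIFF/NIfTI plus a JSON name/hemisphere table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile

from .core import AcquisitionSpec, Movie
from .atlas import RoiAtlas

__all__ = [
    "read_movie",
    "write_movie",
    "read_atlas",
    "write_atlas",
    "read_config",
    "write_config",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path: str | Path, seed: int | None = None) -> None:
    """Write a movie as multi-page TIFF (frame per page) or NIfTI-1.

    The format is chosen from the extension (.tif/.tiff vs
    .nii/.nii.gz).  TIFF gets a sidecar JSON with ``dt_s`` and
    ``pixel_mm``; NIfTI stores them in the header.  ``seed`` is logged
    in the sidecar / header description when given.
    """
    path = Path(path)
    spec = movie.spec
    if path.suffix.lower() in (".tif", ".tiff"):
        # pages are frames: (t, row, col)
        tifffile.imwrite(path, np.moveaxis(movie.data.astype(np.float32), 2, 0))
        meta = {"dt_s": spec.dt, "pixel_mm": spec.pixel_mm}
        if seed is not None:
            meta["seed"] = seed
        _sidecar_path(path).write_text(json.dumps(meta))
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        # x, y, t axis order
        img = nib.Nifti1Image(movie.data.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((spec.pixel_mm, spec.pixel_mm, spec.dt))
        img.header["xyzt_units"] = 2 | 8  # mm, sec
        if seed is not None:
            img.header["descrip"] = f"seed={seed}".encode()
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported movie format: {path.suffix!r}")


def read_movie(path: str | Path) -> Movie:
    """Read a movie written by :func:`write_movie` (TIFF or NIfTI)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) != 1:
                raise ValueError(f"TIFF has ragged pages: shapes {sorted(shapes)}")
            data = tf.asarray()
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D stack, got shape {data.shape}")
        data = np.moveaxis(data, 0, 2)
        sidecar = _sidecar_path(path)
        dt, pixel_mm = 0.4, 0.1
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            dt = float(meta.get("dt_s", dt))
            pixel_mm = float(meta.get("pixel_mm", pixel_mm))
        spec = AcquisitionSpec(data.shape[0], data.shape[1], data.shape[2], dt, pixel_mm)
        return Movie(np.ascontiguousarray(data, dtype=np.float32), spec)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D NIfTI, got shape {data.shape}")
        zooms = img.header.get_zooms()
        spec = AcquisitionSpec(
            data.shape[0], data.shape[1], data.shape[2],
            dt=float(zooms[2]), pixel_mm=float(zooms[0]),
        )
        return Movie(data, spec)
    raise ValueError(f"unsupported movie format: {path.suffix!r}")


def write_atlas(atlas: RoiAtlas, path: str | Path) -> None:
    """Integer label TIFF/NIfTI plus a JSON id→name/hemisphere table."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, atlas.labels.astype(np.int32))
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported atlas format: {path.suffix!r}")
    table = {
        str(i): {"name": atlas.names[i], "hemisphere": atlas.hemisphere[i]}
        for i in atlas.all_ids()
    }
    _sidecar_path(path).write_text(json.dumps(table, indent=1))


def read_atlas(path: str | Path) -> RoiAtlas:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path).astype(np.int32)
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    else:
        raise ValueError(f"unsupported atlas format: {path.suffix!r}")
    table = json.loads(_sidecar_path(path).read_text())
    names = {int(k): v["name"] for k, v in table.items()}
    hemisphere = {int(k): v["hemisphere"] for k, v in table.items()}
    return RoiAtlas(labels, names, hemisphere)


def write_config(config: dict, path: str | Path) -> None:
    """Flat ``key = value`` text config; sections via dotted keys."""
    lines = [f"{k} = {v}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict:
    config: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = line.split("=", 1)
        config[k.strip()] = v.strip()
    return config
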