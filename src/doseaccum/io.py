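"""Reading and writing volumes, masks and doses.

Two on-disk formats are supported: MetaImage (``.mha``/``.mhd``+``.raw``,
uncompressed) and NIfTI-1 (``.nii``/``.nii.gz``, via nibabel).  Only 3D
axis-aligned grids are accepted; oblique direction matrices are rejected
rather than silently resampled.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    DoseFrame,
    DoseGrid,
    GridGeometry,
    GridObject,
    ImageVolume,
    Modality,
    StructureMask,
)


class FormatError(ValueError):
    """File is missing, malformed, or not a supported 3D volume."""


_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {v: k for k, v in _MET_TYPES.items()}


def _read_metaimage(path: Path) -> tuple[GridGeometry, np.ndarray]:
    header: dict[str, str] = {}
    data: np.ndarray | None = None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", "replace").partition("=")
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                if value.upper() == "LOCAL":
                    raw = fh.read()
                else:
                    raw_path = path.parent / value
                    raw = raw_path.read_bytes()
                break
    ndims = int(header.get("NDims", "0"))
    if ndims != 3:
        raise FormatError(f"{path}: expected 3D volume, got NDims={ndims}")
    if header.get("CompressedData", "False").lower() == "true":
        raise FormatError(f"{path}: compressed MetaImage not supported")
    if "ElementSpacing" not in header:
        raise FormatError(f"{path}: missing ElementSpacing")
    shape = tuple(int(v) for v in header["DimSize"].split())
    spacing = tuple(float(v) for v in header["ElementSpacing"].split())
    origin = tuple(
        float(v) for v in header.get("Offset", "0 0 0").split()
    )
    if "TransformMatrix" in header:
        mat = np.array([float(v) for v in header["TransformMatrix"].split()])
        if not np.allclose(mat.reshape(3, 3), np.eye(3)):
            raise FormatError(f"{path}: oblique orientation not supported")
    dtype = _MET_TYPES.get(header.get("ElementType", ""))
    if dtype is None:
        raise FormatError(f"{path}: unsupported ElementType")
    expected = int(np.prod(shape)) * np.dtype(dtype).itemsize
    if len(raw) < expected:
        raise FormatError(f"{path}: raw data shorter than DimSize implies")
    arr = np.frombuffer(raw[:expected], dtype=dtype)
    # MetaImage stores x fastest-varying; our arrays are indexed [x, y, z]
    arr = arr.reshape(shape, order="F")
    geom = GridGeometry(shape, spacing, origin)
    return geom, arr


def _write_metaimage(path: Path, geom: GridGeometry, arr: np.ndarray) -> None:
    dtype = arr.dtype.type
    if dtype not in _MET_NAMES:
        raise FormatError(f"cannot write dtype {arr.dtype} as MetaImage")
    is_mhd = path.suffix.lower() == ".mhd"
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {geom.origin[0]:.10g} {geom.origin[1]:.10g} {geom.origin[2]:.10g}",
        f"ElementSpacing = {geom.spacing[0]:.10g} {geom.spacing[1]:.10g} {geom.spacing[2]:.10g}",
        f"DimSize = {geom.shape[0]} {geom.shape[1]} {geom.shape[2]}",
        f"ElementType = {_MET_NAMES[dtype]}",
    ]
    payload = np.asfortranarray(arr).tobytes(order="F")
    if is_mhd:
        raw_name = path.with_suffix(".raw").name
        lines.append(f"ElementDataFile = {raw_name}")
        path.write_text("\n".join(lines) + "\n")
        (path.parent / raw_name).write_bytes(payload)
    else:
        lines.append("ElementDataFile = LOCAL")
        with open(path, "wb") as fh:
            fh.write(("\n".join(lines) + "\n").encode("ascii"))
            fh.write(payload)


def _read_nifti(path: Path) -> tuple[GridGeometry, np.ndarray]:
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise FormatError(f"{path}: expected 3D volume, got shape {shape}")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise FormatError(f"{path}: oblique orientation not supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: non-positive or flipped spacing")
    origin = affine[:3, 3]
    geom = GridGeometry(tuple(shape), tuple(spacing), tuple(origin))
    return geom, np.asanyarray(img.dataobj)


def _write_nifti(path: Path, geom: GridGeometry, arr: np.ndarray) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(geom.spacing)
    affine[:3, 3] = geom.origin
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))


def _dispatch(path: str | os.PathLike) -> str:
    name = str(path).lower()
    if name.endswith((".mha", ".mhd")):
        return "meta"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise FormatError(f"unrecognised volume extension on {path}")


def read_volume(
    path: str | os.PathLike,
    kind: str = "image",
    *,
    modality: Modality | str = Modality.CT,
    frame: DoseFrame | str = DoseFrame.PLANNING,
    name: str = "",
) -> GridObject:
    """Read a volume from MetaImage or NIfTI.

    ``kind`` selects the returned type: ``"image"`` (HU, clipped to
    [-1024, 3000]), ``"mask"`` (binarised at > 0.5) or ``"dose"`` (Gy).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _dispatch(path)
    geom, arr = _read_metaimage(path) if fmt == "meta" else _read_nifti(path)
    if kind == "image":
        return ImageVolume(geom, arr, modality=modality).clipped_hu()
    if kind == "mask":
        return StructureMask(geom, arr > 0.5, name=name)
    if kind == "dose":
        return DoseGrid(geom, arr, frame=frame)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(path: str | os.PathLike, obj: GridObject) -> None:
    """Write to MetaImage or NIfTI, chosen by extension.

    Images are stored float32, doses float64 and masks uint8, so a
    write/read round trip is bit-exact for each kind.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = obj.values
    if isinstance(obj, StructureMask):
        arr = arr.astype(np.uint8)
    elif isinstance(obj, ImageVolume):
        arr = arr.astype(np.float32, copy=False)
    else:
        arr = arr.astype(np.float64, copy=False)
    if _dispatch(path) == "meta":
        _write_metaimage(path, obj.geometry, arr)
    else:
        _write_nifti(path, obj.geometry, arr)


def write_field(path: str | os.PathLike, vectors: np.ndarray, geom: GridGeometry) -> None:
    """Write a 3-vector displacement field as a 4D NIfTI (last axis = x,y,z)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(geom.spacing)
    affine[:3, 3] = geom.origin
    nib.save(nib.Nifti1Image(np.asarray(vectors, dtype=np.float32), affine), str(path))


def read_field(path: str | os.PathLike) -> tuple[GridGeometry, np.ndarray]:
    img = nib.load(str(path))
    if len(img.shape) != 4 or img.shape[-1] != 3:
        raise FormatError(f"{path}: expected a (nx, ny, nz, 3) field")
    affine = img.affine
    geom = GridGeometry(
        tuple(img.shape[:3]),
        tuple(np.diag(affine[:3, :3])),
        tuple(affine[:3, 3]),
    )
    return geom, np.asanyarray(img.dataobj).astype(np.float64)
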