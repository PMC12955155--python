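"""Reading and writing scalar volumes (density grids, masks, dose) as
NIfTI-1 or NRRD.

NIfTI goes through nibabel.  NRRD is handled by a small self-contained
codec (raw little-endian encoding, detached header is not supported) so
that no optional dependency is needed; it covers exactly the subset this
package writes: 3D scalar volumes with axis-aligned spacings.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from fvheeplan.phantoms import Phantom, VoxelGrid

_NRRD_TYPES = {
    "float": np.float32,
    "double": np.float64,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "uint8": np.uint8,
    "float32": np.float32,
    "float64": np.float64,
}
_NRRD_TYPE_NAMES = {np.dtype(np.float32): "float", np.dtype(np.float64): "double", np.dtype(np.uint8): "uchar"}


def _write_nrrd(path: Path, data: np.ndarray, grid: VoxelGrid) -> None:
    dtype = np.dtype(data.dtype)
    if dtype not in _NRRD_TYPE_NAMES:
        raise ValueError(f"unsupported dtype for NRRD: {dtype}")
    header = [
        "NRRD0004",
        "# generated by fvheeplan",
        f"type: {_NRRD_TYPE_NAMES[dtype]}",
        "dimension: 3",
        "space: right-anterior-superior",
        f"sizes: {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}",
        "space directions: ({!r},0,0) (0,{!r},0) (0,0,{!r})".format(*grid.spacing),
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        "space origin: ({!r},{!r},{!r})".format(*grid.origin),
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(np.ascontiguousarray(data, dtype=dtype.newbyteorder("<")).tobytes(order="F"))


def _parse_vector(text: str) -> tuple[float, ...]:
    return tuple(float(v) for v in text.strip().lstrip("(").rstrip(")").split(","))


def _read_nrrd(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or end < 0:
        raise ValueError(f"{path}: not a valid NRRD file")
    fields: dict[str, str] = {}
    for line in raw[:end].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, value = line.split(":", 1)
        fields[key.strip()] = value.strip()
    if int(fields.get("dimension", 0)) != 3:
        raise ValueError(f"{path}: only 3D NRRD volumes are supported")
    if fields.get("encoding") != "raw":
        raise ValueError(f"{path}: only raw encoding is supported")
    dtype = np.dtype(_NRRD_TYPES[fields["type"]]).newbyteorder(
        "<" if fields.get("endian", "little") == "little" else ">"
    )
    dims = tuple(int(v) for v in fields["sizes"].split())
    dirs = [_parse_vector(v) for v in fields["space directions"].split(") (")]
    spacing = tuple(dirs[i][i] for i in range(3))
    origin = _parse_vector(fields.get("space origin", "(0,0,0)"))
    data = np.frombuffer(raw[end + 2 :], dtype=dtype, count=int(np.prod(dims)))
    data = data.reshape(dims, order="F").astype(dtype.newbyteorder("="))
    return data, VoxelGrid(origin, spacing, dims)


def _write_nifti(path: Path, data: np.ndarray, grid: VoxelGrid) -> None:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.ascontiguousarray(data), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    return data, VoxelGrid(origin, spacing, data.shape)


def write_volume(obj: Phantom | np.ndarray, path: str | Path, *, grid: VoxelGrid | None = None) -> None:
    """Write a Phantom (density) or a raw array (mask/dose) on ``grid``.

    Masks (bool arrays) are stored as uint8 0/1; float arrays as float32
    unless already float64.
    """
    path = Path(path)
    if isinstance(obj, Phantom):
        data, grid = obj.density.astype(np.float32), obj.grid
    else:
        if grid is None:
            raise ValueError("grid is required when writing a raw array")
        data = np.asarray(obj)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        elif data.dtype not in (np.float32, np.float64, np.uint8):
            data = data.astype(np.float32)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid {grid.shape}")
    if path.suffix == ".nrrd":
        _write_nrrd(path, data, grid)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        _write_nifti(path, data, grid)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path, *, expect_grid: VoxelGrid | None = None):
    """Read a volume; returns (array, grid).  uint8 payloads come back as
    boolean masks.  If ``expect_grid`` is given, geometry must match."""
    path = Path(path)
    if path.suffix == ".nrrd":
        data, grid = _read_nrrd(path)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        data, grid = _read_nifti(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if expect_grid is not None and grid != expect_grid:
        raise ValueError(f"{path}: grid {grid} does not match expected {expect_grid}")
    if data.dtype == np.uint8:
        return data.astype(bool), grid
    return data, grid


def read_phantom(path: str | Path) -> Phantom:
    data, grid = read_volume(path)
    return Phantom(grid, np.asarray(data, dtype=np.float64))
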