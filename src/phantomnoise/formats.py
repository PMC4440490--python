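"""Containers and file I/O: MRC2014 maps/stacks, PDB atoms, TSV parameter tables.

The MRC reader/writer is deliberately minimal: little-endian MRC2014,
modes 0/1/2 only, column(x)-fastest axis order. Maps written in other axis
conventions are not auto-permuted.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "ImageStack",
    "AtomList",
    "ParamTable",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_atoms",
    "read_params",
    "write_params",
]


class FormatError(ValueError):
    """Raised on malformed or unsupported input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A cubic 3D density grid.

    data is indexed [z, y, x]; pixel_size is Å per voxel (isotropic);
    origin is the voxel index of the rotation centre (edge // 2 by default,
    0-based, on every axis).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    origin: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"Volume data must be 3D, got shape {self.data.shape}")
        nz, ny, nx = self.data.shape
        if not (nz == ny == nx):
            raise FormatError(f"Volume must be cubic, got shape {self.data.shape}")
        if self.pixel_size <= 0:
            raise FormatError("pixel_size must be > 0")
        if self.origin is None:
            self.origin = nx // 2

    @property
    def box(self) -> int:
        return self.data.shape[0]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/Å."""
        return 1.0 / (2.0 * self.pixel_size)


@dataclass
class ImageStack:
    """N square 2D images sharing one pixel size; data indexed [i, y, x]."""

    data: np.ndarray
    pixel_size: float = 1.0
    ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise FormatError(f"ImageStack data must be N x ny x nx, got {self.data.shape}")
        n, ny, nx = self.data.shape
        if n < 1:
            raise FormatError("ImageStack needs at least one image")
        if ny != nx:
            raise FormatError(f"Images must be square, got {ny} x {nx}")
        if self.pixel_size <= 0:
            raise FormatError("pixel_size must be > 0")
        if not self.ids:
            self.ids = list(range(n))
        if len(self.ids) != n:
            raise FormatError("ids length must match image count")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def box(self) -> int:
        return self.data.shape[1]


@dataclass
class AtomList:
    """Atomic coordinates in Å with element symbols, occupancies and B factors."""

    positions: np.ndarray
    elements: list[str]
    occupancies: np.ndarray
    b_iso: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.positions) == 0 or self.positions.shape[1] != 3:
            raise FormatError("AtomList needs a nonempty N x 3 coordinate array")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("atom positions must be finite")
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.b_iso = np.asarray(self.b_iso, dtype=float)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def atomic_numbers(self) -> np.ndarray:
        import gemmi

        return np.array([max(gemmi.Element(e).atomic_number, 1) for e in self.elements])


PARAM_COLUMNS = ["id", "phi", "theta", "psi", "dx", "dy", "score", "select"]


@dataclass
class ParamTable:
    """Per-image alignment parameters.

    One row per image id: ZYZ Euler angles phi/theta/psi in degrees,
    shift dx/dy in pixels, correlation score in [-1, 1], selection flag.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PARAM_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"ParamTable missing column(s): {', '.join(missing)}")
        self.df = self.df[PARAM_COLUMNS].reset_index(drop=True)
        if self.df["id"].duplicated().any():
            raise FormatError("ParamTable must have one row per image id")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "ParamTable":
        if not rows:
            return cls(pd.DataFrame(columns=PARAM_COLUMNS))
        return cls(pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.df)

    def selected_ids(self) -> np.ndarray:
        return self.df.loc[self.df["select"] > 0, "id"].to_numpy()

    def row_for(self, image_id) -> pd.Series:
        hit = self.df[self.df["id"] == image_id]
        if len(hit) == 0:
            raise KeyError(f"no parameter row for image id {image_id}")
        return hit.iloc[0]

    def subset(self, ids) -> "ParamTable":
        idx = self.df["id"].isin(np.asarray(ids))
        return ParamTable(self.df[idx].copy())


# ---------------------------------------------------------------------------
# MRC2014 I/O
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32}
_HEADER_SIZE = 1024


def _read_mrc(path):
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise FormatError(f"{path}: truncated MRC header")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise FormatError(f"{path}: missing MAP marker, not an MRC2014 file")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if mode not in _MRC_MODES:
            raise FormatError(f"{path}: unsupported MRC mode {mode} (only 0/1/2)")
        if min(nx, ny, nz) < 1:
            raise FormatError(f"{path}: bad dimensions {nx}x{ny}x{nz}")
        fh.seek(_HEADER_SIZE + nsymbt)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=np.dtype(_MRC_MODES[mode]).newbyteorder("<"), count=count)
        if data.size != count:
            raise FormatError(f"{path}: data block shorter than header promises")
    data = data.reshape(nz, ny, nx).astype(np.float32)
    pixel = float(cella[0]) / mx if mx > 0 and cella[0] > 0 else 1.0
    return data, pixel


def _write_mrc(path, data: np.ndarray, pixel_size: float, is_stack: bool):
    data = np.ascontiguousarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError("refusing to write non-finite (NaN/Inf) data")
    nz, ny, nx = data.shape
    mz = 1 if is_stack else nz
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, mz)
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, mz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0 if is_stack else 1)  # ispg
    struct.pack_into("<i", header, 108, 20140)  # nversion
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        data.tofile(fh)


def read_volume(path) -> Volume:
    """Read a cubic MRC2014 map. Non-cubic grids are rejected."""
    data, pixel = _read_mrc(path)
    if not (data.shape[0] == data.shape[1] == data.shape[2]):
        raise FormatError(
            f"{path}: expected a cubic volume, got {data.shape[::-1]} (x,y,z)"
        )
    return Volume(data, pixel_size=pixel)


def write_volume(v: Volume, path) -> None:
    _write_mrc(path, v.data, v.pixel_size, is_stack=False)


def read_stack(path) -> ImageStack:
    data, pixel = _read_mrc(path)
    return ImageStack(data, pixel_size=pixel)


def write_stack(stack: ImageStack, path) -> None:
    _write_mrc(path, stack.data, stack.pixel_size, is_stack=True)


# ---------------------------------------------------------------------------
# PDB atoms
# ---------------------------------------------------------------------------

def read_atoms(path, exclude_waters: bool = True) -> AtomList:
    """Read ATOM/HETATM records from a PDB file (waters excluded by default)."""
    import gemmi

    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    positions, elements, occs, bs = [], [], [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                if exclude_waters and residue.is_water():
                    continue
                for atom in residue:
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(atom.element.name)
                    occs.append(atom.occ)
                    bs.append(atom.b_iso)
        break  # first model only
    if not positions:
        raise FormatError(f"{path}: no atoms parsed (after water filtering)")
    return AtomList(np.array(positions), elements, np.array(occs), np.array(bs))


# ---------------------------------------------------------------------------
# Parameter tables (TSV)
# ---------------------------------------------------------------------------

def write_params(table: ParamTable, path) -> None:
    """Write a tab-separated parameter table with a fixed header line."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_params(path) -> ParamTable:
    """Read a TSV parameter table; columns are matched by name."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return ParamTable(df)
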