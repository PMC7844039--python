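"""Reading and writing gridded height-map surfaces and texture-parameter tables.

Surfaces are rectangular grids of heights in micrometres with an explicit
lateral sampling step (``dx``, ``dy``).  Non-measured points ("voids") are
carried as NaN in memory.  Three on-disk dialects are supported:

``sur``
    A minimal Digital-Surf-style single-object binary layout: 512-byte
    header followed by int16/int32 height counts with a z-scale and offset.
    Header fields honoured on read: signature, object type, bits per point,
    stored min/max counts, grid dimensions, x/y/z spacing, x/y/z offsets and
    the non-measured-points flag.  All other fields (operator, timestamps,
    unit strings, client zone) are preserved into ``HeightMap.meta`` but not
    interpreted.  Voids are stored as the format's non-measured flag
    (a count below the stored minimum) when the flag is set.

``ascii_matrix``
    Whitespace-separated rows preceded by a ``# nx ny dx dy`` header line;
    voids are the token ``NaN``.

``xyz``
    Three-column ``x y z`` text on a complete rectangular lattice.

Parameter tables are plain CSV with ISO-symbol column headers and one row
per measured surface.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (FormatError, GridError, ParameterError, ParseError,
                     ValidationError)

__all__ = [
    "HeightMap",
    "SpecimenTable",
    "ISO_PARAMETER_ORDER",
    "METADATA_COLUMNS",
    "read_height_map",
    "write_height_map",
    "read_parameter_table",
    "write_parameter_table",
]

#: The 23 areal texture parameters, in the canonical reporting order used
#: throughout the package (height, feature, spatial, hybrid, then functional
#: volume/core parameters).
ISO_PARAMETER_ORDER: tuple[str, ...] = (
    "Sq", "Ssk", "Sku", "Sp", "Sv", "Sz", "Sds", "Str", "Sal", "Sdq",
    "Ssc", "Sdr", "Vmp", "Vmc", "Vvc", "Vvv", "Spk", "Sk", "Svk",
    "Smr1", "Smr2", "S5z", "Sa",
)

#: Specimen metadata columns preceding the parameter block in CSV output.
METADATA_COLUMNS: tuple[str, ...] = (
    "specimen_id", "sample_id", "group", "diet_rank", "total_length",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HeightMap:
    """A rectangular grid of surface heights.

    Parameters
    ----------
    heights
        ``(ny, nx)`` float array of heights in µm.  NaN marks a void
        (non-measured point).  Row index maps to y, column index to x.
    dx, dy
        Lateral sample spacing in µm; both strictly positive.
    origin
        ``(x0, y0)`` of the first sample, µm.
    meta
        Free-form provenance (instrument, specimen ID, tooth ID, ...).
    """

    heights: np.ndarray
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValidationError("heights must be a 2-D array")
        ny, nx = self.heights.shape
        if nx < 2 or ny < 2:
            raise ValidationError(f"grid must be at least 2x2, got {nx}x{ny}")
        if not (self.dx > 0 and self.dy > 0):
            raise ValidationError("dx and dy must be positive")
        finite = np.isfinite(self.heights)
        if not finite.any():
            raise ValidationError("height map contains no measured points")
        if np.isinf(self.heights).any():
            raise ValidationError("height map contains infinite values")

    @property
    def nx(self) -> int:
        return self.heights.shape[1]

    @property
    def ny(self) -> int:
        return self.heights.shape[0]

    @property
    def void_mask(self) -> np.ndarray:
        """Boolean mask of non-measured points."""
        return np.isnan(self.heights)

    @property
    def n_voids(self) -> int:
        return int(self.void_mask.sum())

    def copy(self) -> "HeightMap":
        return HeightMap(self.heights.copy(), self.dx, self.dy,
                         self.origin, dict(self.meta))


@dataclass
class SpecimenTable:
    """Per-surface texture parameters plus specimen metadata.

    Wraps a :class:`pandas.DataFrame` with one row per measured surface.
    The parameter block uses the ISO symbols of :data:`ISO_PARAMETER_ORDER`;
    metadata columns are ``specimen_id``, ``sample_id``, ``group`` (sample
    label such as ``"1"``, ``"2a"``), ``diet_rank`` (ordinal, may be missing)
    and ``total_length`` (cm, may be missing).  Unknown columns survive
    round-trips untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "group" not in df.columns:
            raise ValidationError("table must have a 'group' column")
        if df["group"].isna().any() or (df["group"].astype(str) == "").any():
            raise ValidationError("group labels must be non-empty")
        if "sample_id" in df.columns and df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicated sample_id: {dup!r}")
        if "diet_rank" in df.columns:
            ranks = pd.to_numeric(df["diet_rank"], errors="coerce")
            present = ranks.dropna()
            if ((present <= 0) | (present != present.round())).any():
                raise ValidationError("diet_rank must be a positive integer")

    @property
    def parameters(self) -> list[str]:
        """ISO parameter columns present, in canonical order."""
        return [p for p in ISO_PARAMETER_ORDER if p in self.data.columns]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["group"].astype(str):
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.data["group"].astype(str) == g).sum())
                for g in self.groups}

    def subset(self, groups: Iterable[str]) -> "SpecimenTable":
        keep = self.data["group"].astype(str).isin([str(g) for g in groups])
        return SpecimenTable(self.data.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Digital-Surf-style .sur binary dialect
# ---------------------------------------------------------------------------

_SUR_STRUCT = struct.Struct(
    "<12s h H h h 30s 30s h h h h h 8s h i i i i i f f f "
    "16s 16s 16s 16s 16s 16s 16s 16s 16s f f f h h h 12s "
    "h h h h h h h f 10s h h 128s f f f 34s"
)
assert _SUR_STRUCT.size == 512

_SUR_SIGNATURE = b"DIGITAL SURF"
_SUR_TYPE_SURFACE = 2
# Stored counts span [-_SUR_IMAX, +_SUR_IMAX]; voids use _SUR_IMAX - 2 below min.
_SUR_IMAX_32 = 2 ** 30
_SUR_IMAX_16 = 2 ** 14


def _sur_pack_text(s: str, width: int) -> bytes:
    return s.encode("latin-1", "replace")[:width].ljust(width, b"\x00")


def _write_sur(m: HeightMap, path: Path, bits: int = 32) -> None:
    if bits not in (16, 32):
        raise FormatError("bits per point must be 16 or 32")
    imax = _SUR_IMAX_32 if bits == 32 else _SUR_IMAX_16
    z = m.heights
    voids = np.isnan(z)
    have_voids = bool(voids.any())
    zmin = float(np.nanmin(z))
    zmax = float(np.nanmax(z))
    zrange = zmax - zmin
    if zrange == 0.0:
        dz = 1.0
    else:
        dz = zrange / (2.0 * imax)
    # quantize against the float32-rounded scale/offset the header stores,
    # so the round-trip error stays within one quantization step
    dz = float(np.float32(dz))
    zoffset = float(np.float32(0.5 * (zmin + zmax)))
    counts = np.zeros(z.shape, dtype=np.int64)
    measured = ~voids
    counts[measured] = np.rint((z[measured] - zoffset) / dz).astype(np.int64)
    np.clip(counts, -2 * imax + 8, 2 * imax - 8, out=counts)
    cmin = int(counts[measured].min())
    cmax = int(counts[measured].max())
    counts[voids] = cmin - 2  # non-measured flag: below stored minimum
    dtype = np.int32 if bits == 32 else np.int16
    header = _SUR_STRUCT.pack(
        _SUR_SIGNATURE,
        0,                      # format: PC binary
        1,                      # number of objects
        1,                      # version
        _SUR_TYPE_SURFACE,
        _sur_pack_text(str(m.meta.get("name", "surface")), 30),
        _sur_pack_text(str(m.meta.get("operator", "dmta")), 30),
        0, 0, 1,                # material, acquisition, range type
        1 if have_voids else 0,  # special (non-measured) points present
        0,                      # absolute heights
        b"\x00" * 8,
        bits,
        cmin, cmax,
        m.nx, m.ny, m.nx * m.ny,
        np.float32(m.dx), np.float32(m.dy), np.float32(dz),
        _sur_pack_text("X", 16), _sur_pack_text("Y", 16), _sur_pack_text("Z", 16),
        _sur_pack_text("um", 16), _sur_pack_text("um", 16), _sur_pack_text("um", 16),
        _sur_pack_text("um", 16), _sur_pack_text("um", 16), _sur_pack_text("um", 16),
        1.0, 1.0, 1.0,          # unit ratios
        0, 0, 0,                # imprint, inverted, levelled
        b"\x00" * 12,
        0, 0, 0, 1, 1, 2000, 1,  # timestamp fields (unused)
        0.0,
        b"\x00" * 10,
        0, 0,                   # comment / private zone sizes
        b"\x00" * 128,
        np.float32(m.origin[0]), np.float32(m.origin[1]), np.float32(zoffset),
        b"\x00" * 34,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(counts.astype("<" + np.dtype(dtype).str[1:]).tobytes())


def _read_sur(path: Path) -> HeightMap:
    raw = Path(path).read_bytes()
    if len(raw) < _SUR_STRUCT.size:
        raise FormatError("file shorter than the 512-byte header")
    (sig, fmt, nobj, version, obj_type, name, operator, _mat, _acq, _rng,
     special, _absolute, _res1, bits, stored_min, stored_max, nx, ny, npts,
     fdx, fdy, fdz, *_rest) = _SUR_STRUCT.unpack(raw[:_SUR_STRUCT.size])
    tail = _SUR_STRUCT.unpack(raw[:_SUR_STRUCT.size])
    xoff, yoff, zoff = tail[-4], tail[-3], tail[-2]
    if sig != _SUR_SIGNATURE:
        raise FormatError(f"bad signature {sig!r}; expected {_SUR_SIGNATURE!r}")
    if obj_type != _SUR_TYPE_SURFACE:
        raise FormatError(f"unsupported object type {obj_type} (need surface=2)")
    if bits not in (16, 32):
        raise FormatError(f"unsupported bits-per-point {bits}")
    if nx < 2 or ny < 2 or npts != nx * ny:
        raise FormatError(
            f"inconsistent grid fields: nx={nx} ny={ny} total={npts}")
    if not (fdx > 0 and fdy > 0 and fdz > 0):
        raise FormatError("non-positive spacing field")
    dtype = np.dtype("<i4" if bits == 32 else "<i2")
    need = npts * dtype.itemsize
    body = raw[_SUR_STRUCT.size:_SUR_STRUCT.size + need]
    if len(body) < need:
        raise FormatError("data block truncated")
    counts = np.frombuffer(body, dtype=dtype).astype(np.int64).reshape(ny, nx)
    z = counts * float(fdz) + float(zoff)
    if special:
        z = np.where(counts < stored_min, np.nan, z)
    meta = {
        "name": name.rstrip(b"\x00").decode("latin-1", "replace"),
        "operator": operator.rstrip(b"\x00").decode("latin-1", "replace"),
        "format_version": int(version),
        "bits_per_point": int(bits),
        "source_format": "sur",
    }
    return HeightMap(z, float(fdx), float(fdy), (float(xoff), float(yoff)), meta)


# ---------------------------------------------------------------------------
# ASCII matrix dialect
# ---------------------------------------------------------------------------

def _write_ascii_matrix(m: HeightMap, path: Path) -> None:
    lines = ["# nx ny dx dy x0 y0",
             "# %d %d %.17g %.17g %.17g %.17g"
             % (m.nx, m.ny, m.dx, m.dy, m.origin[0], m.origin[1])]
    for row in m.heights:
        lines.append(" ".join("NaN" if np.isnan(v) else "%.17g" % v
                              for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_ascii_matrix(path: Path) -> HeightMap:
    text = Path(path).read_text().splitlines()
    header_vals: list[str] | None = None
    rows: list[list[float]] = []
    for line in text:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            fields = stripped[1:].split()
            if fields and all(_is_number(f) for f in fields):
                header_vals = fields
            continue
        try:
            rows.append([float(tok) for tok in stripped.split()])
        except ValueError as exc:
            raise ParseError(f"non-numeric height token: {exc}") from exc
    if header_vals is None or len(header_vals) < 4:
        raise FormatError("missing '# nx ny dx dy' header line")
    nx, ny = int(header_vals[0]), int(header_vals[1])
    dx, dy = float(header_vals[2]), float(header_vals[3])
    x0 = float(header_vals[4]) if len(header_vals) > 4 else 0.0
    y0 = float(header_vals[5]) if len(header_vals) > 5 else 0.0
    if len(rows) != ny or any(len(r) != nx for r in rows):
        raise FormatError(
            f"data block is not the declared {ny} rows x {nx} columns")
    return HeightMap(np.array(rows), dx, dy, (x0, y0),
                     {"source_format": "ascii_matrix"})


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# XYZ dialect
# ---------------------------------------------------------------------------

def _write_xyz(m: HeightMap, path: Path) -> None:
    x0, y0 = m.origin
    lines = []
    for j in range(m.ny):
        for i in range(m.nx):
            v = m.heights[j, i]
            lines.append("%.17g %.17g %s" % (
                x0 + i * m.dx, y0 + j * m.dy,
                "NaN" if np.isnan(v) else "%.17g" % v))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_xyz(path: Path, fill_missing: bool = False) -> HeightMap:
    pts = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        toks = stripped.split()
        if len(toks) != 3:
            raise ParseError(f"line {ln}: expected 3 columns, got {len(toks)}")
        try:
            pts.append((float(toks[0]), float(toks[1]), float(toks[2])))
        except ValueError as exc:
            raise ParseError(f"line {ln}: {exc}") from exc
    if not pts:
        raise FormatError("empty XYZ file")
    arr = np.array(pts)
    xs = np.unique(arr[:, 0])
    ys = np.unique(arr[:, 1])
    nx, ny = len(xs), len(ys)
    if nx < 2 or ny < 2:
        raise GridError("fewer than two distinct x or y coordinates")
    dxs, dys = np.diff(xs), np.diff(ys)
    if (not np.allclose(dxs, dxs[0], rtol=1e-6)
            or not np.allclose(dys, dys[0], rtol=1e-6)):
        raise GridError("x/y coordinates are not uniformly spaced")
    dx, dy = float(dxs[0]), float(dys[0])
    z = np.full((ny, nx), np.nan)
    filled = np.zeros((ny, nx), dtype=bool)
    ix = np.searchsorted(xs, arr[:, 0])
    iy = np.searchsorted(ys, arr[:, 1])
    z[iy, ix] = arr[:, 2]
    filled[iy, ix] = True
    if not filled.all():
        if not fill_missing:
            missing = np.argwhere(~filled)[0]
            raise GridError(
                "lattice point missing at row %d col %d "
                "(pass fill_missing=True to treat as void)"
                % (missing[0], missing[1]))
        # absent lattice points become voids
    return HeightMap(z, dx, dy, (float(xs[0]), float(ys[0])),
                     {"source_format": "xyz"})


# ---------------------------------------------------------------------------
# Public surface API
# ---------------------------------------------------------------------------

_FORMATS = ("sur", "ascii_matrix", "xyz")


def read_height_map(path, format: str | None = None,
                    fill_missing: bool = False) -> HeightMap:
    """Read a gridded surface from ``path``.

    ``format`` is one of ``"sur"``, ``"ascii_matrix"``, ``"xyz"``; when
    omitted it is inferred from the file extension (``.sur``, ``.xyz``,
    anything else → ASCII matrix).  ``fill_missing`` controls the XYZ
    dialect's handling of absent lattice points: error (default) or void.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        suffix = path.suffix.lower()
        format = {"sur": "sur", ".sur": "sur", ".xyz": "xyz"}.get(
            suffix, "ascii_matrix")
    if format not in _FORMATS:
        raise ParameterError(f"unknown surface format {format!r}; "
                             f"expected one of {_FORMATS}")
    if format == "sur":
        return _read_sur(path)
    if format == "xyz":
        return _read_xyz(path, fill_missing=fill_missing)
    return _read_ascii_matrix(path)


def write_height_map(m: HeightMap, path, format: str | None = None,
                     bits: int = 32) -> None:
    """Write ``m`` to ``path`` in the given dialect (see read_height_map)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".sur": "sur", ".xyz": "xyz"}.get(suffix, "ascii_matrix")
    if format not in _FORMATS:
        raise ParameterError(f"unknown surface format {format!r}; "
                             f"expected one of {_FORMATS}")
    if format == "sur":
        _write_sur(m, path, bits=bits)
    elif format == "xyz":
        _write_xyz(m, path)
    else:
        _write_ascii_matrix(m, path)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def read_parameter_table(path, column_map: Mapping[str, str] | None = None
                         ) -> SpecimenTable:
    """Read a CSV of per-surface texture parameters with specimen metadata.

    ``column_map`` renames source columns to the canonical names (ISO
    symbols and the metadata names of :data:`METADATA_COLUMNS`), so deposits
    with arbitrary headers can be consumed without editing the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty or headerless CSV") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in [c for c in ISO_PARAMETER_ORDER if c in df.columns]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}")
        df[col] = converted
    for col in ("diet_rank", "total_length"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "group" not in df.columns:
        raise ValidationError(f"{path}: missing 'group' column "
                              "(use column_map to rename the group label)")
    df["group"] = df["group"].astype(str)
    return SpecimenTable(df.reset_index(drop=True))


def write_parameter_table(table: SpecimenTable, path) -> None:
    """Write a SpecimenTable as CSV with stable column order.

    Metadata columns first, then the 23 ISO symbols in canonical order,
    then any extra columns in their original order.  Missing values are
    written as empty cells.
    """
    df = table.data
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    param_cols = [c for c in ISO_PARAMETER_ORDER if c in df.columns]
    extra = [c for c in df.columns if c not in meta_cols + param_cols]
    ordered = df[meta_cols + param_cols + extra]
    ordered.to_csv(path, index=False, float_format="%.10g")
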