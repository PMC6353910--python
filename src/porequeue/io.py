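"""Readers and writers for section images and annotation tables.

Section images come as single-slice TIFF (any integer or float grayscale)
or MRC2014 mode 0/1/2 volumes, of which the first slice is taken.  The MRC
reader is a minimal, self-contained implementation of the fixed 1024-byte
header (little-endian) sufficient for single-section tomogram exports; the
voxel size is derived from the cell dimensions when present.  A pixel size
given explicitly always wins over the file header (with a warning logged on
conflict), because headers of exported sections frequently carry stale
calibrations.

Annotation tables are TSV with one point per row:
``npc_id  point_role  x_nm  y_nm  compartment_side`` where ``point_role``
is one of the four envelope bend-edge roles or ``particle``.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import SectionImage
from .npc_mapper import EDGE_ROLES, NpcAnnotation

__all__ = [
    "read_section",
    "write_section_tiff",
    "write_section_mrc",
    "read_annotations",
    "write_annotations",
    "write_positions",
    "read_positions",
    "write_particles",
]

logger = logging.getLogger(__name__)

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32}


def _read_mrc_slice(path: Path) -> tuple[np.ndarray, float | None]:
    """First z-slice and pixel size (nm) of an MRC2014 mode 0/1/2 file."""
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (only 0/1/2)")
        cella = struct.unpack("<3f", header[40:52])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        fh.seek(1024 + nsymbt)
        dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
        data = np.fromfile(fh, dtype=dtype, count=nx * ny)
        if data.size < nx * ny:
            raise ValueError(f"{path}: truncated MRC data")
    # cell dimensions are in Angstrom; 0 means uncalibrated
    pixel_nm = cella[0] / nx / 10.0 if cella[0] > 0 and nx > 0 else None
    del nz
    return data.reshape(ny, nx), pixel_nm


def read_section(
    path, pixel_size: float | None = None, slice_index: int = 0
) -> SectionImage:
    """Load a single-slice grayscale image as a :class:`SectionImage`.

    ``pixel_size`` (nm/px) must be given for TIFF; for MRC it defaults to
    the header voxel size but an explicit value overrides it.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".rec"):
        pixels, header_px = _read_mrc_slice(path)
        if pixel_size is None:
            if header_px is None:
                raise ValueError(f"{path}: no pixel size in header; pass pixel_size")
            pixel_size = header_px
        elif header_px is not None and abs(header_px - pixel_size) > 1e-6:
            logger.warning(
                "%s: pixel size %.4g nm overrides header value %.4g nm",
                path, pixel_size, header_px,
            )
    else:
        pixels = tifffile.imread(path)
        if pixels.ndim == 3:
            pixels = pixels[slice_index]
        if pixel_size is None:
            raise ValueError(f"{path}: pixel_size (nm/px) required for TIFF input")
    return SectionImage(
        pixels=np.asarray(pixels),
        pixel_size=float(pixel_size),
        provenance=f"{path}[{slice_index}]",
    )


def write_section_tiff(path, image: SectionImage) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def write_section_mrc(path, image: SectionImage) -> None:
    """Write a single-section float32 MRC2014 file (mode 2)."""
    pixels = image.pixels.astype("<f4")
    ny, nx = pixels.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx, my, mz
    cell = (nx * image.pixel_size * 10.0, ny * image.pixel_size * 10.0, image.pixel_size * 10.0)
    struct.pack_into("<3f", header, 40, *cell)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76, float(pixels.min()), float(pixels.max()), float(pixels.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(pixels.tobytes())


def write_annotations(path, annotations: list[NpcAnnotation]) -> None:
    rows = []
    for ann in annotations:
        for role in EDGE_ROLES:
            x, y = ann.edge_points[role]
            rows.append(
                {
                    "npc_id": ann.npc_id,
                    "point_role": role,
                    "x_nm": x,
                    "y_nm": y,
                    "compartment_side": ann.compartment_side or "",
                }
            )
        for pid, (x, y) in zip(ann.particle_ids, ann.particles):
            rows.append(
                {
                    "npc_id": ann.npc_id,
                    "point_role": "particle",
                    "point_id": pid,
                    "x_nm": x,
                    "y_nm": y,
                    "compartment_side": ann.compartment_side or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[NpcAnnotation]:
    """Read an annotation TSV into per-NPC annotation objects."""
    df = pd.read_csv(path, sep="\t", dtype={"npc_id": str})
    required = {"npc_id", "point_role", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    annotations = []
    for npc_id, group in df.groupby("npc_id", sort=True):
        edges = {}
        particles, ids = [], []
        side = None
        for _, row in group.iterrows():
            role = row["point_role"]
            pt = np.array([row["x_nm"], row["y_nm"]], dtype=float)
            if role in EDGE_ROLES:
                if role in edges:
                    raise ValueError(f"{path}: NPC {npc_id}: duplicate {role}")
                edges[role] = pt
            elif role == "particle":
                particles.append(pt)
                pid = row.get("point_id")
                ids.append(str(pid) if pd.notna(pid) else f"{npc_id}_p{len(ids)}")
            else:
                raise ValueError(f"{path}: NPC {npc_id}: unknown point_role {role!r}")
            if "compartment_side" in row and pd.notna(row["compartment_side"]):
                s = str(row["compartment_side"]).strip()
                if s:
                    side = s
        annotations.append(
            NpcAnnotation(
                npc_id=str(npc_id),
                edge_points=edges,
                particles=particles,
                particle_ids=ids,
                compartment_side=side,
            )
        )
    return annotations


def write_positions(path, positions: pd.DataFrame) -> None:
    cols = [c for c in ("npc_id", "particle_id", "X_nm", "Y_nm", "ring") if c in positions]
    extra = [c for c in positions.columns if c not in cols]
    positions[cols + extra].to_csv(path, sep="\t", index=False)


def read_positions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"npc_id": str, "particle_id": str})


def write_particles(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
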