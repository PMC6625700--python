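"""Reading and writing LUNA16-style inputs.

CT scans travel as MetaImage (``.mhd`` header + ``.raw`` data) volumes with
world-coordinate metadata; candidate locations and reference-standard nodule
annotations travel as CSV files keyed by series id and world (x, y, z)
millimetre coordinates.

Axis-order convention
---------------------
Voxel arrays are stored slice-major, ``(z, y, x)``, because axial-slice access
dominates every downstream step.  File metadata (MetaImage ``Offset`` /
``ElementSpacing``, CSV ``coordX/Y/Z``) is in ``(x, y, z)`` order and is
reordered on read.  ``CtVolume.origin`` and ``CtVolume.spacing`` are therefore
``(z, y, x)`` triples; world points handed to :func:`world_to_voxel` are
``(x, y, z)`` as they appear in the CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "CtVolume",
    "Candidate",
    "Annotation",
    "FormatError",
    "read_metaimage",
    "write_metaimage",
    "read_candidates",
    "write_candidates",
    "read_annotations",
    "write_annotations",
    "world_to_voxel",
    "voxel_to_world",
]


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


@dataclass
class CtVolume:
    """One CT scan: a 3D intensity array plus its world geometry.

    ``voxels`` is indexed ``(z, y, x)``; ``origin`` and ``spacing`` are
    millimetre triples in the same ``(z, y, x)`` order.  Intensities are
    Hounsfield units as stored on disk unless the volume has been normalized.
    """

    voxels: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    series_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"CT volume must be rank 3, got rank {self.voxels.ndim}"
            )
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class Candidate:
    """A candidate detection: world point, binary label, optional score.

    ``label`` is +1 for nodule, -1 for non-nodule — the two-class coding used
    throughout the boosting stage.  ``world_xyz`` is ``(x, y, z)`` mm.
    """

    series_id: str
    world_xyz: tuple[float, float, float]
    label: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"candidate label must be -1 or +1, got {self.label}")
        if self.score is not None and not math.isfinite(self.score):
            raise ValueError(f"candidate score must be finite, got {self.score}")


@dataclass
class Annotation:
    """A reference-standard nodule: world centre ``(x, y, z)`` mm + diameter."""

    series_id: str
    world_xyz: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


# ---------------------------------------------------------------------------
# MetaImage
# ---------------------------------------------------------------------------

_REQUIRED_MHD_KEYS = ("NDims", "ElementSpacing", "ElementDataFile")


def _scan_mhd_header(path: Path) -> dict[str, str]:
    header: dict[str, str] = {}
    try:
        text = path.read_text(errors="replace")
    except OSError as exc:
        raise FormatError(f"cannot read MetaImage header {path}: {exc}") from exc
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip()] = value.strip()
    for key in _REQUIRED_MHD_KEYS:
        if key not in header:
            raise FormatError(f"MetaImage header {path} lacks required field {key}")
    if header["NDims"] != "3":
        raise FormatError(
            f"MetaImage header {path}: NDims must be 3, got {header['NDims']}"
        )
    return header


def read_metaimage(path: str | Path) -> CtVolume:
    """Read a MetaImage volume, mapping (x, y, z) metadata to (z, y, x).

    The header is pre-scanned so that a missing ``ElementSpacing`` or a
    non-3D ``NDims`` raises :class:`FormatError` naming the offending field
    instead of silently acquiring defaults.
    """
    path = Path(path)
    header = _scan_mhd_header(path)
    data_file = header["ElementDataFile"]
    if data_file.upper() != "LOCAL":
        raw = path.parent / data_file
        if not raw.exists():
            raise FormatError(f"MetaImage raw data file missing: {raw}")
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"malformed MetaImage {path}: {exc}") from exc
    voxels = sitk.GetArrayFromImage(image)  # (z, y, x)
    ox, oy, oz = image.GetOrigin()
    sx, sy, sz = image.GetSpacing()
    return CtVolume(
        voxels=voxels,
        origin=(oz, oy, ox),
        spacing=(sz, sy, sx),
        series_id=path.stem,
    )


def write_metaimage(volume: CtVolume, path: str | Path) -> Path:
    """Write ``volume`` as an uncompressed ``.mhd`` + ``.raw`` pair."""
    path = Path(path)
    image = sitk.GetImageFromArray(volume.voxels)
    oz, oy, ox = volume.origin
    sz, sy, sx = volume.spacing
    image.SetOrigin((ox, oy, oz))
    image.SetSpacing((sx, sy, sz))
    sitk.WriteImage(image, str(path), useCompression=False)
    return path


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_CAND_COLUMNS = ("seriesuid", "coordX", "coordY", "coordZ", "class")
_ANNO_COLUMNS = ("seriesuid", "coordX", "coordY", "coordZ", "diameter_mm")


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in columns:
        if col == "seriesuid":
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, + header row
            raise FormatError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        frame[col] = coerced
    return frame


def read_candidates(path: str | Path) -> list[Candidate]:
    """Read a LUNA16-dialect candidates CSV.

    The ``class`` column {0, 1} is mapped to labels {-1, +1}; an optional
    ``score`` column is carried through.  Row order is preserved.
    """
    frame = _read_table(path, _CAND_COLUMNS)
    has_score = "score" in frame.columns
    out: list[Candidate] = []
    for i in range(len(frame)):
        cls = int(frame["class"].iloc[i])
        if cls not in (0, 1):
            raise FormatError(f"{path}: class must be 0 or 1, got {cls} at line {i + 2}")
        out.append(
            Candidate(
                series_id=str(frame["seriesuid"].iloc[i]),
                world_xyz=(
                    float(frame["coordX"].iloc[i]),
                    float(frame["coordY"].iloc[i]),
                    float(frame["coordZ"].iloc[i]),
                ),
                label=1 if cls == 1 else -1,
                score=float(frame["score"].iloc[i]) if has_score else None,
            )
        )
    return out


def write_candidates(candidates: Sequence[Candidate], path: str | Path) -> Path:
    """Write candidates (label mapped back to {0,1}; score column if any set)."""
    path = Path(path)
    rows = {
        "seriesuid": [c.series_id for c in candidates],
        "coordX": [c.world_xyz[0] for c in candidates],
        "coordY": [c.world_xyz[1] for c in candidates],
        "coordZ": [c.world_xyz[2] for c in candidates],
        "class": [1 if c.label == 1 else 0 for c in candidates],
    }
    if any(c.score is not None for c in candidates):
        rows["score"] = [c.score if c.score is not None else "" for c in candidates]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read an annotations CSV (``seriesuid,coordX,coordY,coordZ,diameter_mm``)."""
    frame = _read_table(path, _ANNO_COLUMNS)
    return [
        Annotation(
            series_id=str(frame["seriesuid"].iloc[i]),
            world_xyz=(
                float(frame["coordX"].iloc[i]),
                float(frame["coordY"].iloc[i]),
                float(frame["coordZ"].iloc[i]),
            ),
            diameter_mm=float(frame["diameter_mm"].iloc[i]),
        )
        for i in range(len(frame))
    ]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "seriesuid": [a.series_id for a in annotations],
            "coordX": [a.world_xyz[0] for a in annotations],
            "coordY": [a.world_xyz[1] for a in annotations],
            "coordZ": [a.world_xyz[2] for a in annotations],
            "diameter_mm": [a.diameter_mm for a in annotations],
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def _round_half_away_from_zero(values: np.ndarray) -> np.ndarray:
    # np.round rounds half-to-even; hit tests need the deterministic
    # half-away-from-zero convention.
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def world_to_voxel(
    world_xyz: Sequence[float], volume: CtVolume
) -> tuple[int, int, int]:
    """Map a world (x, y, z) mm point to the nearest 0-based (z, y, x) index.

    ``index = round((world - origin) / spacing)`` component-wise, rounding
    half away from zero.  Out-of-bounds indices are returned as-is; bounds
    are the patch extractor's concern.
    """
    wx, wy, wz = (float(v) for v in world_xyz)
    world_zyx = np.array([wz, wy, wx])
    continuous = (world_zyx - np.array(volume.origin)) / np.array(volume.spacing)
    idx = _round_half_away_from_zero(continuous).astype(int)
    return int(idx[0]), int(idx[1]), int(idx[2])


def voxel_to_world(
    index_zyx: Sequence[int], volume: CtVolume
) -> tuple[float, float, float]:
    """Inverse affine map: (z, y, x) voxel index to world (x, y, z) mm."""
    iz, iy, ix = index_zyx
    oz, oy, ox = volume.origin
    sz, sy, sx = volume.spacing
    return (ox + ix * sx, oy + iy * sy, oz + iz * sz)
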