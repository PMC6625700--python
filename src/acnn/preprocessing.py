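"""Signal enhancement and multi-scale 3D patch extraction.

The classification pipeline works on cubes cropped around candidate points.
Before cropping, intensities are normalized from Hounsfield units to [0, 1]
and each axial slice is sharpened with an unsharp mask — the original image
plus a scaled 4-neighbour Laplacian high-pass — to boost nodule margins.
Each candidate then yields three co-centred cubes: the raw 96-voxel crop and
trilinear downsamplings of it to 64 and 32 voxels, giving the three network
input scales.  Axial 90-degree rotations provide label-preserving
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_ct import Annotation, Candidate, CtVolume, world_to_voxel

__all__ = [
    "UnsharpParams",
    "MultiScalePatch",
    "unsharp_mask_slice",
    "enhance_volume",
    "filter_annotations",
    "normalize_intensity",
    "extract_patch96",
    "make_multiscale",
    "augment_rotations",
]

PATCH_EDGE = 96
SCALE_EDGES = (96, 64, 32)


@dataclass(frozen=True)
class UnsharpParams:
    """Unsharp-mask configuration.

    ``lambda_`` scales the high-pass correction added back onto the image:
    ``y = x + lambda * z`` with ``z`` the 4-neighbour Laplacian of ``x``.
    ``lambda_ = 0`` is the identity.
    """

    lambda_: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_) or self.lambda_ < 0:
            raise ValueError(f"lambda_ must be finite and >= 0, got {self.lambda_}")


@dataclass
class MultiScalePatch:
    """Three co-centred cubes (edges 96, 64, 32) around one candidate."""

    cube96: np.ndarray
    cube64: np.ndarray
    cube32: np.ndarray
    source: Candidate | None = None

    def __post_init__(self) -> None:
        for cube, edge in ((self.cube96, 96), (self.cube64, 64), (self.cube32, 32)):
            if cube.shape != (edge, edge, edge):
                raise ValueError(
                    f"cube{edge} has shape {cube.shape}, expected {(edge,) * 3}"
                )

    def cube(self, edge: int) -> np.ndarray:
        return {96: self.cube96, 64: self.cube64, 32: self.cube32}[edge]


def unsharp_mask_slice(slice2d: np.ndarray, params: UnsharpParams) -> np.ndarray:
    """Sharpen one 2D slice: ``y(n,m) = x(n,m) + lambda * z(n,m)``.

    The correction ``z`` is the 4-neighbour Laplacian high-pass
    ``z(n,m) = 4x(n,m) - x(n-1,m) - x(n+1,m) - x(n,m-1) - x(n,m+1)``
    with replicate (clamped) borders, so constant slices are exact fixed
    points including at the edges.
    """
    x = np.asarray(slice2d, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D slice, got rank {x.ndim}")
    padded = np.pad(x, 1, mode="edge")
    z = (
        4.0 * x
        - padded[:-2, 1:-1]
        - padded[2:, 1:-1]
        - padded[1:-1, :-2]
        - padded[1:-1, 2:]
    )
    return x + params.lambda_ * z


def enhance_volume(volume: CtVolume, params: UnsharpParams) -> CtVolume:
    """Apply the unsharp mask independently to every axial (z) slice."""
    out = np.empty(volume.voxels.shape, dtype=np.float64)
    for k in range(volume.voxels.shape[0]):
        out[k] = unsharp_mask_slice(volume.voxels[k], params)
    return CtVolume(
        voxels=out,
        origin=volume.origin,
        spacing=volume.spacing,
        series_id=volume.series_id,
    )


def filter_annotations(
    annotations: list[Annotation], min_mm: float = 5.0, max_mm: float = 30.0
) -> list[Annotation]:
    """Keep only nodules with diameter in the closed interval [min_mm, max_mm].

    Small opacities below 5 mm are excluded from the reference standard;
    masses above 30 mm are outside the nodule definition.
    """
    return [a for a in annotations if min_mm <= a.diameter_mm <= max_mm]


def normalize_intensity(
    volume: CtVolume, lo: float = -1000.0, hi: float = 400.0
) -> CtVolume:
    """Clip to [lo, hi] HU and map affinely to [0, 1].

    The default window spans air (-1000 HU) to dense soft tissue / early
    calcification (+400 HU), the range relevant to nodule contrast.
    """
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    clipped = np.clip(volume.voxels.astype(np.float64), lo, hi)
    return CtVolume(
        voxels=(clipped - lo) / (hi - lo),
        origin=volume.origin,
        spacing=volume.spacing,
        series_id=volume.series_id,
    )


def extract_patch96(
    volume: CtVolume, candidate: Candidate, edge: int = PATCH_EDGE
) -> np.ndarray:
    """Crop a cube of ``edge`` voxels centred on the candidate.

    Regions outside the volume are filled with 0, the normalized air level,
    so candidates near the pleura or the scan border stay usable.  A centre
    outside the volume bounds is an error.
    """
    if candidate.series_id and volume.series_id and (
        candidate.series_id != volume.series_id
    ):
        raise ValueError(
            f"candidate series {candidate.series_id!r} does not match "
            f"volume series {volume.series_id!r}"
        )
    centre = world_to_voxel(candidate.world_xyz, volume)
    shape = volume.voxels.shape
    if any(not (0 <= c < n) for c, n in zip(centre, shape)):
        raise ValueError(
            f"candidate centre {centre} outside volume bounds {shape}"
        )
    half = edge // 2
    out = np.zeros((edge, edge, edge), dtype=np.float64)
    src = []
    dst = []
    for c, n in zip(centre, shape):
        lo = c - half
        hi = lo + edge
        src.append(slice(max(lo, 0), min(hi, n)))
        dst.append(slice(max(-lo, 0), edge - max(hi - n, 0)))
    out[tuple(dst)] = volume.voxels[tuple(src)]
    return out


def make_multiscale(cube96: np.ndarray, source: Candidate | None = None) -> MultiScalePatch:
    """Downsample the 96-cube's full field of view to edges 64 and 32.

    Trilinear resampling over the same physical extent — not centre
    cropping — so the three scales see the same anatomy at decreasing
    resolution.
    """
    cube96 = np.asarray(cube96, dtype=np.float64)
    if cube96.shape != (96, 96, 96):
        raise ValueError(f"expected a 96^3 cube, got shape {cube96.shape}")
    cubes = {96: cube96}
    for edge in (64, 32):
        # map output sample i to input coordinate i * (96-1)/(edge-1):
        # endpoints align, interior is trilinear.
        cubes[edge] = _resample_cube(cube96, edge)
    return MultiScalePatch(
        cube96=cubes[96], cube64=cubes[64], cube32=cubes[32], source=source
    )


def _interp_axis(arr: np.ndarray, edge: int, axis: int) -> np.ndarray:
    n = arr.shape[axis]
    pos = np.linspace(0.0, n - 1.0, edge)
    i0 = np.minimum(np.floor(pos).astype(int), n - 2)
    w = pos - i0
    a0 = np.take(arr, i0, axis=axis)
    a1 = np.take(arr, i0 + 1, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = edge
    w = w.reshape(shape)
    return a0 * (1.0 - w) + a1 * w


def _resample_cube(cube: np.ndarray, edge: int) -> np.ndarray:
    # trilinear interpolation is separable: one 1D linear pass per axis
    out = cube
    for axis in range(3):
        out = _interp_axis(out, edge, axis)
    return out


def augment_rotations(patch: MultiScalePatch) -> list[MultiScalePatch]:
    """Return the patch plus its 90/180/270-degree axial-plane rotations.

    Rotations are about the z (slice) axis, the conventional chest-CT
    augmentation; labels are unchanged.
    """
    out = [patch]
    for k in (1, 2, 3):
        out.append(
            MultiScalePatch(
                # clockwise in the axial (y, x) plane = np.rot90 with k
                # negative quarter-turns over axes (1, 2)
                cube96=np.rot90(patch.cube96, k=-k, axes=(1, 2)).copy(),
                cube64=np.rot90(patch.cube64, k=-k, axes=(1, 2)).copy(),
                cube32=np.rot90(patch.cube32, k=-k, axes=(1, 2)).copy(),
                source=patch.source,
            )
        )
    return out
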