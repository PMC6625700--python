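"""CT-like phantom scans with nodules and false-positive confounders.

The generator emulates the statistical structure the classifier relies on,
in Hounsfield-like units: an air-level lung background (~ -900 HU) with a
smooth low-frequency tissue field and additive Gaussian noise; bright
quasi-spherical nodules of 5-30 mm whose margins can be roughened by
needle-like radial spikes (spiculation); and matched-brightness confounders
— smooth spheres and vessel-like tubes — that provide hard negatives.
Candidate lists pair one jittered positive per nodule with a configurable
number of negatives per scan, so per-scan FROC metrics are computable
end-to-end without any external data.

Scans, annotations and candidates can be written as standard MetaImage /
CSV files and flow through the same reading code paths as real data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_ct import Annotation, Candidate, CtVolume, voxel_to_world
from .preprocessing import (
    MultiScalePatch,
    UnsharpParams,
    enhance_volume,
    extract_patch96,
    make_multiscale,
    normalize_intensity,
)

__all__ = [
    "PhantomConfig",
    "NegativeStructure",
    "PatchSet",
    "SplitData",
    "SyntheticDataset",
    "generate_scan",
    "generate_candidates",
    "generate_dataset",
    "render_nodule_mask",
]

AIR_HU = -1000.0
LUNG_BASE_HU = -900.0


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the phantom cohort.

    Defaults: 40 scans of 64x128x128 voxels at (1.25, 0.9, 0.9) mm spacing
    (slice thickness under the 2.5 mm inclusion limit), 2-5 nodules per scan
    with diameters drawn from the full 5-30 mm inclusion range, 11 negative
    candidates per scan, moderate spiculation and 20 HU noise.
    """

    n_scans: int = 40
    volume_shape: tuple[int, int, int] = (64, 128, 128)  # (z, y, x) voxels
    spacing_mm: tuple[float, float, float] = (1.25, 0.9, 0.9)  # (z, y, x)
    nodules_per_scan: tuple[int, int] = (2, 5)  # inclusive range
    diameter_mm_range: tuple[float, float] = (5.0, 30.0)
    fp_candidates_per_scan: int = 11
    spiculation: float = 0.6
    noise_sd: float = 20.0
    nodule_hu_range: tuple[float, float] = (-100.0, 50.0)
    tissue_field_sd_hu: float = 50.0
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        lo, hi = self.diameter_mm_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad diameter range {self.diameter_mm_range}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


@dataclass(frozen=True)
class NegativeStructure:
    """A non-nodule confounder: smooth sphere or vessel-like tube."""

    kind: str  # "sphere" | "tube"
    world_xyz: tuple[float, float, float]
    radius_mm: float


# ---------------------------------------------------------------------------
# Structure rendering
# ---------------------------------------------------------------------------

def _spike_field(
    directions: np.ndarray, spiculation: float, rng: np.random.Generator
) -> np.ndarray:
    """Radial boundary perturbation: a sum of narrow positive lobes.

    Each lobe max(0, d.u_j)^8 is a needle-like protrusion along a random
    unit direction u_j; the spiculation parameter scales all amplitudes, so
    boundary roughness grows monotonically with it.
    """
    if spiculation <= 0:
        return np.zeros(directions.shape[:-1])
    n_spikes = int(rng.integers(8, 15))
    axes = rng.normal(size=(n_spikes, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    amps = rng.uniform(0.15, 0.5, size=n_spikes) * spiculation
    out = np.zeros(directions.shape[:-1])
    for u, a in zip(axes, amps):
        dot = directions @ u
        np.maximum(dot, 0.0, out=dot)
        out += a * dot**8
    return out


def render_nodule_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_vox: tuple[float, float, float],
    diameter_mm: float,
    spiculation: float,
    rng: np.random.Generator,
    edge_mm: float = 1.0,
) -> np.ndarray:
    """Soft occupancy mask of one (possibly spiculated) ellipsoidal nodule.

    The boundary sits where the normalized radial coordinate equals
    1 + spike(direction); the mask ramps linearly from 1 inside to 0 outside
    over ``edge_mm`` to avoid aliasing.
    """
    radius = diameter_mm / 2.0
    semi = radius * (1.0 + rng.uniform(-0.1, 0.1, size=3))  # mild anisotropy
    reach = radius * (1.0 + max(spiculation, 0.0) * 0.5) + 2 * edge_mm
    lo = [max(0, int(np.floor(c - reach / s))) for c, s in zip(centre_vox, spacing)]
    hi = [
        min(n, int(np.ceil(c + reach / s)) + 1)
        for c, s, n in zip(centre_vox, spacing, shape)
    ]
    mask = np.zeros(shape)
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    grids = np.meshgrid(
        *[
            (np.arange(l, h) - c) * s
            for l, h, c, s in zip(lo, hi, centre_vox, spacing)
        ],
        indexing="ij",
    )  # mm offsets (z, y, x)
    offsets = np.stack(grids, axis=-1)
    dist = np.linalg.norm(offsets, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        directions = np.where(dist[..., None] > 0, offsets / dist[..., None], 0.0)
    rho = np.sqrt(sum((g / r) ** 2 for g, r in zip(grids, semi)))
    spikes = _spike_field(directions, spiculation, rng)
    # signed distance proxy in normalized units; convert the soft edge width
    signed = (1.0 + spikes) - rho
    local = np.clip(signed * radius / edge_mm + 0.5, 0.0, 1.0)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = local
    return mask


def _render_tube_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_vox: tuple[float, float, float],
    axis: np.ndarray,
    half_length_mm: float,
    radius_mm: float,
    edge_mm: float = 1.0,
) -> np.ndarray:
    reach = half_length_mm + radius_mm + 2 * edge_mm
    lo = [max(0, int(np.floor(c - reach / s))) for c, s in zip(centre_vox, spacing)]
    hi = [
        min(n, int(np.ceil(c + reach / s)) + 1)
        for c, s, n in zip(centre_vox, spacing, shape)
    ]
    mask = np.zeros(shape)
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    grids = np.meshgrid(
        *[
            (np.arange(l, h) - c) * s
            for l, h, c, s in zip(lo, hi, centre_vox, spacing)
        ],
        indexing="ij",
    )
    offsets = np.stack(grids, axis=-1)
    along = np.clip(offsets @ axis, -half_length_mm, half_length_mm)
    radial = np.linalg.norm(offsets - along[..., None] * axis, axis=-1)
    local = np.clip((radius_mm - radial) / edge_mm + 0.5, 0.0, 1.0)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = local
    return mask


# ---------------------------------------------------------------------------
# Scan generation
# ---------------------------------------------------------------------------

def _place_centres(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radii_mm: Sequence[float],
    max_tries: int = 500,
) -> list[np.ndarray]:
    """Non-overlapping voxel-space centres with a 2 mm clearance.

    Structures are placed largest-first (order restored on return), which
    makes crowded configurations feasible far more often.
    """
    order = sorted(range(len(radii_mm)), key=lambda i: -radii_mm[i])
    centres_by_index: dict[int, np.ndarray] = {}
    centres: list[np.ndarray] = []
    placed_r: list[float] = []
    for i in order:
        r = radii_mm[i]
        margin = [r / s + 2 for s in spacing]
        if any(2 * m >= n for m, n in zip(margin, shape)):
            raise ValueError(
                f"structure of radius {r} mm does not fit volume {shape}"
            )
        for _ in range(max_tries):
            c = np.array(
                [rng.uniform(m, n - m) for m, n in zip(margin, shape)]
            )
            ok = True
            for c2, r2 in zip(centres, placed_r):
                dist_mm = np.linalg.norm((c - c2) * spacing)
                if dist_mm < r + r2 + 2.0:
                    ok = False
                    break
            if ok:
                centres.append(c)
                placed_r.append(r)
                centres_by_index[i] = c
                break
        else:
            raise RuntimeError(
                f"could not place structure of radius {r} mm after {max_tries} tries"
            )
    return [centres_by_index[i] for i in range(len(radii_mm))]


def _draw_structures(config: PhantomConfig, rng: np.random.Generator):
    """Counts and sizes of all structures in one scan (drawn before voxels)."""
    n_nodules = int(
        rng.integers(config.nodules_per_scan[0], config.nodules_per_scan[1] + 1)
    )
    diameters = rng.uniform(*config.diameter_mm_range, size=n_nodules)
    n_spheres = config.fp_candidates_per_scan // 3
    n_tubes = config.fp_candidates_per_scan // 3
    sphere_hi = min(config.diameter_mm_range[1], 20.0)
    sphere_d = rng.uniform(config.diameter_mm_range[0], sphere_hi, size=n_spheres)
    tube_r = rng.uniform(1.5, 3.5, size=n_tubes)
    tube_half = rng.uniform(8.0, 15.0, size=n_tubes)
    return diameters, sphere_d, tube_r, tube_half


def scan_candidate_count(config: PhantomConfig, scan_index: int) -> int:
    """Candidates the scan will contribute (positives + fixed negatives)."""
    rng = np.random.default_rng([config.seed, scan_index])
    diameters, *_ = _draw_structures(config, rng)
    return len(diameters) + config.fp_candidates_per_scan


def generate_scan(
    config: PhantomConfig, scan_index: int
) -> tuple[CtVolume, list[Annotation], list[NegativeStructure]]:
    """One phantom scan with its reference nodules and negative structures.

    Deterministic in (config.seed, scan_index): the same pair always yields
    bit-identical voxels.
    """
    rng = np.random.default_rng([config.seed, scan_index])
    shape = config.volume_shape
    spacing = config.spacing_mm
    series_id = f"phantom-{config.seed}-{scan_index:04d}"
    origin = (
        float(-shape[0] * spacing[0] / 2),
        float(-shape[1] * spacing[1] / 2),
        float(-shape[2] * spacing[2] / 2),
    )

    diameters, sphere_d, tube_r, tube_half = _draw_structures(config, rng)
    n_nodules = len(diameters)
    n_spheres = len(sphere_d)

    # background: lung base + smooth low-frequency tissue field + noise
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0)
    sd = field.std()
    if sd > 0:
        field *= config.tissue_field_sd_hu / sd
    volume = LUNG_BASE_HU + field + rng.normal(0.0, config.noise_sd, size=shape)

    radii = (
        list(diameters / 2)
        + list(sphere_d / 2)
        + [r + h for r, h in zip(tube_r, tube_half)]
    )
    centres = _place_centres(rng, shape, spacing, radii)

    vol = CtVolume(volume, origin=origin, spacing=spacing, series_id=series_id)
    annotations: list[Annotation] = []
    negatives: list[NegativeStructure] = []

    for i, d in enumerate(diameters):
        c = centres[i]
        hu = rng.uniform(*config.nodule_hu_range)
        mask = render_nodule_mask(shape, spacing, tuple(c), d, config.spiculation, rng)
        volume += (hu - LUNG_BASE_HU) * mask
        world = voxel_to_world(c, vol)
        annotations.append(Annotation(series_id, world, float(d)))

    for i, d in enumerate(sphere_d):
        c = centres[n_nodules + i]
        hu = rng.uniform(*config.nodule_hu_range)
        mask = render_nodule_mask(shape, spacing, tuple(c), d, 0.0, rng)
        volume += (hu - LUNG_BASE_HU) * mask
        negatives.append(
            NegativeStructure("sphere", voxel_to_world(c, vol), float(d / 2))
        )

    for i, (r, h) in enumerate(zip(tube_r, tube_half)):
        c = centres[n_nodules + n_spheres + i]
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        hu = rng.uniform(*config.nodule_hu_range)
        mask = _render_tube_mask(shape, spacing, tuple(c), axis, float(h), float(r))
        volume += (hu - LUNG_BASE_HU) * mask
        negatives.append(NegativeStructure("tube", voxel_to_world(c, vol), float(r)))

    vol.voxels = volume
    return vol, annotations, negatives


# ---------------------------------------------------------------------------
# Candidates
# ---------------------------------------------------------------------------

def generate_candidates(
    scan: CtVolume,
    annotations: Sequence[Annotation],
    negatives: Sequence[NegativeStructure],
    config: PhantomConfig,
) -> list[Candidate]:
    """One jittered positive per nodule plus exactly ``fp_candidates_per_scan``
    negatives at confounder centres and random background points."""
    rng = np.random.default_rng(
        [config.seed, zlib.crc32(scan.series_id.encode()), 7]
    )
    candidates: list[Candidate] = []
    for a in annotations:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = direction * (a.radius_mm / 2) * rng.uniform(0, 1) ** (1 / 3)
        world = tuple(np.asarray(a.world_xyz) + shift)
        candidates.append(Candidate(scan.series_id, world, label=1))

    def far_from_nodules(world: np.ndarray) -> bool:
        return all(
            np.linalg.norm(world - np.asarray(a.world_xyz)) > a.radius_mm + 1.0
            for a in annotations
        )

    n_neg = 0
    for neg in negatives:
        if n_neg >= config.fp_candidates_per_scan:
            break
        world = np.asarray(neg.world_xyz, dtype=float)
        if far_from_nodules(world):
            candidates.append(Candidate(scan.series_id, tuple(world), label=-1))
            n_neg += 1
    # top up with random interior background points
    shape = np.array(scan.shape)
    spacing_zyx = np.array(scan.spacing)
    origin_zyx = np.array(scan.origin)
    attempts = 0
    while n_neg < config.fp_candidates_per_scan:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not sample enough negative candidates")
        vox = rng.uniform(8, shape - 8)
        world_zyx = origin_zyx + vox * spacing_zyx
        world = world_zyx[::-1]  # (x, y, z)
        if far_from_nodules(world):
            candidates.append(Candidate(scan.series_id, tuple(world), label=-1))
            n_neg += 1
    return candidates


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Stacked multi-scale cubes with labels, one row per candidate."""

    x96: np.ndarray
    x64: np.ndarray
    x32: np.ndarray
    labels: np.ndarray
    candidates: list[Candidate]

    def cubes(self) -> dict[int, np.ndarray]:
        return {96: self.x96, 64: self.x64, 32: self.x32}

    def __len__(self) -> int:
        return len(self.labels)

    def save(self, directory: str | Path, name: str) -> None:
        """Binary cube container plus a JSON sidecar index."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / f"{name}_patches.npz",
            x96=self.x96, x64=self.x64, x32=self.x32, labels=self.labels,
        )
        index = [
            {
                "offset": i,
                "seriesuid": c.series_id,
                "coordX": c.world_xyz[0],
                "coordY": c.world_xyz[1],
                "coordZ": c.world_xyz[2],
                "label": int(c.label),
            }
            for i, c in enumerate(self.candidates)
        ]
        (directory / f"{name}_index.json").write_text(json.dumps(index))

    @classmethod
    def load(cls, directory: str | Path, name: str) -> "PatchSet":
        import json

        directory = Path(directory)
        data = np.load(directory / f"{name}_patches.npz")
        index = json.loads((directory / f"{name}_index.json").read_text())
        candidates = [
            Candidate(
                e["seriesuid"],
                (e["coordX"], e["coordY"], e["coordZ"]),
                int(e["label"]),
            )
            for e in index
        ]
        return cls(data["x96"], data["x64"], data["x32"], data["labels"], candidates)


@dataclass
class SplitData:
    """Everything FROC needs for one scan-level split."""

    patches: PatchSet
    annotations: list[Annotation]
    scan_ids: list[str]

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)


@dataclass
class SyntheticDataset:
    train: SplitData
    validation: SplitData
    test: SplitData
    config: PhantomConfig


def extract_multiscale_for_scan(
    scan: CtVolume,
    candidates: Sequence[Candidate],
    lambda_: float = 1.0,
) -> list[MultiScalePatch]:
    """Normalize -> unsharp-mask enhance -> crop 96 -> downsample per candidate."""
    prepared = enhance_volume(
        normalize_intensity(scan), UnsharpParams(lambda_=lambda_)
    )
    return [
        make_multiscale(extract_patch96(prepared, c), source=c) for c in candidates
    ]


def split_scan_indices(
    n_scans: int, proportions: tuple[float, float, float], rng: np.random.Generator
) -> tuple[list[int], list[int], list[int]]:
    """Partition scan indices (never candidates) into train/validation/test."""
    if n_scans < 3:
        raise ValueError("need at least as many scans as splits (3)")
    order = list(rng.permutation(n_scans))
    n_train = int(round(proportions[0] * n_scans))
    n_val = int(round(proportions[1] * n_scans))
    n_train = max(1, min(n_train, n_scans - 2))
    n_val = max(1, min(n_val, n_scans - n_train - 1))
    return (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )


def generate_dataset(
    config: PhantomConfig, lambda_: float = 1.0
) -> SyntheticDataset:
    """Generate the full phantom cohort and its scan-level splits."""
    rng = np.random.default_rng([config.seed, 2**20])
    groups = split_scan_indices(config.n_scans, config.split, rng)
    split_names = ("train", "validation", "test")
    membership = {}
    for name, idxs in zip(split_names, groups):
        for i in idxs:
            membership[i] = name

    # cube arrays are preallocated from a cheap counting pass to avoid a
    # transient doubling of the (gigabyte-scale) 96-cube stacks
    totals = {name: 0 for name in split_names}
    for i in range(config.n_scans):
        totals[membership[i]] += scan_candidate_count(config, i)

    buckets: dict[str, dict] = {}
    for name in split_names:
        m = totals[name]
        buckets[name] = {
            "x96": np.empty((m, 96, 96, 96), np.float32),
            "x64": np.empty((m, 64, 64, 64), np.float32),
            "x32": np.empty((m, 32, 32, 32), np.float32),
            "labels": np.empty(m, dtype=int),
            "cands": [],
            "annos": [],
            "scans": [],
            "row": 0,
        }

    for i in range(config.n_scans):
        scan, annotations, negatives = generate_scan(config, i)
        candidates = generate_candidates(scan, annotations, negatives, config)
        patches = extract_multiscale_for_scan(scan, candidates, lambda_)
        b = buckets[membership[i]]
        for p, c in zip(patches, candidates):
            r = b["row"]
            b["x96"][r] = p.cube96
            b["x64"][r] = p.cube64
            b["x32"][r] = p.cube32
            b["labels"][r] = c.label
            b["cands"].append(c)
            b["row"] = r + 1
        b["annos"].extend(annotations)
        b["scans"].append(scan.series_id)

    def finish(name: str) -> SplitData:
        b = buckets[name]
        assert b["row"] == totals[name]
        return SplitData(
            patches=PatchSet(
                x96=b["x96"],
                x64=b["x64"],
                x32=b["x32"],
                labels=b["labels"],
                candidates=b["cands"],
            ),
            annotations=b["annos"],
            scan_ids=b["scans"],
        )

    return SyntheticDataset(
        train=finish("train"),
        validation=finish("validation"),
        test=finish("test"),
        config=config,
    )
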