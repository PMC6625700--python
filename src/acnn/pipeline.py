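"""End-to-end orchestration: simulate -> preprocess -> fit -> predict -> evaluate.

Each stage writes its outputs plus a JSON manifest recording the parameters,
seeds and sha256 content hashes of everything it produced; a stage whose
manifest digest and output hashes still verify is skipped on re-run unless
forced.  Downstream digests include upstream output hashes, so corrupting an
intermediate file forces the stages that depend on it to re-run.

All randomness flows from a single root seed, split per stage with a seed
sequence, so any stage is re-runnable in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from . import ensemble as ens
from .evaluation import (
    FrocCurve,
    HitCriterion,
    average_sensitivity,
    froc,
    sensitivity_at,
    write_operating_table,
    STANDARD_FPS,
)
from .io_ct import (
    Annotation,
    Candidate,
    read_annotations,
    read_candidates,
    write_annotations,
    write_candidates,
    write_metaimage,
)
from .networks import ARCH_NAMES, Cnn3d, TrainConfig
from .synthetic import (
    PatchSet,
    PhantomConfig,
    generate_candidates,
    generate_dataset,
    generate_scan,
)

log = logging.getLogger("acnn")

STAGES = ("simulate", "preprocess", "fit-ensemble", "predict", "evaluate")


@dataclass
class RunConfig:
    """Layered run configuration; YAML keys mirror the field names."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    um_lambda: float = 1.0
    profile: str = "tiny"
    # desk-scale defaults: the tiny profile needs a larger step size than the
    # full-scale 0.001 because it sees ~3 orders of magnitude fewer samples
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.05, epochs=3, batch_size=8
        )
    )
    seed: int = 0
    out_dir: str = "runs/default"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        if "phantom" in raw:
            cfg.phantom = PhantomConfig(**{
                **dataclasses.asdict(cfg.phantom),
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in raw["phantom"].items()},
            })
        if "um" in raw:
            cfg.um_lambda = float(raw["um"].get("lambda", cfg.um_lambda))
        if "train" in raw:
            base = dataclasses.asdict(cfg.train)
            base.update(raw["train"])
            cfg.train = TrainConfig(**base)
        cfg.profile = raw.get("profile", cfg.profile)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        # the phantom seed follows the root seed unless set explicitly
        if "phantom" not in raw or "seed" not in raw.get("phantom", {}):
            cfg.phantom = dataclasses.replace(cfg.phantom, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        return {
            "phantom": dataclasses.asdict(self.phantom),
            "um": {"lambda": self.um_lambda},
            "profile": self.profile,
            "train": dataclasses.asdict(self.train),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


# ---------------------------------------------------------------------------
# Manifest machinery
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _run_stage(
    name: str,
    out_dir: Path,
    digest_inputs: dict,
    fn: Callable[[], Sequence[Path]],
    force: bool = False,
) -> dict:
    manifest_path = out_dir / f"{name}.manifest.json"
    digest = _digest(digest_inputs)
    if manifest_path.exists() and not force:
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("digest") == digest and all(
            Path(p).exists() and _sha256(Path(p)) == h
            for p, h in manifest.get("outputs", {}).items()
        ):
            log.info("stage %s: up to date, skipped", name)
            manifest["skipped"] = True
            return manifest
    log.info("stage %s: running", name)
    outputs = [Path(p) for p in fn()]
    manifest = {
        "stage": name,
        "digest": digest,
        "inputs": digest_inputs,
        "outputs": {str(p): _sha256(p) for p in outputs},
        "skipped": False,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_seed(root_seed: int, stage: str) -> int:
    return int(zlib_crc(stage) ^ (root_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out_dir: Path) -> list[Path]:
    scans_dir = out_dir / "scans"
    scans_dir.mkdir(parents=True, exist_ok=True)
    all_candidates: list[Candidate] = []
    all_annotations: list[Annotation] = []
    outputs: list[Path] = []
    for i in range(cfg.phantom.n_scans):
        scan, annotations, negatives = generate_scan(cfg.phantom, i)
        candidates = generate_candidates(scan, annotations, negatives, cfg.phantom)
        scan.voxels = scan.voxels.astype(np.float32)
        outputs.append(write_metaimage(scan, scans_dir / f"{scan.series_id}.mhd"))
        all_candidates.extend(candidates)
        all_annotations.extend(annotations)
    outputs.append(write_candidates(all_candidates, out_dir / "candidates.csv"))
    outputs.append(write_annotations(all_annotations, out_dir / "annotations.csv"))
    return outputs


def stage_preprocess(cfg: RunConfig, out_dir: Path) -> list[Path]:
    dataset = generate_dataset(cfg.phantom, lambda_=cfg.um_lambda)
    patches_dir = out_dir / "patches"
    outputs: list[Path] = []
    splits_meta = {}
    for name, split in (
        ("train", dataset.train),
        ("validation", dataset.validation),
        ("test", dataset.test),
    ):
        split.patches.save(patches_dir, name)
        outputs.append(patches_dir / f"{name}_patches.npz")
        outputs.append(patches_dir / f"{name}_index.json")
        outputs.append(
            write_annotations(
                split.annotations, patches_dir / f"{name}_annotations.csv"
            )
        )
        splits_meta[name] = {"scan_ids": split.scan_ids, "n_scans": split.n_scans}
    splits_path = out_dir / "splits.json"
    splits_path.write_text(json.dumps(splits_meta, indent=2))
    outputs.append(splits_path)
    return outputs


def stage_fit_ensemble(cfg: RunConfig, out_dir: Path) -> list[Path]:
    patches_dir = out_dir / "patches"
    train_set = PatchSet.load(patches_dir, "train")
    dataset = ens.WeightedTrainingSet(
        cubes=train_set.cubes(), labels=train_set.labels
    )
    fitted, history = ens.fit_acnn(
        dataset, cfg.train, seed=_stage_seed(cfg.seed, "fit"), profile=cfg.profile
    )
    models_dir = out_dir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    checkpoints = []
    for k, member in enumerate(fitted.members):
        name = ARCH_NAMES[k].lower().replace("-", "")
        weights = models_dir / f"{name}.npz"
        manifest = models_dir / f"{name}.arch.json"
        member.model.save(weights, manifest)
        checkpoints.append(str(weights))
        outputs += [weights, manifest]
    outputs.append(
        ens.save_manifest(
            fitted, models_dir / "ensemble.json", checkpoints,
            seed=_stage_seed(cfg.seed, "fit"),
        )
    )
    return outputs


def load_ensemble(models_dir: Path) -> ens.EnsembleModel:
    meta = json.loads((models_dir / "ensemble.json").read_text())
    members = []
    for k, name in enumerate(meta["order"]):
        stem = name.lower().replace("-", "")
        model = Cnn3d.load(models_dir / f"{stem}.npz", models_dir / f"{stem}.arch.json")
        members.append(
            ens.WeakClassifier(
                model, meta["alphas"][k], meta["errors"][k], meta["input_edges"][k]
            )
        )
    return ens.EnsembleModel(members)


def stage_predict(cfg: RunConfig, out_dir: Path) -> list[Path]:
    patches_dir = out_dir / "patches"
    test_set = PatchSet.load(patches_dir, "test")
    fitted = load_ensemble(out_dir / "models")
    scores = ens.score_batch(fitted, test_set.cubes(), batch_size=cfg.train.batch_size)
    scored = [
        dataclasses.replace(c, score=float(s))
        for c, s in zip(test_set.candidates, scores)
    ]
    return [write_candidates(scored, out_dir / "scored_candidates.csv")]


def stage_evaluate(cfg: RunConfig, out_dir: Path) -> list[Path]:
    scored = read_candidates(out_dir / "scored_candidates.csv")
    annotations = read_annotations(out_dir / "patches" / "test_annotations.csv")
    splits = json.loads((out_dir / "splits.json").read_text())
    curve = froc(scored, annotations, splits["test"]["n_scans"], HitCriterion())
    outputs = [
        write_operating_table(curve, out_dir / "operating_points.csv"),
    ]
    points_path = out_dir / "froc_points.csv"
    curve.to_frame().to_csv(points_path, index=False)
    outputs.append(points_path)
    return outputs


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit-ensemble": stage_fit_ensemble,
    "predict": stage_predict,
    "evaluate": stage_evaluate,
}


def run_pipeline(
    cfg: RunConfig,
    stages: Sequence[str] = STAGES,
    force: bool = False,
) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_manifest: dict = {"seed": cfg.seed, "stages": {}}
    upstream_hashes: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        digest_inputs = {
            "config": cfg.to_dict(),
            "stage": stage,
            "upstream": dict(upstream_hashes),
        }
        manifest = _run_stage(
            stage, out_dir, digest_inputs,
            lambda s=stage: _STAGE_FNS[s](cfg, out_dir),
            force=force,
        )
        run_manifest["stages"][stage] = manifest
        upstream_hashes.update(manifest.get("outputs", {}))
    (out_dir / "run.manifest.json").write_text(
        json.dumps(run_manifest, indent=2, default=str)
    )
    return run_manifest


def evaluate_split(
    fitted: ens.EnsembleModel,
    split,
    batch_size: int = 8,
) -> tuple[FrocCurve, list[float], float]:
    """Score a split in memory and return (curve, seven sensitivities, average)."""
    scores = ens.score_batch(fitted, split.patches.cubes(), batch_size=batch_size)
    scored = [
        dataclasses.replace(c, score=float(s))
        for c, s in zip(split.patches.candidates, scores)
    ]
    curve = froc(scored, split.annotations, split.n_scans, HitCriterion())
    sens = sensitivity_at(curve, STANDARD_FPS)
    return curve, sens, average_sensitivity(curve)
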