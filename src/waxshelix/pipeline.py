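"""End-to-end pipeline: forge -> score -> scatter -> dataset -> train.

One :class:`PipelineConfig` (YAML-serializable) drives the whole run.
Every artifact directory carries a snapshot of the config and its hash;
a run refuses to write into an output directory produced by a different
config (no artifact is ever silently overwritten), while a rerun with the
identical config resumes: existing stage outputs are kept, and deleted
ones are regenerated deterministically from the ensemble manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, dataset_builder as db, descriptors as desc
from . import boosted_models as bm
from . import helix_forge as hf
from . import scattering as sc

log = logging.getLogger("waxshelix")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs, in one serializable object."""

    n_conformations: int = 5000
    ensemble_seed: int = 0
    ranges: hf.ParameterRanges = field(default_factory=hf.ParameterRanges)
    condition_names: tuple[str, ...] = tuple(c.name for c in sc.DEFAULT_CONDITIONS)
    qmin: float = 0.0
    qmax: float = 0.950
    q_spacing: float = 0.005
    bead_width: float = sc.DEFAULT_BEAD_WIDTH
    split_fractions: tuple[float, float, float] = db.DEFAULT_FRACTIONS
    split_seed: int = 0
    descriptors: tuple[str, ...] = desc.DESCRIPTOR_NAMES
    variants: tuple[str, ...] = bm.VARIANTS
    training: bm.TrainingConfig = field(default_factory=bm.TrainingConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d))  # plain lists/scalars only

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ranges" in d and isinstance(d["ranges"], dict):
            r = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["ranges"].items()
            }
            d["ranges"] = hf.ParameterRanges(**r)
        if "training" in d and isinstance(d["training"], dict):
            d["training"] = bm.TrainingConfig(**d["training"])
        for key in ("condition_names", "split_fractions", "descriptors", "variants"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def qgrid(self) -> sc.QGrid:
        return sc.make_qgrid(self.qmin, self.qmax, self.q_spacing)

    def conditions(self) -> list[sc.SolutionCondition]:
        return [sc.condition_by_name(n) for n in self.condition_names]


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 resume: bool = True) -> dict:
    """Run (or resume) all stages; returns a dict of artifact paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out)

    state_path = out / "pipeline_state.json"
    if state_path.exists():
        state = json.loads(state_path.read_text())
        if state.get("config_hash") != config.config_hash:
            raise PipelineError(
                f"{out} holds artifacts of a different config "
                f"({state.get('config_hash')} != {config.config_hash}); "
                "refusing to overwrite"
            )
        if not resume:
            raise PipelineError(f"{out} already holds a completed run")
    else:
        state_path.write_text(json.dumps(
            {"config_hash": config.config_hash, "version": __version__}
        ))
    config.to_yaml(out / "config.yaml")

    artifacts: dict[str, Path] = {"outdir": out}

    # ---- stage: forge ----------------------------------------------------
    manifest_path = out / "manifest.csv"
    pdb_dir = out / "pdbs"
    if not manifest_path.exists():
        log.info("forge: sampling %d conformations (seed %d)",
                 config.n_conformations, config.ensemble_seed)
        models = hf.sample_ensemble(
            config.n_conformations, config.ranges, seed=config.ensemble_seed
        )
        pdb_dir.mkdir(exist_ok=True)
        paths = {}
        for m in models:
            p = pdb_dir / f"{m.conformation_id}.pdb"
            hf.write_pdb(m, p)
            paths[m.conformation_id] = str(p.relative_to(out))
        hf.write_manifest(models, manifest_path, paths)
    else:
        log.info("forge: reusing %s", manifest_path)
        models = None
    artifacts["manifest"] = manifest_path

    def _models():
        # deterministic regeneration from the manifest
        nonlocal models
        if models is None:
            params = hf.read_manifest(manifest_path)
            models = [
                hf.build_duplex(p, seed=config.ensemble_seed) for p in params
            ]
        return models

    # ---- stage: score ----------------------------------------------------
    desc_path = out / "descriptors.csv"
    if not desc_path.exists():
        log.info("score: extracting descriptors")
        desc.describe_models(_models()).to_csv(desc_path)
    artifacts["descriptors"] = desc_path

    # ---- stage: scatter + dataset ---------------------------------------
    dataset_path = out / "dataset.h5"
    if not dataset_path.exists():
        log.info("dataset: Debye profiles x %d conditions",
                 len(config.condition_names))
        ds = db.assemble(
            _models(), config.conditions(), config.qgrid(),
            bead_width=config.bead_width,
        )
        ds = db.split_by_conformation(ds, config.split_fractions,
                                      seed=config.split_seed)
        ds.meta["config_hash"] = config.config_hash
        db.save_h5(ds, dataset_path)
    else:
        log.info("dataset: reusing %s", dataset_path)
    artifacts["dataset"] = dataset_path

    # ---- stage: train ----------------------------------------------------
    ds = db.load_h5(dataset_path)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for descriptor in config.descriptors:
        for variant in config.variants:
            bdir = models_dir / f"{descriptor}__{variant}"
            if (bdir / "report.json").exists():
                log.info("train: reusing %s", bdir)
                continue
            log.info("train: %s / %s", descriptor, variant)
            bundle = _train_variant(ds, descriptor, variant, config.training)
            bm.save_bundle(bundle, bdir)
            trace = bm.importance(bundle)
            np.savetxt(
                bdir / "importance.csv",
                np.c_[trace.qgrid.values, trace.gain, trace.weight],
                delimiter=",", header="q,gain,weight", comments="",
            )
    artifacts["models"] = models_dir
    log.info("pipeline complete: %s", out)
    return artifacts


def _train_variant(ds, descriptor, variant, tc: bm.TrainingConfig):
    if variant == "noise-free":
        return bm.train(ds, descriptor, tc, variant=variant)
    if variant == "noisy":
        return bm.train(
            db.add_noise(ds, tc.noise_level, seed=tc.seed, tags=("train",)),
            descriptor, tc, variant=variant)
    if variant == "sparse":
        return bm.train(db.resample_qgrid(ds, tc.sparse_points),
                        descriptor, tc, variant=variant)
    if variant == "dense":
        return bm.train(db.resample_qgrid(ds, tc.dense_points),
                        descriptor, tc, variant=variant)
    if variant == "random":
        return bm.train(db.randomize_labels(ds, seed=tc.seed),
                        descriptor, tc, variant=variant)
    raise PipelineError(f"unknown variant {variant!r}")


def _setup_log(out: Path) -> None:
    if not any(isinstance(h, logging.FileHandler)
               and Path(h.baseFilename) == (out / "run.log").resolve()
               for h in log.handlers):
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(logging.INFO)
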