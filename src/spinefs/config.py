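"""Pipeline configuration, seed fan-out, and the end-to-end runner.

One global seed drives everything: each stage derives its own seed by stable
hashing of the stage name, so stages stay decoupled (re-ordering or re-running
one stage never shifts another stage's random stream). Every stage writes its
outputs plus a config-hash marker; re-running skips stages whose outputs are
present and whose marker matches the current configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .agreement_stats import summarize_study, write_report
from .gan_core import (AugmentParams, DiscriminatorSpec, GeneratorSpec,
                       SsimParams, TrainConfig, load_checkpoint,
                       save_checkpoint, save_history_csv, train)
from .preprocess import PairedSliceDataset, cap_and_scale, extract_sagittal_slices
from .volume_synthesis import synthesize_volume

log = logging.getLogger("spinefs")


@dataclass
class PhantomConfig:
    n_train: int = 20
    n_test: int = 3
    shape: tuple[int, int, int] = (10, 64, 64)
    n_vertebrae: int = 5
    noise_sd: float = 0.02
    pathology_rate: float = 0.7     # fraction of phantoms carrying a lesion


@dataclass
class ReaderStudyConfig:
    n_datasets: int = 101
    n_readers: int = 2
    prevalence: dict | None = None
    error_rates: dict | None = None   # per protocol; defaults in phantom module


@dataclass
class PipelineConfig:
    out_dir: str = "spinefs_run"
    seed: int = 0
    log_level: str = "INFO"
    phantoms: PhantomConfig = field(default_factory=PhantomConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    readers: ReaderStudyConfig = field(default_factory=ReaderStudyConfig)
    register: bool = False            # phantoms are simulated pre-aligned

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()),
                                             sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        ph_cfg = PhantomConfig(**_tuplify(raw.pop("phantoms", {}),
                                          ("shape",)))
        tr_raw = dict(raw.pop("train", {}))
        for key, sub in (("augment", AugmentParams), ("generator", GeneratorSpec),
                         ("discriminator", DiscriminatorSpec), ("ssim", SsimParams)):
            if key in tr_raw and isinstance(tr_raw[key], dict):
                tr_raw[key] = sub(**_tuplify(
                    tr_raw[key], ("smooth_sigma_range", "noise_sd_range")))
        if "betas" in tr_raw:
            tr_raw["betas"] = tuple(tr_raw["betas"])
        tr_cfg = TrainConfig(**tr_raw)
        rd_cfg = ReaderStudyConfig(**raw.pop("readers", {}))
        return cls(phantoms=ph_cfg, train=tr_cfg, readers=rd_cfg, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def _tuplify(d: dict, keys: tuple[str, ...]) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 by stable hashing."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

_LESION_MENU: list[tuple[str, float]] = [
    ("bone_marrow_abnormality", 0.25),
    ("bone_marrow_abnormality", 0.8),
    ("modic_type1", 1),
    ("vertebral_fracture", 1),
    ("vertebral_fracture", 2),
    ("cord_lesion", 1),
    ("paravertebral_abnormality", 1),
    ("spondylodiscitis_expansion", 0.5),
]


def _phantom_spec(rng: np.random.Generator, rate: float) -> list[tuple[str, float]]:
    if rng.random() >= rate:
        return []
    k = int(rng.integers(1, 3))
    picks = rng.choice(len(_LESION_MENU), size=k, replace=False)
    return [_LESION_MENU[i] for i in picks]


def make_phantom_dataset(seed: int, cfg: PhantomConfig, n: int, first_id: int = 0,
                         ) -> list[dict]:
    """Render ``n`` aligned, normalized phantom datasets with all contrasts."""
    out = []
    for i in range(n):
        ds_seed = stage_seed(seed, f"phantom{first_id + i}")
        rng = np.random.default_rng(ds_seed)
        scene = ph.make_phantom(ds_seed, shape=cfg.shape,
                                n_vertebrae=cfg.n_vertebrae,
                                pathology_spec=_phantom_spec(rng, cfg.pathology_rate))
        vols, records = {}, {}
        for j, contrast in enumerate(("T1", "T2", "T2FS")):
            v = ph.render_contrast(scene, contrast, noise_sd=cfg.noise_sd,
                                   seed=ds_seed + j + 1)
            vols[contrast], records[contrast] = cap_and_scale(v)
        out.append({"id": first_id + i, "scene": scene, "volumes": vols,
                    "norm_records": records,
                    "grades": dict(ph.grade_from_scene(scene))})
    return out


def build_training_dataset(datasets: list[dict]) -> PairedSliceDataset:
    parts = [extract_sagittal_slices(d["volumes"]["T1"], d["volumes"]["T2"],
                                     d["volumes"]["T2FS"]) for d in datasets]
    return PairedSliceDataset.concatenate(parts)


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    marker = stage_dir / "config_hash.txt"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_stage(stage_dir: Path, cfg_hash: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "config_hash.txt").write_text(cfg_hash)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""


def _stage(name: str):
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc
    return ctx()


def run_end_to_end(config: PipelineConfig) -> dict:
    """simulate -> preprocess/train -> synthesize -> simulate readers -> evaluate.

    Each stage is resumable: outputs carry the config hash that produced
    them, and a rerun with an unchanged config skips completed stages.
    Returns a dict of artifact paths plus the final agreement report; a
    failing stage aborts with a :class:`StageError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    config.save(out / "config.yaml")
    artifacts: dict = {"out_dir": str(out), "config_hash": h}

    # -- stage 1+2: simulate phantoms & build slice dataset ------------------
    sim_dir = out / "phantoms"
    ck_path = out / "checkpoint.npz"
    with _stage("simulate"):
        seed_sim = stage_seed(config.seed, "simulate")
        train_sets = make_phantom_dataset(seed_sim, config.phantoms,
                                          config.phantoms.n_train)
        test_sets = make_phantom_dataset(seed_sim, config.phantoms,
                                         config.phantoms.n_test,
                                         first_id=config.phantoms.n_train)
    if not _stage_done(sim_dir, h):
        sim_dir.mkdir(exist_ok=True)
        for d in test_sets:       # persist the held-out cases for inspection
            for contrast, v in d["volumes"].items():
                v.save(sim_dir / f"ds{d['id']:03d}_{contrast}.nii.gz")
        pd.DataFrame([{"dataset_id": d["id"], "pathology": k, "gt_grade": g}
                      for d in train_sets + test_sets
                      for k, g in d["grades"].items()]
                     ).to_csv(sim_dir / "gt_grades.csv", index=False)
        _mark_stage(sim_dir, h)
        log.info("simulate: %d train + %d test phantoms",
                 len(train_sets), len(test_sets))
    artifacts["phantom_dir"] = str(sim_dir)

    # -- stage 3: train ------------------------------------------------------
    train_dir = out / "training"
    if not (_stage_done(train_dir, h) and ck_path.exists()):
        with _stage("train"):
            slice_ds = build_training_dataset(train_sets)
            cfg = dataclasses.replace(config.train,
                                      seed=stage_seed(config.seed, "train"))
            log.info("train: %d slices, %d epochs", len(slice_ds), cfg.epochs)
            checkpoint, history = train(slice_ds, cfg)
            save_checkpoint(checkpoint, ck_path)
            train_dir.mkdir(exist_ok=True)
            save_history_csv(history, train_dir / "history.csv")
            _mark_stage(train_dir, h)
    artifacts["checkpoint"] = str(ck_path)

    # -- stage 4: synthesize held-out volumes --------------------------------
    syn_dir = out / "synthesis"
    if not _stage_done(syn_dir, h):
        with _stage("synthesize"):
            syn_dir.mkdir(exist_ok=True)
            checkpoint = load_checkpoint(ck_path)
            quality = []
            for d in test_sets:
                res = synthesize_volume(d["volumes"]["T1"], d["volumes"]["T2"],
                                        checkpoint, reference=d["volumes"]["T2FS"])
                res.volume.save(syn_dir / f"ds{d['id']:03d}_SYNTH_T2FS.nii.gz")
                quality.append({"dataset_id": d["id"], "mean_ssim": res.mean_ssim,
                                "per_slice_ssim": res.per_slice_ssim})
            (syn_dir / "quality.json").write_text(json.dumps(quality, indent=2))
            _mark_stage(syn_dir, h)
            log.info("synthesize: mean held-out SSIM %.3f",
                     float(np.mean([q["mean_ssim"] for q in quality])))
    artifacts["synthesis_dir"] = str(syn_dir)

    # -- stage 5: simulated reader study -------------------------------------
    gradings_path = out / "gradings.csv"
    if not gradings_path.exists() or not _stage_done(out / "readers", h):
        with _stage("simulate_readers"):
            seed_rd = stage_seed(config.seed, "readers")
            gt = ph.sample_ground_truth(seed_rd, config.readers.n_datasets,
                                        config.readers.prevalence)
            frames = []
            for proto in ("two_sequence", "synthetic_protocol"):
                err = (config.readers.error_rates or {}).get(proto) \
                    if config.readers.error_rates else None
                frames.append(ph.simulate_readers(
                    gt, proto, error_model=err,
                    seed=stage_seed(seed_rd, proto),
                    n_readers=config.readers.n_readers))
            pd.concat(frames).to_csv(gradings_path, index=False)
            _mark_stage(out / "readers", h)
    artifacts["gradings"] = str(gradings_path)

    # -- stage 6: evaluate ----------------------------------------------------
    report_path = out / "report.json"
    with _stage("evaluate"):
        records = pd.read_csv(gradings_path)
        report = summarize_study(records)
        write_report(report, report_path)
        report.kappa_table().to_csv(out / "kappa_table.csv", index=False)
        report.accuracy_table().to_csv(out / "accuracy_table.csv", index=False)
    artifacts["report"] = str(report_path)
    artifacts["agreement_report"] = report
    log.info("evaluate: mean kappa %s", report.mean_kappa)
    return artifacts
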