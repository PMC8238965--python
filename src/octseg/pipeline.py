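"""End-to-end orchestration of the segmentation pipeline and its ablations.

Four pipeline modes correspond to the classical ablation arms of this
method family:

* ``plain`` — coarse network segmentation only;
* ``wt``    — wavelet despeckling before training/prediction;
* ``crf``   — dense-CRF refinement after prediction;
* ``full``  — both despeckling and refinement.

Every stage hands off through files in the working directory (phantom
PNGs, denoised PNGs, probability TIFFs, mask PNGs, JSON reports), so a
run is fully inspectable, and a structured run log records each stage's
parameters, seed and timing. The global seed determines phantom
generation, the patient-level split, weight initialization, and
shuffling; a rerun with the same config reproduces the same report.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .crf import CRFParams, refine
from .metrics import aggregate_reports, evaluate_masks, roc_auc
from .nn.network import NetConfig
from .nn.training import TrainConfig, save_checkpoint, train
from .phantom import DatasetManifest, PhantomSpec, generate_dataset
from .wavelet import DenoiseConfig, denoise

MODES = ("plain", "wt", "crf", "full")


@dataclass
class PipelineConfig:
    mode: str = "full"
    workdir: Path = Path("runs/run0")
    data_dir: Path | None = None          # reuse an existing phantom dataset
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_patients: int = 25
    scans_per_patient: int = 8
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)  # train/val/test
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    crf: CRFParams = field(default_factory=CRFParams)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.workdir = Path(self.workdir)
        if self.data_dir is not None:
            self.data_dir = Path(self.data_dir)
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a nested-key YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sub = {
        "phantom": PhantomSpec, "denoise": DenoiseConfig, "net": NetConfig,
        "train": TrainConfig, "crf": CRFParams,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in sub:
            if isinstance(val.get("blocks_per_stage"), list):
                val["blocks_per_stage"] = tuple(val["blocks_per_stage"])
            for tup in ("atrous_rates", "input_size", "kernel_weights",
                        "pocket_scale_range", "layer_intensities",
                        "class_weights"):
                if tup in val:
                    val[tup] = tuple(val[tup])
            kwargs[key] = sub[key](**val)
        elif key == "split":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


def _split_patients(patient_ids: list[str], split, seed: int):
    rng = np.random.default_rng(seed)
    patients = sorted(set(patient_ids))
    order = rng.permutation(len(patients))
    n_train = max(1, int(round(split[0] * len(patients))))
    n_val = max(1, int(round(split[1] * len(patients))))
    roles = {}
    for rank, idx in enumerate(order):
        role = ("train" if rank < n_train
                else "val" if rank < n_train + n_val else "test")
        roles[patients[idx]] = role
    if "test" not in roles.values():  # tiny cohorts: borrow one val patient
        roles[patients[order[-1]]] = "test"
    return roles


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: dict
    run_log: list[dict]
    workdir: Path


def _stage(log: list[dict], name: str, **params):
    entry = {"stage": name, "params": params, "t_start": time.time()}
    log.append(entry)
    return entry


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> PipelineResult:
    """Execute exactly the stages implied by ``config.mode``; see module docs."""
    cfg = config
    wd = cfg.workdir
    wd.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    use_wt = cfg.mode in ("wt", "full")
    use_crf = cfg.mode in ("crf", "full")

    # -- phantoms ------------------------------------------------------
    data_dir = cfg.data_dir or (wd / "data")
    manifest_path = Path(data_dir) / "manifest.json"
    entry = _stage(log, "phantom", seed=cfg.phantom.seed,
                   n_patients=cfg.n_patients,
                   scans_per_patient=cfg.scans_per_patient,
                   reused=manifest_path.exists())
    if manifest_path.exists():
        manifest = DatasetManifest.load(manifest_path)
    else:
        spec = dataclasses.replace(cfg.phantom, seed=cfg.phantom.seed + cfg.seed)
        manifest = generate_dataset(spec, cfg.n_patients,
                                    cfg.scans_per_patient, data_dir)
    entry["t_end"] = time.time()

    # -- despeckling (wt / full) --------------------------------------
    if use_wt:
        entry = _stage(log, "denoise", **dataclasses.asdict(cfg.denoise))
        dn_dir = wd / "denoised"
        dn_dir.mkdir(exist_ok=True)
        for e in manifest.entries:
            noisy = _io.read_gray(manifest.root / e["noisy"])
            _io.write_gray(dn_dir / e["noisy"], denoise(noisy, cfg.denoise))
        entry["t_end"] = time.time()

    def input_image(e):
        if use_wt:
            return _io.read_gray(wd / "denoised" / e["noisy"])
        return _io.read_gray(manifest.root / e["noisy"])

    # -- patient-level split ------------------------------------------
    roles = _split_patients([e["patient_id"] for e in manifest.entries],
                            cfg.split, cfg.seed)
    by_role = {r: [e for e in manifest.entries if roles[e["patient_id"]] == r]
               for r in ("train", "val", "test")}
    _stage(log, "split", roles={r: sorted({e["patient_id"] for e in v})
                                for r, v in by_role.items()})["t_end"] = time.time()

    # -- training ------------------------------------------------------
    entry = _stage(log, "train", **dataclasses.asdict(cfg.train))
    stack = lambda es: (
        np.stack([input_image(e) for e in es]),
        np.stack([_io.read_mask(manifest.root / e["mask"]) for e in es]),
    )
    x_tr, y_tr = stack(by_role["train"])
    x_va, y_va = stack(by_role["val"])
    tc = dataclasses.replace(cfg.train, seed=cfg.train.seed + cfg.seed)
    model, history = train(x_tr, y_tr, x_va, y_va, cfg.net, tc, verbose=verbose)
    ckpt = wd / "model.ckpt"
    save_checkpoint(ckpt, model, history)
    entry["t_end"] = time.time()

    # -- prediction + optional CRF refinement + evaluation ------------
    entry = _stage(log, "predict", n_test=len(by_role["test"]))
    pred_dir = wd / "predictions"
    pred_dir.mkdir(exist_ok=True)
    reports, aucs = [], []
    for e in by_role["test"]:
        img = input_image(e)
        proba = model.predict_proba(img)
        stem = Path(e["noisy"]).stem
        _io.write_proba(pred_dir / f"{stem}_proba.tiff", proba)
        mask = (proba[..., 1] > 0.5).astype(np.uint8)
        _io.write_mask(pred_dir / f"{stem}_coarse.png", mask)
        if use_crf:
            _, labeling = refine(proba, img, cfg.crf)
            mask = labeling.astype(np.uint8)
            _io.write_mask(pred_dir / f"{stem}_refined.png", mask)
        truth = _io.read_mask(manifest.root / e["mask"])
        reports.append(evaluate_masks(mask, truth))
        if truth.any() and not truth.all():
            aucs.append(roc_auc(proba[..., 1], truth).auc)
    entry["t_end"] = time.time()

    report = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "test_patients": sorted({e["patient_id"] for e in by_role["test"]}),
        "metrics": aggregate_reports(reports, mode="per-image"),
        "mean_auc": float(np.mean(aucs)) if aucs else None,
        "val_f1_best": max((h.get("val_f1", 0.0) for h in history), default=None),
    }
    (wd / "report.json").write_text(json.dumps(report, indent=1))
    (wd / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return PipelineResult(config=cfg, report=report, run_log=log, workdir=wd)


def run_ablation(base_config: PipelineConfig,
                 verbose: bool = False) -> dict[str, dict]:
    """Run all four modes on identical phantoms, split and seeds.

    Returns {mode: report}; the shared dataset lives under
    ``workdir/data`` so arms are strictly comparable.
    """
    base_wd = Path(base_config.workdir)
    data_dir = base_wd / "data"
    results = {}
    for mode in MODES:
        cfg = dataclasses.replace(base_config, mode=mode,
                                  workdir=base_wd / mode, data_dir=data_dir)
        results[mode] = run_pipeline(cfg, verbose=verbose).report
    return results


def format_ablation_table(results: dict[str, dict]) -> str:
    """Four-arm comparison table (mean ± sd, percent) per metric."""
    header = f"{'model':<10}" + "".join(
        f"{c:>20}" for c in ("precision (%)", "sensitivity (%)",
                             "specificity (%)", "F1-score (%)"))
    lines = [header]
    for mode in MODES:
        m = results[mode]["metrics"]
        cells = []
        for key in ("precision", "sensitivity", "specificity", "f1"):
            cells.append(f"{100 * m[key]['mean']:.2f} ± {100 * m[key]['sd']:.2f}")
        lines.append(f"{mode:<10}" + "".join(f"{c:>20}" for c in cells))
    return "\n".join(lines)
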