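"""Stage orchestration: synth → preprocess → segment → train/crossval/loocv/compare.

Each stage is a pure function of (inputs, config, seed) that writes its
outputs plus a structured log line into the work directory; a run manifest
records the config hash and seeds so any deterministic stage can be
reproduced byte-for-byte. Stages read the previous stage's on-disk outputs,
so a partial pipeline can be resumed or re-run selectively.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, imaging, model, preprocess, synth
from .io import load_manifest
from .montage import LABELS

__all__ = ["PipelineConfig", "DependencyError", "run_pipeline", "load_config"]

STAGES = ("synth", "preprocess", "segment", "train", "crossval", "loocv", "compare")


class DependencyError(RuntimeError):
    """An earlier stage's outputs are missing."""


@dataclass
class PipelineConfig:
    work_dir: Path
    seed: int = 0
    manifest: Path | None = None  # external dataset; omit when using synth
    synth: dict = field(default_factory=dict)
    denoise: preprocess.DenoiseConfig = field(default_factory=preprocess.DenoiseConfig)
    window_s: float = 5.0
    image_format: str = "png"
    variant: str = "baseline"
    train: model.TrainConfig = field(default_factory=model.TrainConfig)
    k: int = 10
    batch_sizes: tuple[int, ...] = ()  # crossval sweep; empty = train batch only
    compare_reports: tuple[Path, ...] = ()

    def model_config(self) -> model.ModelConfig:
        variants = model.ablation_configs()
        if self.variant not in variants:
            raise ValueError(f"unknown model variant {self.variant!r}; "
                             f"choose from {sorted(variants)}")
        return variants[self.variant]


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Read a YAML pipeline config; an explicit ``seed`` overrides the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(
        work_dir=Path(raw.get("work_dir", "eegstage-run")),
        seed=int(raw.get("seed", 0)),
        manifest=Path(raw["manifest"]) if raw.get("manifest") else None,
        synth=raw.get("synth", {}),
        denoise=preprocess.DenoiseConfig(**raw.get("denoise", {})),
        window_s=float(raw.get("imaging", {}).get("window_s", 5.0)),
        image_format=raw.get("imaging", {}).get("format", "png"),
        variant=raw.get("model", {}).get("variant", "baseline"),
        train=model.TrainConfig(**raw.get("train", {})),
        k=int(raw.get("evaluate", {}).get("k", 10)),
        batch_sizes=tuple(raw.get("evaluate", {}).get("batch_sizes", [])),
        compare_reports=tuple(Path(p) for p in raw.get("evaluate", {}).get("compare", [])),
    )
    if seed is not None:
        cfg.seed = seed
        cfg.train = dataclasses.replace(cfg.train, seed=seed)
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(cfg).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log(work: Path, record: dict) -> None:
    with open(work / "run.log", "a") as fh:
        fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# stages


def _stage_synth(cfg: PipelineConfig) -> Path:
    opts = dict(cfg.synth)
    profile_kind = opts.pop("profiles", "default")
    profiles = synth.null_profiles() if profile_kind == "null" else synth.default_profiles()
    spec = synth.SynthSpec(
        n_per_class=int(opts.pop("n_per_class", 12)),
        duration_s=float(opts.pop("duration_s", 300.0)),
        rate_cycle=tuple(opts.pop("rate_cycle", (256,))),
        subject_sigma=float(opts.pop("subject_sigma", 0.2)),
        profiles=profiles,
        seed=cfg.seed,
        **opts,
    )
    manifest, recordings = synth.generate_dataset(spec)
    return synth.save_dataset(manifest, recordings, cfg.work_dir / "data")


def _stage_preprocess(cfg: PipelineConfig) -> Path:
    manifest_path = cfg.manifest or cfg.work_dir / "data" / "manifest.csv"
    if not Path(manifest_path).exists():
        raise DependencyError(f"preprocess needs a manifest ({manifest_path}); "
                              "run the synth stage or point 'manifest' at a dataset")
    manifest = load_manifest(manifest_path)
    out_dir = cfg.work_dir / "denoised"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    entries = []
    for entry in manifest.entries:
        rec = manifest.load_recording(entry)
        rec256 = preprocess.downsample(rec)
        den = preprocess.swt_denoise(rec256, cfg.denoise)
        q = preprocess.quality(rec256, den)
        from .io import write_recording

        write_recording(den, out_dir / f"{entry.subject_id}.txt", "matrix")
        rows.append({"subject_id": entry.subject_id, "label": entry.label,
                     "psnr_db": q.psnr, "mse_uv2": q.mse})
        entries.append(dataclasses.replace(entry, path=f"{entry.subject_id}.txt", fs=256))
    pd.DataFrame(rows).to_csv(out_dir / "quality.csv", index=False)
    from .io import DatasetManifest, save_manifest

    save_manifest(DatasetManifest(entries=entries, root=out_dir), out_dir / "manifest.csv")
    return out_dir


def _stage_segment(cfg: PipelineConfig) -> Path:
    den_manifest = cfg.work_dir / "denoised" / "manifest.csv"
    if not den_manifest.exists():
        raise DependencyError("segment needs denoised recordings; run the preprocess stage")
    manifest = load_manifest(den_manifest)
    out_dir = cfg.work_dir / "segments"
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in manifest.iter_recordings():
        for seg in imaging.segment(rec, cfg.window_s):
            img = imaging.to_image(seg)
            name = imaging.image_filename(img, cfg.image_format)
            imaging.write_image(img, out_dir / name, cfg.image_format)
            rows.append({"file": name, "subject_id": seg.subject_id,
                         "label": seg.label, "index": seg.index})
    pd.DataFrame(rows).to_csv(out_dir / "index.csv", index=False)
    return out_dir


def _load_segments(cfg: PipelineConfig):
    seg_dir = cfg.work_dir / "segments"
    index = seg_dir / "index.csv"
    if not index.exists():
        raise DependencyError("this stage needs segment images; run the segment stage")
    df = pd.read_csv(index, dtype={"subject_id": str})
    X = np.stack([imaging.read_image(seg_dir / f).pixels for f in df["file"]])
    return X, df["label"].to_numpy(), df["subject_id"].to_numpy()


def _cnn_fit_predict(cfg: PipelineConfig):
    arch = model.build_model(cfg.model_config())

    def fit_predict(xtr, ytr, xte):
        trained = model.train(arch, xtr, ytr, cfg.train)
        fit_predict.last_epochs_run = trained.epochs_run
        return model.predict(trained, xte)

    return fit_predict


def _stage_train(cfg: PipelineConfig) -> Path:
    X, y, _ = _load_segments(cfg)
    arch = model.build_model(cfg.model_config())
    trained = model.train(arch, X, y, cfg.train)
    out_dir = cfg.work_dir / "model"
    out_dir.mkdir(parents=True, exist_ok=True)
    model.save_model(trained, out_dir / "model.npz")
    pd.DataFrame(trained.history).to_csv(out_dir / "history.csv", index=False)
    (out_dir / "summary.txt").write_text(arch.summary() + "\n")
    return out_dir


def _report_frame(reports: list[evaluate.FoldReport], summary: dict) -> pd.DataFrame:
    rows = [
        {"fold": r.fold_index, "acc": round(r.acc, 2), "sen": round(r.sen, 2),
         "spe": round(r.spe, 2), "epochs": r.epochs_run}
        for r in reports
    ]
    for stat in ("mean", "sd", "ci95_low", "ci95_high"):
        rows.append({"fold": stat, **{m: round(summary[m][stat], 2) for m in ("acc", "sen", "spe")}})
    return pd.DataFrame(rows)


def _stage_crossval(cfg: PipelineConfig) -> Path:
    X, y, _ = _load_segments(cfg)
    out = None
    for bs in cfg.batch_sizes or (cfg.train.batch_size,):
        sub = dataclasses.replace(cfg, train=dataclasses.replace(cfg.train, batch_size=int(bs)))
        reports, summary = evaluate.run_kfold(
            X, y, _cnn_fit_predict(sub), k=cfg.k, seed=cfg.seed
        )
        out = cfg.work_dir / f"crossval_{cfg.variant}_bs{bs}.csv"
        _report_frame(reports, summary).to_csv(out, index=False)
    return out


def _stage_loocv(cfg: PipelineConfig) -> Path:
    X, y, subjects = _load_segments(cfg)
    scores = evaluate.run_loocv(X, y, subjects, _cnn_fit_predict(cfg))
    out = cfg.work_dir / f"loocv_{cfg.variant}_bs{cfg.train.batch_size}.csv"
    pd.DataFrame(
        [{"subject_id": s, "accuracy": round(a, 2)} for s, a in scores.items()]
    ).to_csv(out, index=False)
    return out


def _stage_compare(cfg: PipelineConfig) -> Path:
    if len(cfg.compare_reports) != 2:
        raise DependencyError("compare needs exactly two crossval report paths "
                              "(evaluate.compare in the config)")
    cols = []
    for path in cfg.compare_reports:
        if not Path(path).exists():
            raise DependencyError(f"compare input missing: {path}; run crossval first")
        df = pd.read_csv(path)
        fold_rows = df[pd.to_numeric(df["fold"], errors="coerce").notna()]
        cols.append(fold_rows["acc"].to_numpy(dtype=float))
    t, p_t = evaluate.paired_ttest(cols[0], cols[1])
    w, p_w = evaluate.wilcoxon_exact(cols[0], cols[1])
    out = cfg.work_dir / "compare.json"
    out.write_text(json.dumps({
        "reports": [str(p) for p in cfg.compare_reports],
        "paired_t": {"t": t, "p": p_t},
        "wilcoxon_exact": {"w": w, "p": p_w},
    }, indent=1))
    return out


_STAGE_FNS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "segment": _stage_segment,
    "train": _stage_train,
    "crossval": _stage_crossval,
    "loocv": _stage_loocv,
    "compare": _stage_compare,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES[:3]) -> dict:
    """Run the requested stages in canonical order; returns the run report."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    cfg.work_dir = Path(cfg.work_dir)
    cfg.work_dir.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": _config_hash(cfg), "seed": cfg.seed, "stages": {}}
    for name in ordered:
        t0 = time.perf_counter()
        out = _STAGE_FNS[name](cfg)
        wall = time.perf_counter() - t0
        report["stages"][name] = {"output": str(out), "wall_s": round(wall, 2)}
        _log(cfg.work_dir, {"stage": name, "output": str(out),
                            "wall_s": round(wall, 2), "seed": cfg.seed})
    (cfg.work_dir / "run_manifest.json").write_text(json.dumps(report, indent=1))
    return report
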