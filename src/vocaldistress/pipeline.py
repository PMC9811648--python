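"""Stage orchestration: simulate -> extract -> screen -> select -> cluster -> train -> evaluate.

Each stage reads its upstream artifacts from the run directory, writes its
outputs as CSV/JSON, and appends a manifest entry recording the stage,
seed, parameters and SHA-256 hashes of its inputs, so every number in any
report traces back to a config and seed.  Stages are plain functions;
`run_stage("all", cfg)` runs the whole chain in order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audio_io, boost, clustering, evaluation, gamm, screening, synthetic
from .features import FEATURE_NAMES, ExtractionConfig, extract_feature_table

__all__ = ["PipelineConfig", "DependencyError", "run_stage", "STAGES"]

STAGES = ["simulate", "extract", "screen", "select", "cluster", "train", "evaluate"]


class DependencyError(RuntimeError):
    """An upstream stage's artifact is missing."""


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_run"
    seed: int = 0
    # simulate
    n_callers: int = 6
    segments_per_call: int = 3
    segment_duration_s: float = 0.8
    silence_fraction: float = 0.3
    # preprocess/extract
    preemphasis_alpha: float = audio_io.DEFAULT_PREEMPHASIS
    silence_dbfs: float = audio_io.DEFAULT_SILENCE_DBFS
    cutoff: int = audio_io.DEFAULT_CUTOFF
    # screening
    r_threshold: float = screening.DEFAULT_R_THRESHOLD
    # gamm
    n_basis: int = 9
    alpha: float = 0.05
    # clustering
    k_range: tuple = (1, 5)
    # boosting
    nu: float = 0.1
    mstop_grid: tuple = (25, 50, 100)
    inner_folds: int = 10
    use_cluster_pcs: bool = True
    n_boot: int = 500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("k_range", "mstop_grid"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_append(out: Path, stage: str, cfg: PipelineConfig, inputs: list[Path], outputs: list[Path]) -> None:
    entry = {
        "stage": stage,
        "seed": cfg.seed,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else []
    manifest = [e for e in manifest if e["stage"] != stage] + [entry]
    path.write_text(json.dumps(manifest, indent=2))


def _require(out: Path, name: str, produced_by: str) -> Path:
    p = out / name
    if not p.exists():
        raise DependencyError(f"missing artifact {name!r}: run stage {produced_by!r} first")
    return p


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = synthetic.SimConfig(
        segment_duration_s=cfg.segment_duration_s,
        silence_fraction=cfg.silence_fraction,
        cutoff=cfg.cutoff,
        seed=cfg.seed,
    )
    synthetic.synthesize_call_audio(
        sim, out_dir=out / "audio", n_callers=cfg.n_callers,
        segments_per_call=cfg.segments_per_call,
    )
    _manifest_append(out, "simulate", cfg, [], sorted((out / "audio").glob("*")))


def _stage_extract(cfg: PipelineConfig, out: Path) -> None:
    audio_dir = out / "audio"
    if not audio_dir.exists():
        raise DependencyError("missing audio directory: run stage 'simulate' first")
    meta = pd.read_csv(_require(out, "audio/metadata.csv", "simulate"))
    recordings, annotations = [], []
    for row in meta.itertuples():
        rec = audio_io.read_wav(audio_dir / f"{row.call_id}.wav")
        rec.call_id, rec.caller_id, rec.sex = row.call_id, row.caller_id, row.sex
        rec = audio_io.normalize_preemphasize(audio_io.to_pcm16(rec), cfg.preemphasis_alpha)
        recordings.append(rec)
        annotations.extend(
            audio_io.read_audacity_labels(
                audio_dir / f"{row.call_id}.txt", cutoff=cfg.cutoff, call_id=row.call_id
            )
        )
    table = extract_feature_table(
        recordings, annotations, ExtractionConfig(silence_dbfs=cfg.silence_dbfs)
    )
    table = table.dropna(subset=FEATURE_NAMES)  # listwise removal of unusable frames
    table.to_csv(out / "frames.csv", index=False)
    _manifest_append(out, "extract", cfg, sorted(audio_dir.glob("*")), [out / "frames.csv"])


def _stage_screen(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(_require(out, "frames.csv", "extract"))
    report = screening.prune_correlated(table, cfg.r_threshold, feature_cols=list(FEATURE_NAMES))
    keep_cols = [c for c in table.columns if c not in set(FEATURE_NAMES) - set(report.kept)]
    table[keep_cols].to_csv(out / "frames_screened.csv", index=False)
    (out / "screening.json").write_text(json.dumps(report.to_dict(), indent=2))
    _manifest_append(out, "screen", cfg, [out / "frames.csv"],
                     [out / "frames_screened.csv", out / "screening.json"])


def _stage_select(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(_require(out, "frames_screened.csv", "screen"))
    kept = json.loads(_require(out, "screening.json", "screen").read_text())["kept"]
    spec = gamm.GammSpec(predictors=kept, n_basis=cfg.n_basis, alpha=cfg.alpha)
    design = gamm.build_design(table, spec)
    fit = gamm.fit_pgamm(design, table["label"].to_numpy())
    tt = gamm.term_table(fit, table=table)
    tt.to_csv(out / "term_table.csv", index=False)
    sel = gamm.select_predictors(fit, alpha=cfg.alpha, table=table)
    (out / "selection.json").write_text(json.dumps({
        "selected": [list(p) for p in sel.selected],
        "features": sel.features,
        "n_selected": sel.n_selected,
        "fallback": sel.fallback,
        "deviance_explained": fit.deviance_explained,
    }, indent=2))
    _manifest_append(out, "select", cfg, [out / "frames_screened.csv"],
                     [out / "term_table.csv", out / "selection.json"])


def _stage_cluster(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(_require(out, "frames_screened.csv", "screen"))
    _require(out, "selection.json", "select")  # stage ordering contract
    # clusters and their principal components are computed on the full
    # screened feature space: the cluster variables are meant to add signal
    # beyond the selected predictors, which a rotation of the selected
    # features alone could never do
    feats = json.loads((out / "screening.json").read_text())["kept"]
    flags0: list[str] = []
    scree, k, flags = clustering.scree_select(
        table, range(cfg.k_range[0], cfg.k_range[1] + 1), seed=cfg.seed, feature_cols=feats
    )
    k_use = max(k, 2)
    model = clustering.kmeans_fit(table, k_use, seed=cfg.seed, feature_cols=feats)
    if k_use == 2:
        validation = clustering.validate_clusters(table, model.assignments, feature_cols=feats)
    else:
        two = clustering.kmeans_fit(table, 2, seed=cfg.seed, feature_cols=feats)
        validation = clustering.validate_clusters(table, two.assignments, feature_cols=feats)
        flags.append(f"elbow chose k={k}; validation reported for the 2-cluster solution")
    table2, pc_flags = clustering.cluster_pcs(table, feature_cols=feats)
    table2["cluster"] = model.assignments
    table2.to_csv(out / "frames_clustered.csv", index=False)
    (out / "cluster.json").write_text(json.dumps({
        "scree": {str(kk): v for kk, v in scree.items()},
        "chosen_k": k,
        "flags": flags0 + flags + pc_flags,
        "cramers_v_sex": validation.cramers_v_sex,
        "pseudo_r2": validation.pseudo_r2,
        "direction_summary": validation.direction_summary,
    }, indent=2))
    _manifest_append(out, "cluster", cfg, [out / "frames_screened.csv", out / "selection.json"],
                     [out / "frames_clustered.csv", out / "cluster.json"])


def _stage_train(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(_require(out, "frames_clustered.csv", "cluster"))
    feats = json.loads(_require(out, "selection.json", "select").read_text())["features"]
    y = table["label"].to_numpy()
    pcs = ["pc1", "pc2"] if cfg.use_cluster_pcs else []
    builder = lambda t: boost.make_learners(t, feats, pc_cols=pcs)
    probs = boost.loco_cv(
        table, y, builder, nu=cfg.nu,
        mstop_grid=np.asarray(cfg.mstop_grid), inner_folds=cfg.inner_folds, seed=cfg.seed,
    )
    report = boost.discrimination(
        probs[np.isfinite(probs)], y[np.isfinite(probs)],
        callers=table["caller_id"].to_numpy()[np.isfinite(probs)],
        n_boot=cfg.n_boot, seed=cfg.seed,
    )
    final_model = boost.fit_cgb(table, y, builder(table), nu=cfg.nu, mstop=int(max(cfg.mstop_grid)))
    importance = boost.variable_importance(final_model)
    pd.DataFrame({"oof_prob": probs}).to_csv(out / "oof_probs.csv", index=False)
    (out / "metrics.json").write_text(json.dumps({
        "auroc": report.auroc, "auroc_ci": report.auroc_ci,
        "auprc": report.auprc, "auprc_ci": report.auprc_ci,
        "youden_threshold": report.threshold,
        "confusion": report.confusion,
        "importance": importance,
    }, indent=2))
    _manifest_append(out, "train", cfg, [out / "frames_clustered.csv"],
                     [out / "oof_probs.csv", out / "metrics.json"])


def _stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(_require(out, "frames_clustered.csv", "cluster"))
    probs = pd.read_csv(_require(out, "oof_probs.csv", "train"))["oof_prob"].to_numpy()
    tau = json.loads(_require(out, "metrics.json", "train").read_text())["youden_threshold"]
    tau = float(np.clip(tau, 1e-6, 1 - 1e-6))
    truths = np.where(table["label"].to_numpy() == 1, "high", "low")
    ok = np.isfinite(probs)
    seg = evaluation.aggregate_segments(probs[ok], table["segment_id"].to_numpy()[ok], truths[ok], tau)
    frame_cm = evaluation.confusion_summary(
        np.where(probs[ok] >= tau, "high", "low"), truths[ok], level="frame"
    )
    seg_cm = evaluation.confusion_summary(
        [r.predicted for r in seg], [r.truth for r in seg], level="segment"
    )
    mis = evaluation.misclassification_report(seg)
    mis.to_csv(out / "misclassified_segments.csv", index=False)
    (out / "evaluation.json").write_text(json.dumps({
        "frame": frame_cm.per_class,
        "segment": seg_cm.per_class,
        "summary": evaluation.results_paragraph(frame_cm, seg_cm),
    }, indent=2))
    _manifest_append(out, "evaluate", cfg, [out / "oof_probs.csv", out / "frames_clustered.csv"],
                     [out / "evaluation.json", out / "misclassified_segments.csv"])


_STAGE_FN = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "screen": _stage_screen,
    "select": _stage_select,
    "cluster": _stage_cluster,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}


def run_stage(stage: str, config: PipelineConfig) -> Path:
    """Run one stage (or "all") against config.out_dir; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if stage == "all":
        for s in STAGES:
            _STAGE_FN[s](config, out)
        return out
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ['all']}")
    _STAGE_FN[stage](config, out)
    return out
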