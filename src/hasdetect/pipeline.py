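"""End-to-end orchestration: simulate -> preprocess -> featurize -> train ->
evaluate -> report.

Every run lives in its own directory; the config is archived next to the
outputs together with a manifest carrying the config hash and seeds, so any
output file is traceable and a rerun with the same config reproduces the
metric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers, evaluation, io as hio, synth, trend
from .classifiers import FeatureProfile, TrainConfig
from .core import CHANNELS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "featurize", "train", "evaluate", "report")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "runs/run0"
    profile: str = "desk"  # "desk" | "paper"
    detectors: tuple[str, ...] = ("ws", "wf", "1d")
    studies: tuple[int, ...] = (1, 2, 3)
    k_folds: int = 5
    seed: int = 0
    epochs: int = 60
    batch_size: int = 32
    use_true_centers: bool = False
    synthetic: dict = field(default_factory=dict)

    def synth_config(self) -> synth.SyntheticCohortConfig:
        params = dict(self.synthetic)
        params.setdefault("seed", self.seed)
        if self.profile == "desk":
            return synth.SyntheticCohortConfig.desk(**params)
        return synth.SyntheticCohortConfig(**params)

    def feature_profile(self) -> FeatureProfile:
        L = self.synth_config().segment_length
        if self.profile == "desk":
            return FeatureProfile.desk(segment_length=L)
        return FeatureProfile.paper()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("detectors", "studies"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _run_dir(config: RunConfig) -> Path:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort; write records + ground truth."""
    run = _run_dir(config)
    scfg = config.synth_config()
    records, truth = synth.generate_cohort(scfg)
    rec_dir = run / "records"
    rec_dir.mkdir(exist_ok=True)
    by_animal: dict[str, list] = {}
    for r in records:
        by_animal.setdefault(r.animal_id, []).append(r)
    for animal, recs in by_animal.items():
        hio.write_npz_record(recs, rec_dir / f"{animal}.npz")
    hio.write_annotations(truth, run / "annotations.tsv")
    config.to_yaml(run / "config.yaml")
    return run


def preprocess(config: RunConfig) -> Path:
    """Cut the labeled segment dataset from simulated records.

    HAS segments are located with the power-trend centering procedure
    applied to the minute containing each annotated event (or directly from
    the annotated centers when ``use_true_centers``); non-HAS segments are
    sampled outside HAS intervals.
    """
    run = _run_dir(config)
    scfg = config.synth_config()
    truth = hio.read_annotations(run / "annotations.tsv")
    records = []
    for p in sorted((run / "records").glob("*.npz")):
        records.extend(hio.read_record(p))
    if config.use_true_centers:
        segments, manifest = synth.make_classification_dataset(records, truth, scfg)
    else:
        segments, manifest = _centered_dataset(records, truth, scfg)
    hio.write_segment_store(segments, run / "segments.npz")
    return run


def _centered_dataset(records, truth, scfg):
    """Dataset via the per-minute mark -> centering -> extraction path."""
    from .synth import _spread

    L = scfg.segment_length
    fs = scfg.fs
    counts = scfg.scaled_counts()
    segments, rows = [], []
    rng = np.random.default_rng(scfg.seed + 1)
    minute = int(60 * fs)
    for g in scfg.groups:
        for ch_i, ch in enumerate(CHANNELS):
            ch_recs = [r for r in records if r.group == g and r.channel == ch]
            for rec in ch_recs:
                for ev in truth.get(rec.animal_id, ch):
                    if ev.event_type != "HAS":
                        continue
                    marked = ev.true_center_sample // minute
                    trace = trend.center_seizure(rec, marked)
                    seg = trend.extract_segment(rec, trace.center_sample, L=L)
                    seg.label = "HAS"
                    segments.append(seg)
                    rows.append(seg)
            target_non = counts[g]["non_seizures"][ch_i]
            for rec, n_non in zip(ch_recs, _spread(target_non, len(ch_recs))):
                if n_non:
                    segs = trend.sample_non_has(
                        rec, truth, n=n_non, L=L, seed=int(rng.integers(0, 2**31))
                    )
                    segments.extend(segs)
                    rows.extend(segs)
    manifest = pd.DataFrame(
        [
            {
                "label": s.label,
                "group": s.group,
                "animal_id": s.animal_id,
                "channel": s.channel,
                "center_sample": s.center_sample,
            }
            for s in rows
        ]
    )
    return segments, manifest


def featurize(config: RunConfig) -> Path:
    """Front-end tensors for every detector, stored per detector."""
    run = _run_dir(config)
    segments = hio.read_segment_store(run / "segments.npz")
    profile = config.feature_profile()
    feat_dir = run / "features"
    feat_dir.mkdir(exist_ok=True)
    for det in config.detectors:
        X = classifiers.featurize(det, segments, profile)
        np.savez(feat_dir / f"{det}.npz", X=X)
    return run


def _load_manifest(run: Path) -> pd.DataFrame:
    return pd.read_csv(run / "segments.manifest.tsv", sep="\t")


def _schemes(config: RunConfig, manifest: pd.DataFrame) -> list:
    schemes = []
    if 1 in config.studies:
        schemes += evaluation.build_loocv_schemes(manifest, include_sham=True)
    if 2 in config.studies:
        schemes += evaluation.build_loocv_schemes(manifest, include_sham=False)
    if 3 in config.studies:
        schemes += evaluation.build_kfold(manifest, k=config.k_folds, seed=config.seed)
    return schemes


def train(config: RunConfig) -> Path:
    """Train every detector on every scheme; write checkpoints/predictions."""
    run = _run_dir(config)
    manifest = _load_manifest(run)
    y = (manifest["label"] == "HAS").to_numpy().astype(int)
    profile = config.feature_profile()
    desk = config.profile == "desk"
    out_rows = []
    for det in config.detectors:
        with np.load(run / "features" / f"{det}.npz") as data:
            X = data["X"]
        spec = classifiers.build_spec(det, profile, desk=desk)
        for scheme in _schemes(config, manifest):
            tag = f"{det}_s{scheme.study_id}_{scheme.scheme}"
            t0 = time.time()
            clf = classifiers.train_classifier(
                spec,
                X[scheme.train_idx],
                y[scheme.train_idx],
                TrainConfig(
                    epochs=config.epochs,
                    batch_size=config.batch_size,
                    seed=config.seed,
                ),
                detector=det,
            )
            scores, labels = classifiers.predict(clf, X[scheme.test_idx])
            ckpt_dir = run / "checkpoints"
            ckpt_dir.mkdir(exist_ok=True)
            classifiers.save_checkpoint(clf, ckpt_dir / f"{tag}.npz")
            pred_dir = run / "predictions"
            pred_dir.mkdir(exist_ok=True)
            np.savez(
                pred_dir / f"{tag}.npz",
                scores=scores,
                labels=labels,
                truth=y[scheme.test_idx],
                test_idx=scheme.test_idx,
            )
            logger.info("trained %s in %.1f s", tag, time.time() - t0)
            out_rows.append(
                {
                    "detector": det,
                    "study": scheme.study_id,
                    "scheme": scheme.scheme,
                    "final_train_acc": clf.history["train_acc"][-1],
                    "final_val_acc": clf.history["val_acc"][-1],
                    "seconds": round(time.time() - t0, 1),
                }
            )
    pd.DataFrame(out_rows).to_csv(run / "training_log.tsv", sep="\t", index=False)
    return run


def evaluate(config: RunConfig) -> pd.DataFrame:
    """Confusion metrics + AUC per detector/study/scheme, as a TSV table."""
    run = _run_dir(config)
    rows = []
    for p in sorted((run / "predictions").glob("*.npz")):
        det, study, scheme = _parse_tag(p.stem)
        with np.load(p) as data:
            m = evaluation.confusion(data["truth"], data["labels"])
            m.auc = evaluation.roc_auc(data["scores"], data["truth"]).auc
        rows.append(
            {"detector": det, "study": study, "scheme": scheme, **m.as_row()}
        )
    table = pd.DataFrame(rows).sort_values(["detector", "study", "scheme"])
    table.to_csv(run / "metrics.tsv", sep="\t", index=False)
    return table


def _parse_tag(stem: str):
    det, s_part, scheme = stem.rsplit("_", 2)
    return det, int(s_part[1:]), int(scheme)


def report(config: RunConfig) -> pd.DataFrame:
    """Study-level summaries (mean +/- SD) and ROC plots."""
    run = _run_dir(config)
    table = pd.read_csv(run / "metrics.tsv", sep="\t")
    summaries = []
    for (det, study), grp in table.groupby(["detector", "study"]):
        ms = [
            evaluation.ConfusionMetrics(
                tp=r.TP, fp=r.FP, fn=r.FN, tn=r.TN, auc=r.auc
            )
            for r in grp.itertuples()
        ]
        summaries.append(
            {"detector": det, "study": study, **evaluation.summarize_study(ms)}
        )
    summary = pd.DataFrame(summaries)
    summary.to_csv(run / "summary.tsv", sep="\t", index=False)
    _plot_rocs(config, run)
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": list(STAGES),
        "outputs": sorted(str(p.relative_to(run)) for p in run.rglob("*") if p.is_file()),
    }
    (run / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def _plot_rocs(config: RunConfig, run: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred_dir = run / "predictions"
    fig, axes = plt.subplots(
        1, len(config.detectors), figsize=(4 * len(config.detectors), 4), squeeze=False
    )
    for ax, det in zip(axes[0], config.detectors):
        curves = []
        for p in sorted(pred_dir.glob(f"{det}_*.npz")):
            with np.load(p) as data:
                if np.unique(data["truth"]).size < 2:
                    continue
                curves.append(evaluation.roc_auc(data["scores"], data["truth"]))
        if not curves:
            continue
        grid, mean_tpr, sd_tpr = evaluation.mean_roc(curves)
        ax.plot(grid, mean_tpr, label=f"mean AUC {np.mean([c.auc for c in curves]):.3f}")
        ax.fill_between(grid, mean_tpr - sd_tpr, np.minimum(mean_tpr + sd_tpr, 1), alpha=0.3)
        ax.plot([0, 1], [0, 1], "k:", lw=0.5)
        ax.set_title(det)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(run / "roc.png", dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """All stages in order; aborts with the failing stage's name."""
    stage_fns = {
        "simulate": simulate,
        "preprocess": preprocess,
        "featurize": featurize,
        "train": train,
        "evaluate": evaluate,
        "report": report,
    }
    result = None
    for stage in STAGES:
        t0 = time.time()
        try:
            result = stage_fns[stage](config)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise StageError(stage, exc) from exc
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    return result
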