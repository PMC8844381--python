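"""End-to-end orchestration: simulate -> fuse -> annotate -> train ->
predict -> smooth -> evaluate.

A single ``PipelineConfig`` nests every stage's configuration plus a
master seed.  Stage seeds are derived by hashing the master seed with
the stage name, so adding or reordering stages never perturbs the
randomness of earlier ones, and the whole run is reproducible from the
master seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import AnnotationConfig, annotate_compaction, annotate_polarization_onset, label_frames
from .classify import EnsembleConfig, ensemble_predict, split_cohort, train_ensemble
from .evaluate import EvalConfig, evaluate_frames, pearson_corr, wilcoxon_signed_rank
from .fusion import FusionConfig, fuse_recording
from .synthetic_embryo import SynthConfig, generate_cohort
from .temporal import call_onset, smooth_labels, time_discrepancy

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (1 << 31)


@dataclass
class PipelineConfig:
    """Nested configuration of the full synthetic-cohort experiment."""

    n_train: int = 40
    n_test: int = 10
    smoothing_window: int = 3
    master_seed: int = 0
    compaction_range: tuple = (4, 9)
    lag_range: tuple = (2, 5)
    synth: SynthConfig = field(default_factory=SynthConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd")


_NESTED = {
    "synth": SynthConfig,
    "fusion": FusionConfig,
    "annotation": AnnotationConfig,
    "ensemble": EnsembleConfig,
    "eval": EvalConfig,
}


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a JSON file path or a dict; defaults
    are filled in, unknown keys rejected with the offending name."""
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = dict(source)
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in top_fields:
            raise ValueError(f"unknown config key {key!r}")
        if key in _NESTED:
            cls = _NESTED[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            for sub in value:
                if sub not in sub_fields:
                    raise ValueError(f"unknown config key {key}.{sub}")
            value = cls(**{k: _detuple(v) for k, v in value.items()})
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    if cfg.smoothing_window % 2 == 0:
        raise ValueError("window must be odd")
    return cfg


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Run the full synthetic experiment and return (and optionally
    write) the evaluation report."""
    log = []

    def _log(stage, **info):
        log.append({"stage": stage, **_jsonify(info)})

    # -- simulate -------------------------------------------------------------
    n_total = cfg.n_train + cfg.n_test
    synth_seed = stage_seed(cfg.master_seed, "simulate")
    cohort = generate_cohort(
        n_total,
        template=cfg.synth,
        seed=synth_seed,
        compaction_range=cfg.compaction_range,
        lag_range=cfg.lag_range,
    )
    _log("simulate", n_embryos=n_total, seed=synth_seed)

    # -- fuse -----------------------------------------------------------------
    fused = {rec.id: fuse_recording(rec, cfg.fusion) for rec, _ in cohort}
    truths = {truth.recording_id: truth for _, truth in cohort}
    _log("fuse", n_sequences=len(fused))

    # -- annotate (from fluorescence-derived cap fractions) -------------------
    labels = {}
    for rid, truth in truths.items():
        onset = annotate_polarization_onset(truth.cap_fraction_series, cfg.annotation)
        labels[rid] = label_frames(onset, len(truth.cap_fraction_series))
    _log("annotate", n_recordings=len(labels))

    # -- split ----------------------------------------------------------------
    split_seed = stage_seed(cfg.master_seed, "split")
    train_ids, test_ids = split_cohort(
        sorted(fused), counts=(cfg.n_train, cfg.n_test), seed=split_seed
    )
    _log("split", train=len(train_ids), test=len(test_ids), seed=split_seed)

    # -- train ----------------------------------------------------------------
    train_frames = np.concatenate([fused[r].dic for r in train_ids])
    train_labels = np.concatenate([labels[r] for r in train_ids])
    ens_cfg = dataclasses.replace(
        cfg.ensemble, seed=stage_seed(cfg.master_seed, "train")
    )
    models = train_ensemble(train_frames, train_labels, ens_cfg)
    _log(
        "train",
        n_frames=len(train_frames),
        members=len(models),
        train_accuracy=[m.train_accuracy for m in models],
    )

    # -- predict + smooth + onset --------------------------------------------
    onset_rows = {}
    all_scores, all_pred, all_true = [], [], []
    model_onsets, true_onsets, compaction_onsets = [], [], []
    model_disc, compaction_disc = [], []
    for rid in test_ids:
        seq = fused[rid]
        truth = truths[rid]
        probs, pred = ensemble_predict(models, seq.dic, ens_cfg)
        smoothed = smooth_labels(pred, cfg.smoothing_window)
        onset = call_onset(smoothed)
        n = len(pred)
        true_onset = int(truth.polarization_onset_idx)
        disc = time_discrepancy(onset, true_onset, seq.frame_interval_s, n)
        comp_idx = annotate_compaction(truth.angle_series_deg, cfg.annotation)
        comp_disc = time_discrepancy(comp_idx, true_onset, seq.frame_interval_s, n)
        onset_rows[rid] = {
            "called_onset": onset,
            "true_onset": true_onset,
            "compaction_onset": comp_idx,
            "frame_interval_s": seq.frame_interval_s,
            "model_discrepancy_s": disc,
            "compaction_discrepancy_s": comp_disc,
        }
        all_scores.append(probs[:, 1])
        all_pred.append(pred)
        all_true.append(labels[rid])
        model_onsets.append(n if onset is None else onset)
        compaction_onsets.append(n if comp_idx is None else comp_idx)
        true_onsets.append(true_onset)
        model_disc.append(disc)
        compaction_disc.append(comp_disc)

    # -- evaluate -------------------------------------------------------------
    eval_cfg = dataclasses.replace(cfg.eval, seed=stage_seed(cfg.master_seed, "eval"))
    report = evaluate_frames(
        np.concatenate(all_scores),
        np.concatenate(all_pred),
        np.concatenate(all_true),
        eval_cfg,
    )
    paired = np.abs(np.asarray(compaction_disc)) - np.abs(np.asarray(model_disc))
    tests = {}
    if np.any(paired != 0):
        w, p = wilcoxon_signed_rank(paired)
        tests["wilcoxon_model_vs_compaction"] = {"W": w, "p": p}
    if np.std(model_onsets) > 0 and np.std(compaction_onsets) > 0:
        tests["pearson_model_vs_compaction"] = pearson_corr(
            model_onsets, compaction_onsets
        )
    result = {
        "config": _jsonify(dataclasses.asdict(cfg)),
        "frame_metrics": _jsonify(report.to_dict()),
        "onsets": _jsonify(onset_rows),
        "tests": _jsonify(tests),
        "mean_abs_model_discrepancy_s": float(np.mean(np.abs(model_disc))),
        "mean_abs_compaction_discrepancy_s": float(np.mean(np.abs(compaction_disc))),
        "log": log,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(result, indent=1, sort_keys=True)
        )
    return result
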