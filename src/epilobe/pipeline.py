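"""End-to-end orchestration: synthesis/ingestion -> preprocessing ->
augmentation (train only) -> spectrograms -> backbone features ->
SVGL-HBO selection -> FC detection -> fuzzy activity index -> Wave-GRU
lobe localization -> metrics.

Every stage is seeded from a single pipeline seed; two runs with the
same configuration produce identical reports.  The default
configuration is the desk-scale synthetic benchmark: 10 subjects,
8 channels, 64 x 64 spectrograms, 1/8-width backbone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import augment as aug
from . import backbone as bb
from . import fuzzy as fz
from . import hbo
from . import metrics as mx
from . import owgru as og
from . import preprocess as pp
from . import synth
from .recording import LOBES
from .spectrogram import StftParams, spectrogram

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # synthetic data
    n_subjects: int = 10
    duration: float = 120.0
    events_per_subject: int = 2
    sampling_rate: float = 256.0
    # preprocessing
    lowpass_hz: float = 30.0
    denoise: bool = True
    window_s: float = 2.0
    overlap: float = 0.5
    exclusion_margin_s: float = 20.0
    balance_ratio: float = 1.0
    # augmentation
    augment_multiplicity: int = 1
    # spectrogram / backbone (desk scale)
    image_size: int = 64
    backbone_scale: float = 0.125
    backbone_epochs: int = 8
    backbone_lr: float = 1e-4
    # feature selection
    hbo_population: int = 15
    hbo_iterations: int = 25
    # detection head
    head_epochs: int = 100
    head_batch: int = 140
    head_lr: float = 1e-4
    # localizer
    owgru_layers: int = 4
    owgru_units: int = 32
    owgru_epochs: int = 40
    owgru_trials: int = 10
    owgru_batch: int = 64


def _segments_for(labeled, cfg, partition):
    rec = labeled.recording
    rec = pp.lowpass_filter(rec, cfg.lowpass_hz)
    if cfg.denoise:
        rec = pp.denoise_recording(rec)
    segs = pp.segment_windows(rec, cfg.window_s, cfg.overlap)
    segs = pp.label_segments(
        segs, labeled.recording.annotations, exclusion_margin_s=cfg.exclusion_margin_s
    )
    segs.partition = partition
    return pp.balance_segments(segs, ratio=cfg.balance_ratio, seed=cfg.seed)


def _assemble(dataset, cfg):
    """Per-partition lists of (segment, label, lobe, subject)."""
    out = {}
    for name, labeled_list in dataset.partitions().items():
        part = "train" if name == "train" else name
        xs, ys, lobes, subjects = [], [], [], []
        for labeled in labeled_list:
            segs = _segments_for(labeled, cfg, part)
            if part == "train" and cfg.augment_multiplicity > 0:
                sx, sy, slobe, _ = aug.augment_segments(
                    segs, multiplicity=cfg.augment_multiplicity, seed=cfg.seed
                )
            else:
                sx, sy, slobe = segs.segments, segs.labels, segs.lobes
            xs.extend(sx)
            ys.extend(sy)
            lobes.extend(slobe)
            subjects.extend([segs.source_subject] * len(sx))
        out[name] = {"segments": xs, "labels": ys, "lobes": lobes, "subjects": subjects}
    return out


def run_pipeline(config=None):
    """Execute the full pipeline on synthetic data; returns the report bundle."""
    cfg = config or PipelineConfig()
    report = {"config": asdict(cfg), "stages": {}}
    rng = np.random.default_rng(cfg.seed)

    logger.info("stage 1/7: synthetic dataset")
    dataset = synth.generate_dataset(
        n_subjects=cfg.n_subjects,
        duration=cfg.duration,
        events_per_subject=cfg.events_per_subject,
        sampling_rate=cfg.sampling_rate,
        seed=cfg.seed,
    )
    parts = _assemble(dataset, cfg)
    for name, p in parts.items():
        n_seiz = sum(1 for l in p["labels"] if l == "seizure")
        report["stages"][f"segments_{name}"] = {"n": len(p["labels"]), "seizure": n_seiz}

    logger.info("stage 2/7: spectrograms")
    stft = StftParams(out_shape=(cfg.image_size, cfg.image_size))
    images = {
        name: [spectrogram(s, cfg.sampling_rate, stft) for s in p["segments"]]
        for name, p in parts.items()
    }

    logger.info("stage 3/7: backbone")
    bcfg = bb.BackboneConfig(
        input_shape=(1, cfg.image_size, cfg.image_size),
        scale=cfg.backbone_scale,
        base_blocks=(1, 1, 1, 1),
        seed=cfg.seed,
    )
    model = bb.build_backbone(bcfg)
    y_train = np.array([1 if l == "seizure" else 0 for l in parts["train"]["labels"]])
    bb.train_backbone(
        model,
        images["train"],
        y_train,
        epochs=cfg.backbone_epochs,
        lr=cfg.backbone_lr,
        seed=cfg.seed,
    )
    feats = {name: bb.extract_features(model, imgs) for name, imgs in images.items()}

    logger.info("stage 4/7: SVGL-HBO feature selection")
    hcfg = hbo.HBOConfig(
        population=cfg.hbo_population, iterations=cfg.hbo_iterations, seed=cfg.seed
    )
    selected, hstate = hbo.run(feats["train"], y_train, hcfg)
    report["stages"]["feature_selection"] = {
        "selected": [int(i) for i in selected],
        "n_selected": int(len(selected)),
        "best_fitness": hstate.best_fitness,
    }

    logger.info("stage 5/7: FC detection head")
    head = bb.train_detect(
        feats["train"][:, selected],
        y_train,
        bb.HeadConfig(epochs=cfg.head_epochs, batch_size=cfg.head_batch, lr=cfg.head_lr, seed=cfg.seed),
    )
    y_test = np.array([1 if l == "seizure" else 0 for l in parts["test"]["labels"]])
    pred_cls, _ = bb.detect(head, feats["test"][:, selected])
    y_pred = np.array([1 if c == "epilepsy" else 0 for c in pred_cls])
    det = mx.compute_metrics(mx.confusion_from_labels(y_test, y_pred))
    report["stages"]["detection"] = det.as_dict()
    report["detection_accuracy"] = det.accuracy

    logger.info("stage 6/7: fuzzy Seizure Activity Index")
    train_inputs = [
        fz.compute_fuzzy_inputs(s, cfg.sampling_rate) for s in parts["train"]["segments"]
    ]
    rulebase = fz.fit_memberships(
        [i.alpha for i in train_inputs],
        [i.delta for i in train_inputs],
        [i.entropy for i in train_inputs],
    )
    indices = {}
    for name, p in parts.items():
        vals = []
        for s in p["segments"]:
            df, _ = fz.seizure_activity_index(s, cfg.sampling_rate, rulebase)
            vals.append(df)
        indices[name] = vals
    report["stages"]["fuzzy_index_mean"] = {
        name: float(np.mean(v)) if v else 0.0 for name, v in indices.items()
    }

    logger.info("stage 7/7: Wave-GRU lobe localization")
    channel_names = dataset.train[0].recording.channel_names

    def seiz_sequences(name):
        p = parts[name]
        seqs, labels = [], []
        for s, l, lobe, df in zip(p["segments"], p["labels"], p["lobes"], indices[name]):
            if l == "seizure" and lobe in LOBES:
                seqs.append(
                    og.sequence_features(s, cfg.sampling_rate, channel_names, fuzzy_index=df)
                )
                labels.append(LOBES.index(lobe))
        return np.array(seqs, dtype=np.float32), np.array(labels)

    xtr, ytr = seiz_sequences("train")
    xva, yva = seiz_sequences("validation")
    xte, yte = seiz_sequences("test")
    ocfg = og.OWGRUConfig(
        layers=cfg.owgru_layers,
        units=cfg.owgru_units,
        epochs=cfg.owgru_epochs,
        batch_size=cfg.owgru_batch,
        trials=cfg.owgru_trials,
        seed=cfg.seed,
    )
    if cfg.owgru_trials > 0 and len(xva):
        ocfg, trial_log = og.tune_owgru(xtr, ytr, xva, yva, ocfg)
        report["stages"]["owgru_tuning"] = {
            "n_trials": len(trial_log),
            "best_lr": ocfg.lr,
            "best_dropout": ocfg.dropout,
            "best_optimizer": ocfg.optimizer,
        }
    localizer = og.WaveGRU(xtr.shape[2], ocfg)
    og.train_localizer(localizer, xtr, ytr, ocfg)
    probs = og.localize(localizer, xte)
    lobe_pred = probs.argmax(axis=1)
    loc = mx.multiclass_report(
        np.array([LOBES[i] for i in yte]), np.array([LOBES[i] for i in lobe_pred]), LOBES
    )
    report["stages"]["localization"] = {
        "macro": loc["macro"],
        "accuracy": loc["accuracy"],
        "n_test_segments": int(len(yte)),
    }
    report["localization_accuracy"] = loc["accuracy"]

    manifest = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "numpy": np.__version__,
    }
    report["manifest"] = manifest
    return report
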