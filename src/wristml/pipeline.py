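"""End-to-end orchestration, configuration and model serialisation.

Train: raw labelled recordings -> 30-s epoch features -> a six-class
balanced random forest with OOB emissions + empirical transitions for
behaviour, an eleven-class twin for MET, and the MET scheme — bundled into
one versioned JSON file.  Predict: recording -> resample -> calibrate ->
epochs -> features -> raw votes, Viterbi-smoothed classes, forward-backward
marginals, MET, wear flags and time-of-day imputation -> epoch CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstats, forest as rf, hmm as hmm_mod, met as met_mod, wear
from .features import FEATURE_NAMES, feature_matrix
from .signal import (
    DEFAULT_RATE,
    EPOCH_SECONDS,
    Recording,
    ValidationError,
    calibrate,
    epoch_array,
    epoch_start_times,
    load_recording_csv,
    resample,
)
from .simulate import LabelledRecording, load_labels_csv

BUNDLE_VERSION = 1

#: CLI exit codes: success / validation error / partial failure.
EXIT_OK, EXIT_VALIDATION, EXIT_PARTIAL = 0, 2, 3


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the method's printed constants."""

    epoch_seconds: int = EPOCH_SECONDS
    rate: float = DEFAULT_RATE
    n_trees: int = 100
    features_per_tree: int | None = None
    min_leaf: int = 1
    seed: int = 0
    min_wear_hours: float = 72.0
    max_mean_vm_mg: float = 100.0
    max_clipped_fraction: float = 0.01
    include_met: bool = True
    #: optional explicit behaviour class list; training data carrying labels
    #: outside it is a schema error (None = infer classes from the labels)
    behaviour_classes: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class ModelBundle:
    """Versioned container for everything prediction needs.

    Holds the six-class behaviour model and the eleven-class MET model
    (each a forest + HMM), the MET scheme, the feature-name manifest and a
    config snapshot, so one predict pass emits behaviours and MET.
    """

    behaviour_forest: rf.ForestModel
    behaviour_hmm: hmm_mod.HmmModel
    met_forest: rf.ForestModel | None
    met_hmm: hmm_mod.HmmModel | None
    met_scheme: met_mod.MetScheme | None
    config: RunConfig = field(default_factory=RunConfig)

    def save(self, path) -> None:
        doc = {
            "version": BUNDLE_VERSION,
            "feature_names": list(FEATURE_NAMES),
            "config": dataclasses.asdict(self.config),
            "behaviour": {
                "forest": self.behaviour_forest.to_dict(),
                "hmm": self.behaviour_hmm.to_dict(),
            },
            "met": None
            if self.met_forest is None
            else {
                "forest": self.met_forest.to_dict(),
                "hmm": self.met_hmm.to_dict(),
                "scheme": self.met_scheme.to_dict(),
            },
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        doc = json.loads(Path(path).read_text())
        if doc.get("version") != BUNDLE_VERSION:
            raise ValidationError(
                f"unsupported bundle version {doc.get('version')}"
            )
        if doc["feature_names"] != list(FEATURE_NAMES):
            raise ValidationError("bundle feature manifest does not match")
        met_doc = doc.get("met")
        return cls(
            behaviour_forest=rf.ForestModel.from_dict(doc["behaviour"]["forest"]),
            behaviour_hmm=hmm_mod.HmmModel.from_dict(doc["behaviour"]["hmm"]),
            met_forest=None if met_doc is None else rf.ForestModel.from_dict(met_doc["forest"]),
            met_hmm=None if met_doc is None else hmm_mod.HmmModel.from_dict(met_doc["hmm"]),
            met_scheme=None if met_doc is None else met_mod.MetScheme.from_dict(met_doc["scheme"]),
            config=RunConfig(**doc["config"]),
        )


def _load_labelled_subject(recording_csv, labels_csv) -> LabelledRecording:
    rec_path, lab_path = Path(recording_csv), Path(labels_csv)
    for p in (rec_path, lab_path):
        if not p.exists():
            raise ValidationError(f"missing input file: {p}")
    rec = load_recording_csv(rec_path, subject_id=rec_path.stem)
    labels = load_labels_csv(lab_path)
    return LabelledRecording(
        recording=rec,
        epoch_labels=labels["label"].to_numpy(dtype=object),
        epoch_fine=list(
            zip(labels["fine_activity"].astype(str), labels["met"].astype(float))
        ),
        nonwear_truth=labels.get(
            "nonwear", pd.Series(np.zeros(len(labels)))
        ).to_numpy().astype(bool),
    )


def load_cohort_dir(data_dir) -> list[LabelledRecording]:
    """Load every ``*_recording.csv`` / ``*_labels.csv`` pair in a directory."""
    data_dir = Path(data_dir)
    rec_files = sorted(data_dir.glob("*_recording.csv"))
    if not rec_files:
        raise ValidationError(f"no *_recording.csv files under {data_dir}")
    cohort = []
    for rec_file in rec_files:
        lab_file = data_dir / rec_file.name.replace("_recording", "_labels")
        cohort.append(_load_labelled_subject(rec_file, lab_file))
    return cohort


def train_models(
    cohort: list[LabelledRecording], config: RunConfig
) -> ModelBundle:
    """Fit forest + HMM (and the MET twin) on a labelled cohort."""
    tables = evalstats.cohort_tables(cohort)
    observed = sorted(set(np.concatenate([t.labels for t in tables])))
    if config.behaviour_classes is not None:
        extra = sorted(set(observed) - set(config.behaviour_classes))
        if extra:
            raise ValidationError(
                f"label(s) {extra} not in the configured class scheme "
                f"{list(config.behaviour_classes)}"
            )
        scheme = rf.ClassScheme(tuple(config.behaviour_classes))
    else:
        scheme = rf.ClassScheme(tuple(observed))
    eval_cfg = evalstats.EvalConfig(
        n_trees=config.n_trees,
        min_leaf=config.min_leaf,
        features_per_tree=config.features_per_tree,
        seed=config.seed,
    )
    b_forest, b_hmm = evalstats._fit_fold(tables, "labels", scheme, eval_cfg, config.seed)
    m_forest = m_hmm = m_scheme = None
    if config.include_met:
        fine_scheme = rf.ClassScheme(
            tuple(sorted(set(np.concatenate([t.fine_labels for t in tables]))))
        )
        m_forest, m_hmm = evalstats._fit_fold(
            tables, "fine_labels", fine_scheme, eval_cfg, config.seed + 1
        )
        m_scheme = met_mod.class_met_scores(
            [
                (fine, fine, m)
                for t in tables
                for fine, m in zip(t.fine_labels[t.worn], t.true_met[t.worn])
            ],
            classes=fine_scheme.classes,
        )
    return ModelBundle(
        behaviour_forest=b_forest,
        behaviour_hmm=b_hmm,
        met_forest=m_forest,
        met_hmm=m_hmm,
        met_scheme=m_scheme,
        config=config,
    )


def predict_recording(
    bundle: ModelBundle, recording: Recording
) -> tuple[pd.DataFrame, wear.QcReport]:
    """Full prediction pass over one raw recording.

    Returns the per-epoch prediction frame (raw class, class probabilities,
    smoothed class, marginals, MET, wear and imputation flags) and the QC
    report.  Probabilities of non-worn epochs are imputed from the same
    time-of-day slot on other days where donors exist.
    """
    rec = resample(recording, bundle.config.rate)
    rec, cal = calibrate(rec)
    blocks = epoch_array(rec)
    feats, valid = feature_matrix(blocks)
    mask = wear.detect_nonwear(rec)
    qc = wear.inclusion_check(
        rec,
        mask,
        cal,
        min_wear_hours=bundle.config.min_wear_hours,
        max_mean_vm_mg=bundle.config.max_mean_vm_mg,
        max_clipped_fraction=bundle.config.max_clipped_fraction,
    )
    scheme = bundle.behaviour_forest.scheme
    table = evalstats.SubjectTable(
        subject_id=rec.subject_id,
        features=feats,
        labels=np.array([], dtype=object),
        fine_labels=np.array([], dtype=object),
        true_met=np.array([]),
        worn=mask.worn,
        day_index=np.arange(len(blocks)) // (86400 // EPOCH_SECONDS),
    )
    raw, smoothed, marginals = evalstats._decode_subject(
        table, bundle.behaviour_forest, bundle.behaviour_hmm
    )
    _, probs, _ = rf.predict_votes(bundle.behaviour_forest, feats)
    slot = wear.epoch_slot_index(rec, len(blocks))
    probs_imp, imputed, missing = wear.impute_nonwear(probs, mask, slot)

    df = pd.DataFrame(
        {
            "epoch_start": epoch_start_times(rec, len(blocks)),
            "raw_class": np.asarray(scheme.classes, dtype=object)[raw],
            "smoothed_class": np.asarray(scheme.classes, dtype=object)[smoothed],
            "worn": mask.worn,
            "imputed": imputed,
            "missing": missing,
            "valid_features": valid,
        }
    )
    for j, cls in enumerate(scheme.classes):
        df[f"prob_{cls}"] = probs_imp[:, j]
    for j, cls in enumerate(scheme.classes):
        df[f"marginal_{cls}"] = marginals[:, j]
    if bundle.met_forest is not None:
        m_table = dataclasses.replace(table)
        _, _, m_marginals = evalstats._decode_subject(
            m_table, bundle.met_forest, bundle.met_hmm
        )
        met_series = met_mod.predict_met(m_marginals, bundle.met_scheme)
        met_imp, _, _ = wear.impute_nonwear(met_series.epoch_met, mask, slot)
        df["met"] = met_imp
    return df, qc


def behaviour_fractions(pred: pd.DataFrame, freq: str = "1h") -> pd.DataFrame:
    """Per-window behaviour fractions: epoch predictions for a class over epochs.

    Windows come from resampling epoch starts at ``freq``; fraction columns
    within a window sum to 1.
    """
    s = pred.set_index("epoch_start")["smoothed_class"]
    out = (
        s.groupby(pd.Grouper(freq=freq))
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# Command implementations (the CLI wraps these thinly)
# ---------------------------------------------------------------------------


def cmd_train(data_dir, out_path, config: RunConfig) -> ModelBundle:
    """Train on a labelled cohort directory and write a bundle + report."""
    cohort = load_cohort_dir(data_dir)
    bundle = train_models(cohort, config)
    bundle.save(out_path)
    report = Path(out_path).with_suffix(".report.txt")
    lines = [
        f"subjects: {len(cohort)}",
        f"behaviour classes: {', '.join(bundle.behaviour_forest.scheme.classes)}",
        f"trees: {bundle.behaviour_forest.n_trees}",
        f"n_rare: {bundle.behaviour_forest.n_rare}",
        f"seed: {config.seed}",
    ]
    report.write_text("\n".join(lines) + "\n")
    return bundle


def cmd_predict(bundle_path, recording_paths, out_dir) -> tuple[list, list]:
    """Predict each recording; returns (written paths, per-file errors).

    QC-excluded recordings appear in the summary with their failure reasons
    but produce no epoch output.
    """
    bundle = ModelBundle.load(bundle_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written, errors, summary = [], [], []
    for path in recording_paths:
        path = Path(path)
        try:
            rec = load_recording_csv(path, subject_id=path.stem)
            df, qc = predict_recording(bundle, rec)
            row = {
                "recording": path.name,
                "included": qc.included,
                "wear_hours": round(qc.wear_hours, 2),
                "mean_vm_mg": round(qc.mean_vm_mg, 1),
                "reasons": "; ".join(qc.reasons),
            }
            summary.append(row)
            if qc.included:
                out = out_dir / f"{path.stem}_predictions.csv"
                df.to_csv(out, index=False, date_format="%Y-%m-%dT%H:%M:%S")
                written.append(out)
        except Exception as err:  # per-file failure; continue with the rest
            errors.append((path, err))
            summary.append(
                {"recording": path.name, "included": False, "reasons": f"error: {err}"}
            )
    pd.DataFrame(summary).to_csv(out_dir / "summary.csv", index=False)
    return written, errors


def cmd_evaluate(data_dir, out_dir, config: RunConfig) -> evalstats.CvResult:
    """Run LOSO on a labelled cohort directory and write report files."""
    cohort = load_cohort_dir(data_dir)
    result = evalstats.loso_cv(
        cohort,
        evalstats.EvalConfig(
            n_trees=config.n_trees,
            min_leaf=config.min_leaf,
            features_per_tree=config.features_per_tree,
            seed=config.seed,
            include_met=config.include_met,
        ),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.per_subject.to_csv(out_dir / "per_subject.csv", index=False)
    labels = list(result.scheme.classes)
    pd.DataFrame(result.pooled_confusion, index=labels, columns=labels).to_csv(
        out_dir / "pooled_confusion.csv"
    )
    if result.met_daily is not None:
        result.met_daily.to_csv(out_dir / "met_daily.csv", index=False)
    lines = [
        f"folds: {len(result.per_subject)}",
        f"mean accuracy: {result.mean_accuracy:.3f}",
        f"pooled kappa (raw forest): {result.pooled_kappa_raw:.3f}",
        f"pooled kappa (smoothed): {result.pooled_kappa_smoothed:.3f}",
        f"seed: {config.seed}",
    ]
    if result.met_rmse is not None:
        lines.append(f"MET RMSE (MET-hours/day): {result.met_rmse:.3f}")
        lines.append(f"MET Pearson r: {result.met_r:.3f}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return result
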