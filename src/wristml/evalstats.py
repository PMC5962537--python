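"""Evaluation statistics and leave-one-subject-out cross-validation.

Agreement between predicted and ground-truth behaviour is scored at the
30-s epoch level with Cohen's kappa (chance-corrected agreement) and
row-normalised confusion matrices; energy expenditure with RMSE and
Pearson correlation of daily MET-hours; daily summaries with Bland–Altman
limits of agreement; group contrasts with Cohen's d; and population face
validity with time-of-day behaviour profiles.

``loso_cv`` runs the full pipeline under leave-one-subject-out folds: for
each held-out subject, a balanced random forest, its out-of-bag emission
matrix and the empirical transition matrix are estimated on the remaining
subjects only, then the held-out subject is decoded raw (forest argmax)
and smoothed (Viterbi), and — optionally — an eleven-class model yields
marginal-weighted MET predictions scored against the generator's truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import forest as rf
from . import hmm as hmm_mod
from . import met as met_mod
from .features import feature_matrix
from .signal import EPOCH_SECONDS, ValidationError, epoch_array
from .simulate import LabelledRecording
from .wear import WearMask, wear_bouts


def cohens_kappa(truth, predicted, k: int | None = None) -> float:
    """Chance-corrected agreement between two label sequences.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the raters' marginal
    products.  When both raters are constant and equal (p_e = 1) agreement
    is perfect but chance-uncorrectable; 1.0 is returned with a warning.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if len(t) != len(p) or len(t) == 0:
        raise ValidationError("sequences must have equal, nonzero length")
    labels = np.unique(np.concatenate([t, p]))
    n = len(t)
    ti = np.searchsorted(labels, t)
    pi = np.searchsorted(labels, p)
    counts = np.zeros((len(labels), len(labels)))
    np.add.at(counts, (ti, pi), 1)
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) / n) @ (counts.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("both raters constant and equal; kappa defined as 1", stacklevel=2)
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_counts(truth, predicted, scheme: rf.ClassScheme) -> np.ndarray:
    """Raw k x k confusion counts in scheme order (rows = truth)."""
    t = scheme.encode(truth)
    p = scheme.encode(predicted)
    if len(t) != len(p):
        raise ValidationError("sequences must have equal length")
    counts = np.zeros((scheme.k, scheme.k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return counts


def confusion_rownorm(
    truth, predicted, scheme: rf.ClassScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalised confusion percentages plus an empty-row flag.

    Rows with no ground-truth epochs are reported as zeros and flagged.
    """
    counts = confusion_counts(truth, predicted, scheme)
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    pct = np.zeros_like(counts, dtype=np.float64)
    nz = ~empty
    pct[nz] = 100.0 * counts[nz] / row_sums[nz, None]
    return pct, empty


def kappa_from_confusion(counts: np.ndarray) -> float:
    """Cohen's kappa computed directly from a pooled confusion matrix."""
    n = counts.sum()
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) / n) @ (counts.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def met_agreement(daily_true, daily_pred) -> tuple[float, float]:
    """(RMSE, Pearson r) of paired daily MET-hours values."""
    t = np.asarray(daily_true, dtype=np.float64)
    p = np.asarray(daily_pred, dtype=np.float64)
    if t.shape != p.shape or len(t) < 2:
        raise ValidationError("need >= 2 paired values")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    if np.std(t) == 0 or np.std(p) == 0:
        raise ValidationError("Pearson r undefined for zero-variance input")
    r = float(stats.pearsonr(t, p).statistic)
    return rmse, r


def bland_altman(daily_true, daily_pred) -> tuple[float, float, float]:
    """Daily-level agreement: (bias, lower limit, upper limit).

    Limits of agreement are bias +/- 1.96 x SD of the differences
    (sample SD, ddof=1).
    """
    t = np.asarray(daily_true, dtype=np.float64)
    p = np.asarray(daily_pred, dtype=np.float64)
    if t.shape != p.shape or len(t) < 2:
        raise ValidationError("need >= 2 paired days")
    diff = p - t
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def cohens_d(group_a, group_b) -> float:
    """Standardised mean difference with size-pooled SD."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need >= 2 values")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var <= 0:
        raise ValidationError("pooled SD is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def behaviour_profile(
    timestamps,
    predictions,
    strata=None,
    bin_minutes: int = 60,
) -> pd.DataFrame:
    """Fraction of epochs in each behaviour per time-of-day bin and stratum.

    Returns a tidy frame (stratum, bin, class, fraction); fractions within
    one (stratum, bin) cell sum to 1.  Empty strata are omitted.
    """
    ts = pd.DatetimeIndex(timestamps)
    preds = np.asarray(predictions)
    if strata is None:
        strata = np.array(["all"] * len(preds))
    strata = np.asarray(strata)
    minutes = ts.hour * 60 + ts.minute
    bins = minutes // bin_minutes
    df = pd.DataFrame({"stratum": strata, "bin": bins, "class": preds})
    rows = []
    for (stratum, b), grp in df.groupby(["stratum", "bin"]):
        frac = grp["class"].value_counts(normalize=True)
        for cls, f in frac.items():
            rows.append(
                {"stratum": stratum, "bin": int(b), "class": cls, "fraction": float(f)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvalConfig:
    """Settings for a LOSO run."""

    n_trees: int = 50
    min_leaf: int = 1
    features_per_tree: int | None = None
    seed: int = 0
    include_met: bool = True


@dataclass
class SubjectTable:
    """Per-epoch derived data for one subject, computed once per cohort."""

    subject_id: str
    features: np.ndarray
    labels: np.ndarray
    fine_labels: np.ndarray
    true_met: np.ndarray
    worn: np.ndarray
    day_index: np.ndarray


@dataclass
class CvResult:
    """Outcome of a leave-one-subject-out run.

    ``per_subject`` holds one row per fold (kappa before/after smoothing,
    accuracy); ``pooled_confusion`` sums the per-fold smoothed confusions.
    MET fields are None when MET scoring was disabled.
    """

    per_subject: pd.DataFrame
    pooled_confusion: np.ndarray
    pooled_kappa_raw: float
    pooled_kappa_smoothed: float
    scheme: rf.ClassScheme
    met_daily: pd.DataFrame | None = None
    met_rmse: float | None = None
    met_r: float | None = None
    per_subject_confusion: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_subject["accuracy"].mean())


def cohort_tables(cohort: list[LabelledRecording]) -> list[SubjectTable]:
    """Extract features and ground truth for every subject once."""
    tables = []
    for lrec in cohort:
        blocks = epoch_array(lrec.recording)
        n = min(len(blocks), lrec.n_epochs)
        feats, valid = feature_matrix(blocks[:n])
        if not valid.all():
            warnings.warn(
                f"{lrec.recording.subject_id}: {int((~valid).sum())} invalid epoch(s)",
                stacklevel=2,
            )
        epochs_per_day = int(86400 / EPOCH_SECONDS)
        tables.append(
            SubjectTable(
                subject_id=lrec.recording.subject_id,
                features=feats,
                labels=np.asarray(lrec.epoch_labels[:n]),
                fine_labels=lrec.fine_labels()[:n],
                true_met=lrec.true_met()[:n],
                worn=~lrec.nonwear_truth[:n],
                day_index=np.arange(n) // epochs_per_day,
            )
        )
    return tables


def _bout_sequences(encoded: np.ndarray, worn: np.ndarray) -> list[np.ndarray]:
    """Split an encoded label sequence into contiguous worn bouts."""
    return [encoded[a:b] for a, b in wear_bouts(WearMask(worn=worn))]


def _fit_fold(
    train_tables: list[SubjectTable],
    label_attr: str,
    scheme: rf.ClassScheme,
    config: EvalConfig,
    fold_seed: int,
) -> tuple[rf.ForestModel, hmm_mod.HmmModel]:
    X = np.vstack([t.features[t.worn] for t in train_tables])
    y = np.concatenate([getattr(t, label_attr)[t.worn] for t in train_tables])
    model = rf.train_balanced_forest(
        X,
        y,
        rf.TrainingConfig(
            n_trees=config.n_trees,
            features_per_tree=config.features_per_tree,
            min_leaf=config.min_leaf,
            seed=fold_seed,
        ),
        scheme,
    )
    emission = rf.oob_emission_matrix(model, X, y)
    model.emission = emission
    seqs = [
        s
        for t in train_tables
        for s in _bout_sequences(scheme.encode(getattr(t, label_attr)), t.worn)
    ]
    transition = hmm_mod.estimate_transitions(seqs, scheme.k)
    initial = hmm_mod.empirical_initial(seqs, scheme.k)
    return model, hmm_mod.build_hmm(scheme, initial, transition, emission)


def _decode_subject(
    table: SubjectTable,
    model: rf.ForestModel,
    hmodel: hmm_mod.HmmModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw argmax predictions, Viterbi path, and forward-backward marginals.

    Decoding runs per contiguous wear bout; non-worn epochs carry the raw
    prediction and uniform marginals (they are excluded from scoring).
    """
    _, _, raw = rf.predict_votes(model, table.features)
    smoothed = raw.copy()
    marginals = np.full((len(raw), hmodel.scheme.k), 1.0 / hmodel.scheme.k)
    for a, b in wear_bouts(WearMask(worn=table.worn)):
        smoothed[a:b] = hmm_mod.viterbi(hmodel, raw[a:b])
        marginals[a:b] = hmm_mod.forward_backward(hmodel, raw[a:b])
    return raw, smoothed, marginals


def loso_cv(
    cohort: list[LabelledRecording],
    config: EvalConfig | None = None,
    scheme: rf.ClassScheme | None = None,
) -> CvResult:
    """Leave-one-subject-out cross-validation of the full pipeline.

    Each fold trains on all subjects but one and scores the held-out
    subject's worn epochs, raw (forest argmax) and smoothed (Viterbi).
    With ``include_met`` an eleven-class fine-activity model is trained per
    fold and daily MET-hours are scored against the generator truth.
    """
    if len(cohort) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    config = config or EvalConfig()
    tables = cohort_tables(cohort)
    if scheme is None:
        scheme = rf.ClassScheme(
            tuple(sorted(set(np.concatenate([t.labels for t in tables]))))
        )
    fine_scheme = None
    if config.include_met:
        fine_scheme = rf.ClassScheme(
            tuple(sorted(set(np.concatenate([t.fine_labels for t in tables]))))
        )

    rows = []
    confusions = []
    met_rows = []
    pooled = np.zeros((scheme.k, scheme.k), dtype=np.int64)
    pooled_raw = np.zeros_like(pooled)
    for held_idx, held in enumerate(tables):
        train_tables = [t for i, t in enumerate(tables) if i != held_idx]
        fold_seed = config.seed + 10_000 * held_idx
        model, hmodel = _fit_fold(train_tables, "labels", scheme, config, fold_seed)
        raw, smoothed, _ = _decode_subject(held, model, hmodel)
        truth = scheme.encode(held.labels)
        w = held.worn
        conf = np.zeros((scheme.k, scheme.k), dtype=np.int64)
        np.add.at(conf, (truth[w], smoothed[w]), 1)
        conf_raw = np.zeros_like(conf)
        np.add.at(conf_raw, (truth[w], raw[w]), 1)
        pooled += conf
        pooled_raw += conf_raw
        confusions.append(conf)
        rows.append(
            {
                "subject_id": held.subject_id,
                "n_epochs": int(w.sum()),
                "kappa_raw": cohens_kappa(truth[w], raw[w]),
                "kappa_smoothed": cohens_kappa(truth[w], smoothed[w]),
                "accuracy": float(np.mean(smoothed[w] == truth[w])),
            }
        )

        if config.include_met:
            fmodel, fhmodel = _fit_fold(
                train_tables, "fine_labels", fine_scheme, config, fold_seed + 1
            )
            met_scheme = met_mod.class_met_scores(
                [
                    (fine, fine, m)
                    for t in train_tables
                    for fine, m in zip(t.fine_labels[t.worn], t.true_met[t.worn])
                ],
                classes=fine_scheme.classes,
            )
            _, _, marginals = _decode_subject(held, fmodel, fhmodel)
            pred = met_mod.predict_met(
                marginals[w], met_scheme, day_index=held.day_index[w]
            )
            true_daily = met_mod.daily_met_hours(
                held.true_met[w], held.day_index[w]
            )
            for day in true_daily.index:
                met_rows.append(
                    {
                        "subject_id": held.subject_id,
                        "day": int(day),
                        "true_met_hours": float(true_daily[day]),
                        "pred_met_hours": float(pred.met_hours_per_day[day]),
                    }
                )

    per_subject = pd.DataFrame(rows)
    met_daily = pd.DataFrame(met_rows) if met_rows else None
    met_rmse = met_r = None
    if met_daily is not None and len(met_daily) >= 2:
        met_rmse, met_r = met_agreement(
            met_daily["true_met_hours"], met_daily["pred_met_hours"]
        )
    return CvResult(
        per_subject=per_subject,
        pooled_confusion=pooled,
        pooled_kappa_raw=kappa_from_confusion(pooled_raw),
        pooled_kappa_smoothed=kappa_from_confusion(pooled),
        scheme=scheme,
        met_daily=met_daily,
        met_rmse=met_rmse,
        met_r=met_r,
        per_subject_confusion=confusions,
    )


def prevalence_constant_met_rmse(met_daily: pd.DataFrame) -> float:
    """RMSE of the best constant predictor (mean daily true MET-hours).

    Baseline for the MET pipeline: predicting every subject-day with the
    cohort's prevalence-weighted mean energy expenditure.
    """
    t = met_daily["true_met_hours"].to_numpy()
    return float(np.sqrt(np.mean((t - t.mean()) ** 2)))


def minute_level_confusion(
    truth, predicted, scheme: rf.ClassScheme
) -> np.ndarray:
    """Confusion counts after majority-vote aggregation of epoch pairs.

    Two 30-s epochs form one minute; disagreeing pairs resolve to the first
    epoch's class.
    """
    t = scheme.encode(truth)
    p = scheme.encode(predicted)
    n_min = len(t) // 2
    t2 = t[: 2 * n_min].reshape(n_min, 2)
    p2 = p[: 2 * n_min].reshape(n_min, 2)
    t_min = t2[:, 0]  # majority of two = first unless equal anyway
    p_min = p2[:, 0]
    counts = np.zeros((scheme.k, scheme.k), dtype=np.int64)
    np.add.at(counts, (t_min, p_min), 1)
    return counts
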