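"""Non-wear detection, time-of-day imputation, and cohort inclusion QC.

An epoch is stationary when every axis's standard deviation stays below
13 mg; runs of at least 60 minutes of consecutive stationary epochs are
flagged as device non-wear.  Non-worn stretches of per-epoch quantities
(behaviour probabilities or MET) are imputed with the mean of the same
30-s time-of-day slot on the other, worn, days of the recording.  A
recording enters a cohort analysis only if it passes the wear-time and
signal-quality criteria: at least 72 h worn, every hour of the 24-h cycle
covered by worn data, mean vector magnitude at most 100 mg, successful
calibration, and few clipped samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import (
    CLIP_G,
    EPOCH_SECONDS,
    STATIONARY_SD_G,
    CalibrationResult,
    Recording,
    compute_enmo,
    epoch_array,
)

#: Minimum stationary run, in epochs, that counts as non-wear (60 min).
NONWEAR_MIN_EPOCHS = int(60 * 60 / EPOCH_SECONDS)
#: Number of 30-s time-of-day slots in a day.
SLOTS_PER_DAY = int(86400 / EPOCH_SECONDS)


@dataclass
class WearMask:
    """Per-epoch wear flags plus the maximal non-wear episodes."""

    worn: np.ndarray
    episodes: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.worn)

    @property
    def wear_hours(self) -> float:
        return float(self.worn.sum()) * EPOCH_SECONDS / 3600.0


@dataclass
class QcReport:
    """Inclusion decision with every failed criterion listed."""

    wear_hours: float
    hour_of_day_coverage: np.ndarray
    mean_vm_mg: float
    calibration_ok: bool
    clipped_fraction: float
    included: bool
    reasons: list[str] = field(default_factory=list)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_nonwear(
    recording: Recording,
    sd_threshold: float = STATIONARY_SD_G,
    min_epochs: int = NONWEAR_MIN_EPOCHS,
) -> WearMask:
    """Mark runs of >= 60 min of stationary epochs as non-wear.

    Stationary means per-axis SD below ``sd_threshold`` within the epoch.
    Episode boundaries align to epoch boundaries; the rule is idempotent.
    """
    blocks = epoch_array(recording)
    stationary = np.all(blocks.std(axis=1) < sd_threshold, axis=1)
    worn = np.ones(len(blocks), dtype=bool)
    episodes: list[tuple[int, int, str]] = []
    for start, stop in _runs(stationary):
        if stop - start >= min_epochs:
            worn[start:stop] = False
            episodes.append((int(start), int(stop), "stationary>=60min"))
    return WearMask(worn=worn, episodes=episodes)


def impute_nonwear(
    epoch_values: np.ndarray,
    mask: WearMask,
    slot_index: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill non-worn epochs from the same time-of-day slot on other days.

    ``epoch_values`` may be a vector (e.g. MET) or a matrix of per-epoch
    probability vectors; ``slot_index`` gives each epoch's 30-s slot within
    the 24-h cycle (0..2879).  Worn epochs pass through untouched.  Returns
    ``(imputed, imputed_flag, missing_flag)``: a non-worn epoch with no worn
    donor in its slot stays as-is and is flagged missing instead.
    """
    values = np.asarray(epoch_values, dtype=np.float64)
    slot_index = np.asarray(slot_index)
    worn = mask.worn
    if len(values) != len(worn) or len(slot_index) != len(worn):
        raise ValueError("epoch_values, mask and slot_index lengths must agree")
    out = values.copy()
    imputed = np.zeros(len(worn), dtype=bool)
    missing = np.zeros(len(worn), dtype=bool)
    for i in np.flatnonzero(~worn):
        donors = worn & (slot_index == slot_index[i])
        if donors.any():
            out[i] = values[donors].mean(axis=0)
            imputed[i] = True
        else:
            missing[i] = True
    return out, imputed, missing


def epoch_slot_index(recording: Recording, n_epochs: int) -> np.ndarray:
    """30-s time-of-day slot (0..2879) of each epoch, in the local clock."""
    start = recording.start_time
    midnight = start.normalize()
    offset_slots = int((start - midnight).total_seconds() // EPOCH_SECONDS)
    return (offset_slots + np.arange(n_epochs)) % SLOTS_PER_DAY


def inclusion_check(
    recording: Recording,
    mask: WearMask,
    calibration: CalibrationResult,
    min_wear_hours: float = 72.0,
    max_mean_vm_mg: float = 100.0,
    clip_g: float = CLIP_G,
    max_clipped_fraction: float = 0.01,
) -> QcReport:
    """Apply the cohort inclusion criteria to one recording.

    Included requires: wear time >= 72 h (boundary inclusive), worn data in
    every one-hour period of the 24-h cycle, mean vector magnitude (mean
    ENMO over worn epochs) <= 100 mg, successful calibration, and a clipped
    sample fraction at most ``max_clipped_fraction``.
    """
    blocks = epoch_array(recording)
    n_epochs = len(blocks)
    worn = mask.worn[:n_epochs]

    slot = epoch_slot_index(recording, n_epochs)
    hour = slot * EPOCH_SECONDS // 3600
    coverage = np.zeros(24, dtype=bool)
    covered_hours = np.unique(hour[worn]) if worn.any() else np.array([], dtype=int)
    coverage[covered_hours] = True

    if worn.any():
        mean_vm = float(compute_enmo(blocks[worn]).mean() * 1000.0)
    else:
        mean_vm = 0.0
    clipped = float(
        np.mean(np.any(np.abs(recording.samples) >= clip_g, axis=1))
    ) if recording.n_samples else 0.0

    wear_hours = float(worn.sum()) * EPOCH_SECONDS / 3600.0
    reasons = []
    if wear_hours < min_wear_hours:
        reasons.append(f"wear time {wear_hours:.1f} h < {min_wear_hours:.0f} h")
    if not coverage.all():
        gaps = np.flatnonzero(~coverage)
        reasons.append(f"no worn data in hour-of-day bin(s) {gaps.tolist()}")
    if mean_vm > max_mean_vm_mg:
        reasons.append(f"mean vector magnitude {mean_vm:.0f} mg > {max_mean_vm_mg:.0f} mg")
    if not calibration.ok:
        reasons.append("calibration failed")
    if clipped > max_clipped_fraction:
        reasons.append(f"clipped fraction {clipped:.3f} > {max_clipped_fraction}")
    return QcReport(
        wear_hours=wear_hours,
        hour_of_day_coverage=coverage,
        mean_vm_mg=mean_vm,
        calibration_ok=calibration.ok,
        clipped_fraction=clipped,
        included=not reasons,
        reasons=reasons,
    )


def wear_bouts(mask: WearMask) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of worn epochs (HMM decoding units)."""
    return _runs(mask.worn)
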