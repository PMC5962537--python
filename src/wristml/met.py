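"""Energy-expenditure (MET) prediction.

Each of the eleven MET-relevant behaviour classes groups several fine
activities with compendium-style MET values; a class's representative MET
is the mean of the MET scores that built it.  Per-epoch energy cost is the
representative METs weighted by the HMM's marginal state probabilities —
a soft assignment, so confusable classes blend rather than flip — and days
aggregate to MET-hours/day (epoch MET x 30/3600 summed over the day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import EPOCH_SECONDS, ValidationError

_EPOCH_HOURS = EPOCH_SECONDS / 3600.0


@dataclass
class MetScheme:
    """Representative MET per behaviour class, with provenance.

    ``contributions[c]`` lists the (activity, MET) pairs whose mean defines
    class c's representative value.
    """

    classes: tuple[str, ...]
    values: np.ndarray
    contributions: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.classes),):
            raise ValidationError("one MET value per class required")
        if np.any(self.values <= 0):
            raise ValidationError("MET values must be positive")

    def value_of(self, cls: str) -> float:
        return float(self.values[self.classes.index(cls)])

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "values": self.values.tolist(),
            "contributions": {
                c: [[a, m] for a, m in pairs]
                for c, pairs in self.contributions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetScheme":
        return cls(
            classes=tuple(d["classes"]),
            values=np.asarray(d["values"]),
            contributions={
                c: [(a, float(m)) for a, m in pairs]
                for c, pairs in d.get("contributions", {}).items()
            },
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.classes),
                "met": self.values,
                "n_contributing": [
                    len(self.contributions.get(c, [])) for c in self.classes
                ],
            }
        )


@dataclass
class MetSeries:
    """Per-epoch MET values plus per-day MET-hours aggregates."""

    epoch_met: np.ndarray
    met_hours_per_day: pd.Series | None = None


def class_met_scores(
    annotations, classes: tuple[str, ...] | None = None, weighted: bool = False
) -> MetScheme:
    """Representative MET per class from (class, fine activity, MET) records.

    By default the mean runs over the *distinct* (activity, MET) pairs that
    contribute to a class; with ``weighted=True`` it runs over all records,
    i.e. is duration-weighted when records are epochs.
    """
    per_class_records: dict[str, list[tuple[str, float]]] = {}
    for cls, activity, met in annotations:
        per_class_records.setdefault(str(cls), []).append((str(activity), float(met)))
    if classes is None:
        classes = tuple(sorted(per_class_records))
    missing = [c for c in classes if not per_class_records.get(c)]
    if missing:
        raise ValidationError(f"class(es) with no contributing activity: {missing}")
    values, contributions = [], {}
    for c in classes:
        records = per_class_records[c]
        distinct = sorted(set(records))
        pool = records if weighted else distinct
        values.append(float(np.mean([m for _, m in pool])))
        contributions[c] = distinct
    return MetScheme(
        classes=classes, values=np.asarray(values), contributions=contributions
    )


def predict_met(
    marginals: np.ndarray,
    scheme: MetScheme,
    day_index: np.ndarray | None = None,
) -> MetSeries:
    """Marginal-probability-weighted MET per epoch.

    ``marginals`` rows must sum to 1 over the scheme's classes; each epoch's
    MET is the convex combination sum_k marginal_k * MET_k, so it always
    lies between the scheme's min and max values.  With ``day_index`` the
    per-day MET-hours aggregate is also computed.
    """
    M = np.atleast_2d(np.asarray(marginals, dtype=np.float64))
    if M.shape[1] != len(scheme.classes):
        raise ValidationError(
            f"marginals have {M.shape[1]} columns for {len(scheme.classes)} classes"
        )
    if np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("marginal rows must sum to 1")
    epoch_met = M @ scheme.values
    daily = None
    if day_index is not None:
        day_index = np.asarray(day_index)
        if day_index.shape != (len(epoch_met),):
            raise ValidationError("day_index length must match marginals")
        daily = daily_met_hours(epoch_met, day_index)
    return MetSeries(epoch_met=epoch_met, met_hours_per_day=daily)


def daily_met_hours(epoch_met: np.ndarray, day_index: np.ndarray) -> pd.Series:
    """MET-hours per day: sum of epoch MET x (30 s / 3600 s) within each day."""
    s = pd.Series(np.asarray(epoch_met, dtype=np.float64) * _EPOCH_HOURS)
    return s.groupby(np.asarray(day_index)).sum()
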