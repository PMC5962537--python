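"""Synthetic labelled accelerometer cohorts.

Generates multi-day, multi-subject tri-axial recordings whose statistical
structure matches what the classification pipeline assumes: behaviour labels
follow a first-order Markov chain at 30-s epoch resolution; each behaviour
class imposes a signal signature (a gravity orientation, an optional
sinusoidal oscillation along that orientation, and white noise); each epoch
additionally carries a fine-grained activity drawn from the class's mixture,
with a known MET value; and optional non-wear episodes freeze the signal at
a fixed orientation.  Because the generating chain, emission parameters and
per-epoch METs are known, every pipeline stage can be tested by parameter
recovery rather than against deposited data.

The defaults deliberately do NOT claim to mimic any real annotated dataset;
they are the minimal structure that makes the six behaviour classes
separable by the feature families used downstream (moments, FFT bins,
orientation angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import EPOCH_SECONDS, DEFAULT_RATE, Recording, ValidationError

_ATOL = 1e-9

#: The six behaviour classes used for activity classification.
SIX_CLASSES = ("sleep", "sit/stand", "walking", "vehicle", "mixed", "bicycling")

#: The eleven MET-relevant behaviour labels.
ELEVEN_CLASSES = (
    "bicycling",
    "gym",
    "sitstand+activity",
    "sitstand+lowactivity",
    "sitting",
    "sleep",
    "sports",
    "standing",
    "vehicle",
    "walking",
    "walking+activity",
)


@dataclass
class ActivityProfile:
    """Signal signature and fine-activity mixture of one behaviour class.

    ``base_orientation`` is the unit gravity direction while in the class;
    ``dominant_freq`` (Hz) and ``osc_amplitude`` (g) describe a sinusoid
    oscillating along that orientation (0/0 for static classes);
    ``noise_sd`` (g) is per-axis white noise.  ``fine_activities`` lists
    (name, MET, weight) triples: the fine activity of each epoch is drawn
    from this mixture and its MET is the epoch's ground-truth energy cost.
    """

    label: str
    base_orientation: np.ndarray
    dominant_freq: float
    osc_amplitude: float
    noise_sd: float
    fine_activities: list[tuple[str, float, float]]
    #: per-epoch orientation jitter (small-angle SD, degrees): real wrists
    #: do not hold one exact posture, and without it every class would be
    #: perfectly separable by a single orientation feature
    orient_wobble_deg: float = 0.0
    #: per-epoch lognormal sigma multiplying the oscillation amplitude
    amp_jitter: float = 0.0
    #: per-epoch SD (Hz) on the dominant frequency
    freq_jitter: float = 0.0
    #: probability that an epoch of this class is motionless (amplitude 0):
    #: a stopped car, a still gym rest — the source of irreducible
    #: between-class confusion that time smoothing is there to repair
    rest_prob: float = 0.0

    def __post_init__(self) -> None:
        self.base_orientation = np.asarray(self.base_orientation, dtype=np.float64)
        if abs(np.linalg.norm(self.base_orientation) - 1.0) > _ATOL:
            raise ValidationError(
                f"{self.label}: base_orientation must have unit norm"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"{self.label}: noise_sd must be >= 0")
        weights = [w for _, _, w in self.fine_activities]
        if abs(sum(weights) - 1.0) > _ATOL:
            raise ValidationError(f"{self.label}: mixing weights must sum to 1")
        if any(met <= 0 for _, met, _ in self.fine_activities):
            raise ValidationError(f"{self.label}: MET values must be positive")


@dataclass
class ChainSpec:
    """First-order Markov chain over behaviour classes, one step per epoch."""

    classes: tuple[str, ...]
    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        k = len(self.classes)
        if self.initial.shape != (k,) or self.transition.shape != (k, k):
            raise ValidationError("chain dimensions must match class count")
        if np.any(self.initial < 0) or np.any(self.transition < 0):
            raise ValidationError("chain probabilities must be non-negative")
        if abs(self.initial.sum() - 1.0) > _ATOL:
            raise ValidationError("initial distribution must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > _ATOL):
            raise ValidationError("transition rows must sum to 1")


@dataclass
class LabelledRecording:
    """A synthetic recording with its generating ground truth.

    Per-epoch arrays all share length ``floor(duration / 30 s)``:
    behaviour-class labels, (fine activity, true MET) pairs, and a boolean
    non-wear truth mask.
    """

    recording: Recording
    epoch_labels: np.ndarray
    epoch_fine: list[tuple[str, float]]
    nonwear_truth: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.epoch_labels)
        if len(self.epoch_fine) != n or len(self.nonwear_truth) != n:
            raise ValidationError("per-epoch arrays must share one length")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_labels)

    def true_met(self) -> np.ndarray:
        return np.array([met for _, met in self.epoch_fine])

    def fine_labels(self) -> np.ndarray:
        return np.array([name for name, _ in self.epoch_fine])


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


def default_profiles() -> dict[str, ActivityProfile]:
    """Default signature per behaviour class.

    Orientations are spread on the sphere; periodic classes get distinct
    fundamental frequencies; noise levels keep worn epochs above the 13 mg
    stationarity threshold.  Fine-activity METs follow compendium-style
    values for the eleven MET labels.
    """
    return {
        "sleep": ActivityProfile(
            "sleep", _unit([0.0, 0.0, 1.0]), 0.0, 0.0, 0.02,
            [("sleep", 0.95, 1.0)],
            orient_wobble_deg=8.0,
        ),
        "sit/stand": ActivityProfile(
            "sit/stand", _unit([0.0, 0.6, 0.8]), 1.2, 0.03, 0.03,
            [
                ("sitting", 1.3, 0.35),
                ("standing", 1.8, 0.25),
                ("sitstand+lowactivity", 1.5, 0.2),
                ("sitstand+activity", 2.0, 0.2),
            ],
            orient_wobble_deg=30.0, amp_jitter=1.2, freq_jitter=0.5,
            rest_prob=0.55,
        ),
        "walking": ActivityProfile(
            "walking", _unit([1.0, 0.0, 1.0]), 2.0, 0.2, 0.05,
            [("walking", 3.5, 0.7), ("walking+activity", 4.5, 0.3)],
            orient_wobble_deg=25.0, amp_jitter=0.8, freq_jitter=0.4,
        ),
        # same resting posture as sit/stand plus weak, strongly varying
        # engine vibration: a stopped car is indistinguishable from sitting,
        # so the pair is genuinely confusable, as in life
        "vehicle": ActivityProfile(
            "vehicle", _unit([0.0, 0.6, 0.8]), 10.0, 0.03, 0.03,
            [("vehicle", 1.3, 1.0)],
            orient_wobble_deg=30.0, amp_jitter=1.2, freq_jitter=2.0,
            rest_prob=0.45,
        ),
        "mixed": ActivityProfile(
            "mixed", _unit([0.6, 0.25, 0.76]), 1.2, 0.12, 0.07,
            [("gym", 5.5, 0.5), ("sports", 6.0, 0.5)],
            orient_wobble_deg=40.0, amp_jitter=1.0, freq_jitter=0.5,
            rest_prob=0.2,
        ),
        "bicycling": ActivityProfile(
            "bicycling", _unit([0.5, 0.5, 0.707]), 1.6, 0.18, 0.06,
            [("bicycling", 7.5, 1.0)],
            orient_wobble_deg=30.0, amp_jitter=0.8, freq_jitter=0.3,
        ),
    }


def default_chain() -> ChainSpec:
    """Default diagonal-heavy behaviour chain with forbidden transitions.

    Rows follow ``SIX_CLASSES`` order.  Several transitions (e.g. sleep
    directly to walking, vehicle or bicycling) have probability exactly
    zero, mirroring the structural zeros the time-smoothing model exploits.
    """
    transition = np.array(
        [
            [0.995, 0.004, 0.000, 0.000, 0.001, 0.000],
            [0.003, 0.970, 0.012, 0.005, 0.009, 0.001],
            [0.000, 0.040, 0.930, 0.005, 0.020, 0.005],
            [0.000, 0.020, 0.005, 0.970, 0.005, 0.000],
            [0.002, 0.030, 0.020, 0.003, 0.940, 0.005],
            [0.000, 0.010, 0.020, 0.000, 0.010, 0.960],
        ]
    )
    initial = np.array([0.35, 0.30, 0.10, 0.08, 0.12, 0.05])
    return ChainSpec(SIX_CLASSES, initial, transition)


def demo_chain() -> ChainSpec:
    """A fast-mixing three-class chain for short demos and quick tests.

    The default chain's realistic dwell times (tens of minutes) mean a
    recording of less than a few hours rarely visits all six classes; this
    chain mixes in minutes so even half-hour recordings exercise every
    pipeline stage.
    """
    classes = ("sleep", "sit/stand", "walking")
    transition = np.array(
        [[0.85, 0.10, 0.05], [0.08, 0.84, 0.08], [0.05, 0.15, 0.80]]
    )
    return ChainSpec(classes, np.array([0.4, 0.4, 0.2]), transition)


def simulate_label_sequence(
    chain: ChainSpec, n_epochs: int, seed: int
) -> np.ndarray:
    """Draw a length-``n_epochs`` class-label sequence from the chain.

    Deterministic for a fixed seed; an empty sequence for ``n_epochs == 0``.
    """
    if n_epochs < 0:
        raise ValidationError("n_epochs must be >= 0")
    rng = np.random.default_rng(seed)
    k = len(chain.classes)
    states = np.empty(n_epochs, dtype=np.intp)
    if n_epochs == 0:
        return np.array([], dtype=object)
    # inverse-CDF sampling with pre-drawn uniforms keeps the loop cheap
    cum_init = np.cumsum(chain.initial)
    cum_trans = np.cumsum(chain.transition, axis=1)
    u = rng.random(n_epochs)
    states[0] = np.searchsorted(cum_init, u[0], side="right").clip(0, k - 1)
    for t in range(1, n_epochs):
        states[t] = np.searchsorted(
            cum_trans[states[t - 1]], u[t], side="right"
        ).clip(0, k - 1)
    return np.asarray(chain.classes, dtype=object)[states]


def simulate_recording(
    labels: np.ndarray,
    profiles: dict[str, ActivityProfile],
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    subject_id: str = "sim",
    start_time: str | pd.Timestamp = "2015-01-06 00:00:00",
) -> LabelledRecording:
    """Render an epoch label sequence into a tri-axial signal.

    Per epoch the signal is ``base_orientation * (1 + A sin(2 pi f t))``
    plus per-axis Gaussian noise; the oscillation runs along the gravity
    orientation so the ENMO fundamental sits at the profile's dominant
    frequency.  The fine activity of each epoch is drawn from the class's
    mixture.  Orientation changes occur only at epoch boundaries.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    labels = np.asarray(labels, dtype=object)
    missing = sorted({str(l) for l in labels} - set(profiles))
    if missing:
        raise KeyError(f"no ActivityProfile for label(s): {missing}")
    rng = np.random.default_rng(seed)
    n_epochs = len(labels)
    spe = int(round(EPOCH_SECONDS * rate))

    base = np.zeros((n_epochs, 3))
    amp = np.zeros(n_epochs)
    freq = np.zeros(n_epochs)
    noise_sd = np.zeros(n_epochs)
    wobble = np.zeros(n_epochs)
    jitter = np.zeros(n_epochs)
    fjit = np.zeros(n_epochs)
    rest = np.zeros(n_epochs)
    for cls in dict.fromkeys(labels):  # preserves first-seen order
        p = profiles[str(cls)]
        m = labels == cls
        base[m] = p.base_orientation
        amp[m] = p.osc_amplitude
        freq[m] = p.dominant_freq
        noise_sd[m] = p.noise_sd
        wobble[m] = np.deg2rad(p.orient_wobble_deg)
        jitter[m] = p.amp_jitter
        fjit[m] = p.freq_jitter
        rest[m] = p.rest_prob
    if np.any(wobble > 0):
        base = base + wobble[:, None] * rng.standard_normal((n_epochs, 3))
        base /= np.linalg.norm(base, axis=1, keepdims=True)
    if np.any(jitter > 0):
        amp = amp * np.exp(jitter * rng.standard_normal(n_epochs))
    if np.any(fjit > 0):
        freq = np.maximum(0.2, freq + fjit * rng.standard_normal(n_epochs))
    if np.any(rest > 0):
        amp = np.where(rng.random(n_epochs) < rest, 0.0, amp)

    # generation runs in float32 (the cast dominates neither accuracy nor
    # determinism); the Recording stores float64 as everywhere else
    t = (np.arange(n_epochs * spe, dtype=np.float32) / np.float32(rate)).reshape(
        n_epochs, spe
    )
    osc = 1.0 + amp[:, None].astype(np.float32) * np.sin(
        2.0 * np.pi * freq[:, None].astype(np.float32) * t
    )
    samples = base[:, None, :].astype(np.float32) * osc[:, :, None]
    noise = rng.standard_normal((n_epochs, spe, 3), dtype=np.float32)
    noise *= noise_sd[:, None, None].astype(np.float32)
    samples += noise

    epoch_fine: list[tuple[str, float]] = [None] * n_epochs  # type: ignore[list-item]
    for cls in dict.fromkeys(labels):
        fa = profiles[str(cls)].fine_activities
        weights = np.array([w for _, _, w in fa])
        idx = np.flatnonzero(labels == cls)
        draws = rng.choice(len(fa), size=len(idx), p=weights / weights.sum())
        for i, j in zip(idx, draws):
            epoch_fine[i] = (fa[j][0], fa[j][1])

    recording = Recording(
        subject_id=subject_id,
        rate=rate,
        start_time=pd.Timestamp(start_time),
        samples=samples.reshape(-1, 3),
    )
    return LabelledRecording(
        recording=recording,
        epoch_labels=labels,
        epoch_fine=epoch_fine,
        nonwear_truth=np.zeros(n_epochs, dtype=bool),
    )


def inject_nonwear(
    lrec: LabelledRecording,
    nonwear_rate: float,
    seed: int,
    min_minutes: float = 75.0,
    max_minutes: float = 180.0,
) -> LabelledRecording:
    """Replace random episodes with a frozen orientation and mark the truth.

    ``nonwear_rate`` is the expected number of episodes per day (Poisson).
    Episodes align to epoch boundaries; within one the signal is exactly
    constant (a random unit orientation, zero noise), so per-axis SD is 0 by
    construction and the downstream stationarity rule must fire.
    """
    if nonwear_rate < 0:
        raise ValidationError("nonwear_rate must be >= 0")
    if nonwear_rate == 0:
        return lrec
    rng = np.random.default_rng(seed)
    rec = lrec.recording
    spe = int(round(EPOCH_SECONDS * rec.rate))
    epochs_per_day = int(round(86400 / EPOCH_SECONDS))
    n_days = max(1, int(np.ceil(lrec.n_epochs / epochs_per_day)))
    nonwear = lrec.nonwear_truth.copy()
    samples = rec.samples.copy()
    for _ in range(rng.poisson(nonwear_rate * n_days)):
        length = int(
            round(rng.uniform(min_minutes, max_minutes) * 60 / EPOCH_SECONDS)
        )
        start = int(rng.integers(0, max(1, lrec.n_epochs - length)))
        stop = min(lrec.n_epochs, start + length)
        orientation = rng.standard_normal(3)
        orientation /= np.linalg.norm(orientation)
        samples[start * spe : stop * spe] = orientation
        nonwear[start:stop] = True
    new_rec = Recording(
        subject_id=rec.subject_id,
        rate=rec.rate,
        start_time=rec.start_time,
        samples=samples,
    )
    return LabelledRecording(
        recording=new_rec,
        epoch_labels=lrec.epoch_labels,
        epoch_fine=lrec.epoch_fine,
        nonwear_truth=nonwear,
    )


def simulate_cohort(
    n_subjects: int,
    hours_each: float,
    chain: ChainSpec | None = None,
    profiles: dict[str, ActivityProfile] | None = None,
    nonwear_rate: float = 0.0,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
) -> list[LabelledRecording]:
    """Simulate ``n_subjects`` independent labelled recordings.

    Subject i uses the derived seed ``seed + i``, so cohorts are
    bit-reproducible while subjects stay independent.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if hours_each <= 0:
        raise ValidationError("hours_each must be positive")
    chain = chain or default_chain()
    profiles = profiles if profiles is not None else default_profiles()
    n_epochs = int(hours_each * 3600 / EPOCH_SECONDS)
    cohort = []
    for i in range(n_subjects):
        subj_seed = seed + i
        labels = simulate_label_sequence(chain, n_epochs, seed=subj_seed)
        lrec = simulate_recording(
            labels, profiles, rate=rate, seed=subj_seed,
            subject_id=f"subject_{i:03d}",
        )
        if nonwear_rate > 0:
            lrec = inject_nonwear(lrec, nonwear_rate, seed=subj_seed + 1_000_000)
        cohort.append(lrec)
    return cohort


def standard_cohort(
    seed: int, n_subjects: int = 12, hours_each: float = 24.0
) -> list[LabelledRecording]:
    """The reference evaluation cohort: default chain and profiles, no non-wear.

    12 subjects x 24 h at 100 Hz unless overridden; used by the examples and
    the end-to-end evaluation runs.
    """
    return simulate_cohort(n_subjects, hours_each, seed=seed)


def save_labels_csv(lrec: LabelledRecording, path) -> None:
    """Write per-epoch ground truth: epoch_start, label, fine_activity, met, nonwear."""
    starts = lrec.recording.start_time + pd.to_timedelta(
        np.arange(lrec.n_epochs) * EPOCH_SECONDS, unit="s"
    )
    pd.DataFrame(
        {
            "epoch_start": starts,
            "label": lrec.epoch_labels,
            "fine_activity": [name for name, _ in lrec.epoch_fine],
            "met": [met for _, met in lrec.epoch_fine],
            "nonwear": lrec.nonwear_truth.astype(int),
        }
    ).to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def load_labels_csv(path) -> pd.DataFrame:
    """Read a per-epoch ground-truth CSV written by :func:`save_labels_csv`."""
    return pd.read_csv(path, parse_dates=["epoch_start"])
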