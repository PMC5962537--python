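"""Raw tri-axial signal handling.

Preprocessing for wrist-worn accelerometer streams: resampling onto a
uniform 100 Hz grid, a simplified gain/offset sphere-fit calibration from
stationary windows, ENMO (Euclidean Norm Minus One, negatives truncated)
computation, and segmentation into non-overlapping 30-second epochs — the
unit at which behaviour is classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Length of a classification epoch in seconds.
EPOCH_SECONDS = 30
#: Canonical device sampling rate in Hz.
DEFAULT_RATE = 100.0
#: Per-axis standard deviation below which a window counts as stationary (g).
STATIONARY_SD_G = 0.013
#: Absolute acceleration at or above which a sample counts as clipped (g);
#: just inside the device's +/-8 g dynamic range.
CLIP_G = 7.96


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Recording:
    """One subject's continuous tri-axial acceleration stream.

    Samples are stored in gravity units (g).  When ``timestamps`` is None the
    stream is uniform at ``rate`` starting at ``start_time``; otherwise
    ``timestamps`` gives each sample's offset in seconds from ``start_time``
    (gaps are therefore explicit, never encoded as missing values).
    """

    subject_id: str
    rate: float
    start_time: pd.Timestamp
    samples: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValidationError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(
                f"samples must have shape (n, 3), got {self.samples.shape}"
            )
        self.start_time = pd.Timestamp(self.start_time)
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
            if self.timestamps.shape != (len(self.samples),):
                raise ValidationError("timestamps length must match samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to ``start_time``."""
        if self.timestamps is not None:
            return self.timestamps
        return np.arange(self.n_samples, dtype=np.float64) / self.rate

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (0 for empty streams)."""
        t = self.times()
        return float(t[-1] - t[0]) if len(t) else 0.0


@dataclass
class CalibrationResult:
    """Outcome of the gain/offset sphere fit.

    ``ok`` is False when too few distinct stationary orientations exist to
    determine the six parameters, or the fit residual exceeds the threshold;
    in that case the recording is left untouched.
    """

    gain: np.ndarray
    offset: np.ndarray
    residual: float
    ok: bool
    n_orientations: int = 0


@dataclass
class Epoch:
    """A non-overlapping 30-s window: raw samples plus per-sample ENMO."""

    index: int
    samples: np.ndarray
    enmo: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.enmo is None:
            self.enmo = compute_enmo(self.samples)


def compute_enmo(samples: np.ndarray) -> np.ndarray:
    """Euclidean norm minus one, with negative values truncated to zero.

    The standard gravity-removed movement magnitude, in g.  Truncation makes
    the transform idempotent on its own output and guarantees non-negativity.
    """
    samples = np.asarray(samples)
    if samples.dtype not in (np.float32, np.float64):
        samples = samples.astype(np.float64)
    norm = np.sqrt(np.einsum("...i,...i->...", samples, samples))
    return np.maximum(norm - 1.0, 0.0)


def resample(recording: Recording, target_rate: float = DEFAULT_RATE) -> Recording:
    """Linearly interpolate a recording onto a uniform grid at ``target_rate``.

    The grid spans the original time range; a recording that is already
    uniform at the target rate comes back unchanged up to floating error.
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be positive")
    if recording.n_samples < 2:
        raise ValidationError("resample needs at least 2 samples")
    t = recording.times()
    n_out = int(np.floor((t[-1] - t[0]) * target_rate)) + 1
    grid = t[0] + np.arange(n_out, dtype=np.float64) / target_rate
    out = np.empty((n_out, 3), dtype=np.float64)
    for axis in range(3):
        out[:, axis] = np.interp(grid, t, recording.samples[:, axis])
    return Recording(
        subject_id=recording.subject_id,
        rate=target_rate,
        start_time=recording.start_time + pd.to_timedelta(t[0], unit="s"),
        samples=out,
    )


def stationary_block_means(
    recording: Recording,
    block_seconds: float = 10.0,
    sd_threshold: float = STATIONARY_SD_G,
) -> np.ndarray:
    """Mean acceleration vectors of stationary blocks.

    A block is stationary when every axis has standard deviation below
    ``sd_threshold``.  These means should lie on the unit sphere for a
    well-calibrated device; departures drive the calibration fit.
    """
    spb = int(round(block_seconds * recording.rate))
    n_blocks = recording.n_samples // spb
    if n_blocks == 0:
        return np.empty((0, 3))
    blocks = recording.samples[: n_blocks * spb].reshape(n_blocks, spb, 3)
    sd = blocks.std(axis=1)
    stationary = np.all(sd < sd_threshold, axis=1)
    return blocks[stationary].mean(axis=1)


def _distinct_orientations(means: np.ndarray, tol: float) -> np.ndarray:
    """Greedy dedupe: keep means at least ``tol`` (euclidean, g) apart."""
    kept: list[np.ndarray] = []
    for m in means:
        if all(np.linalg.norm(m - k) >= tol for k in kept):
            kept.append(m)
    return np.asarray(kept) if kept else np.empty((0, 3))


def calibrate(
    recording: Recording,
    *,
    block_seconds: float = 10.0,
    sd_threshold: float = STATIONARY_SD_G,
    min_orientations: int = 10,
    distinct_tol: float = 0.05,
    max_residual: float = 0.01,
) -> tuple[Recording, CalibrationResult]:
    """Fit per-axis gain and offset so stationary vectors have unit norm.

    Least-squares sphere fit on the means of stationary 10-s blocks: solve
    for gain g and offset o minimising sum_i (||g*m_i + o|| - 1)^2, then apply
    a' = g*a + o to the whole stream.  With fewer than ``min_orientations``
    sufficiently distinct stationary orientations the six-parameter fit is
    underdetermined and the recording is returned unchanged with ``ok=False``.
    """
    means = stationary_block_means(recording, block_seconds, sd_threshold)
    distinct = _distinct_orientations(means, distinct_tol)
    identity = CalibrationResult(
        gain=np.ones(3), offset=np.zeros(3), residual=np.inf,
        ok=False, n_orientations=len(distinct),
    )
    if len(distinct) < min_orientations:
        return recording, identity

    def residuals(p: np.ndarray) -> np.ndarray:
        gain, offset = p[:3], p[3:]
        return np.linalg.norm(distinct * gain + offset, axis=1) - 1.0

    fit = least_squares(residuals, x0=np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]))
    gain, offset = fit.x[:3], fit.x[3:]
    rms = float(np.sqrt(np.mean(fit.fun**2)))
    if rms >= max_residual:
        identity.residual = rms
        return recording, identity
    calibrated = Recording(
        subject_id=recording.subject_id,
        rate=recording.rate,
        start_time=recording.start_time,
        samples=recording.samples * gain + offset,
        timestamps=recording.timestamps,
    )
    return calibrated, CalibrationResult(
        gain=gain, offset=offset, residual=rms, ok=True,
        n_orientations=len(distinct),
    )


def epoch_array(recording: Recording) -> np.ndarray:
    """All complete 30-s epochs as one ``(n_epochs, samples_per_epoch, 3)`` block.

    The trailing partial window, if any, is dropped (and logged): the feature
    contract downstream requires exactly 30 s of signal per epoch.
    """
    if recording.timestamps is not None:
        raise ValidationError("segment a resampled (uniform) recording")
    spe = int(round(EPOCH_SECONDS * recording.rate))
    n_epochs = recording.n_samples // spe
    dropped = recording.n_samples - n_epochs * spe
    if dropped:
        logger.info(
            "dropping trailing partial window of %d samples (%.1f s)",
            dropped, dropped / recording.rate,
        )
    return recording.samples[: n_epochs * spe].reshape(n_epochs, spe, 3)


def segment_windows(recording: Recording) -> list[Epoch]:
    """Cut a uniform recording into consecutive non-overlapping 30-s epochs."""
    blocks = epoch_array(recording)
    return [
        Epoch(index=i, samples=blocks[i], start_offset=i * float(EPOCH_SECONDS))
        for i in range(len(blocks))
    ]


def epoch_start_times(recording: Recording, n_epochs: int) -> pd.DatetimeIndex:
    """Timestamps of each epoch's half-open interval start."""
    return recording.start_time + pd.to_timedelta(
        np.arange(n_epochs) * EPOCH_SECONDS, unit="s"
    )


def load_recording_csv(
    path, subject_id: str | None = None, rate: float | None = None
) -> Recording:
    """Read a ``timestamp,x,y,z`` CSV (ISO-8601 timestamps, g units).

    The nominal rate is inferred from the median timestamp spacing unless
    given; non-uniform streams keep explicit timestamps until resampled.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if df.empty:
        raise ValidationError(f"empty recording file: {path}")
    t0 = df["timestamp"].iloc[0]
    secs = (df["timestamp"] - t0).dt.total_seconds().to_numpy()
    if rate is None:
        dt = np.median(np.diff(secs)) if len(secs) > 1 else 1.0
        rate = 1.0 / dt if dt > 0 else DEFAULT_RATE
    uniform = len(secs) > 1 and np.allclose(
        np.diff(secs), 1.0 / rate, atol=1e-6
    )
    return Recording(
        subject_id=subject_id or str(path),
        rate=float(rate),
        start_time=t0,
        samples=df[["x", "y", "z"]].to_numpy(dtype=np.float64),
        timestamps=None if uniform else secs,
    )


def save_recording_csv(recording: Recording, path) -> None:
    """Write a recording as a ``timestamp,x,y,z`` CSV."""
    t = recording.start_time + pd.to_timedelta(recording.times(), unit="s")
    df = pd.DataFrame(
        {
            "timestamp": t,
            "x": recording.samples[:, 0],
            "y": recording.samples[:, 1],
            "z": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")
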