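"""The 126-dimensional epoch feature vector.

Each 30-s epoch at 100 Hz (3000 samples per axis) is mapped to 126 time- and
frequency-domain features, grouped as:

  A. ENMO moments (12): mean, SD, coefficient of variation, median, min,
     max, 25th/75th percentiles, mean amplitude deviation, mean power
     deviation, kurtosis, skew.
  B. ENMO FFT magnitudes at 1..15 Hz (15).
  C. Per-axis mean, range, SD (9).
  D. Per-axis FFT magnitudes at 1..15 Hz (45).
  E. Cross-axis covariance and Pearson correlation, (x,y),(x,z),(y,z) (6).
  F. Roll, pitch, yaw: mean, SD, range (9).
  G. ENMO spectral summaries (6): dominant frequency, power at dominant,
     second-dominant frequency, power at second dominant, total power,
     spectral entropy.
  H. Per-axis dominant frequency and power at dominant (6).
  I. ENMO band power in fifteen 1-Hz bands [0,1)..[14,15) Hz (15).
  J. Per-axis total power (3).

FFT convention: the window mean is subtracted, no taper is applied,
magnitude = |DFT|/n, and "magnitude at f Hz" is the bin nearest f
(resolution 1/30 Hz).  Power is squared magnitude of the one-sided
spectrum.  Degenerate inputs are mapped to 0 rather than NaN (CV of a
zero-mean series, kurtosis/skew/correlation of a constant series, dominant
frequency of an all-zero spectrum) so that downstream tree models never see
non-finite values.

Angle conventions: roll = atan2(y, z); pitch = atan2(-x, sqrt(y^2+z^2));
yaw = atan2(y, x).  Yaw is not observable from gravity alone; a fixed
convention is declared for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import EPOCH_SECONDS, Epoch, ValidationError, compute_enmo

_AXES = ("x", "y", "z")
_MOMENT_NAMES = (
    "mean", "sd", "cv", "median", "min", "max", "p25", "p75",
    "mad", "mpd", "kurtosis", "skew",
)
_FFT_HZ = range(1, 16)


def _build_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"enmo_{m}" for m in _MOMENT_NAMES]                      # A (12)
    names += [f"enmo_fft_{f}hz" for f in _FFT_HZ]                      # B (15)
    for ax in _AXES:                                                   # C (9)
        names += [f"{ax}_mean", f"{ax}_range", f"{ax}_sd"]
    for ax in _AXES:                                                   # D (45)
        names += [f"{ax}_fft_{f}hz" for f in _FFT_HZ]
    for a, b in (("x", "y"), ("x", "z"), ("y", "z")):                  # E (6)
        names += [f"cov_{a}{b}", f"corr_{a}{b}"]
    for ang in ("roll", "pitch", "yaw"):                               # F (9)
        names += [f"{ang}_mean", f"{ang}_sd", f"{ang}_range"]
    names += [                                                         # G (6)
        "enmo_dom_freq", "enmo_dom_power",
        "enmo_dom2_freq", "enmo_dom2_power",
        "enmo_total_power", "enmo_spectral_entropy",
    ]
    for ax in _AXES:                                                   # H (6)
        names += [f"{ax}_dom_freq", f"{ax}_dom_power"]
    names += [f"enmo_band_{b}_{b + 1}hz" for b in range(15)]           # I (15)
    names += [f"{ax}_total_power" for ax in _AXES]                     # J (3)
    return tuple(names)


#: Canonical ordered feature names; length is the feature dimensionality.
FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
N_FEATURES: int = len(FEATURE_NAMES)
assert N_FEATURES == 126

_SAMPLES_PER_EPOCH = EPOCH_SECONDS * 100  # feature contract: 3000 at 100 Hz


@dataclass
class FeatureVector:
    """Ordered 126-feature representation of one epoch.

    ``valid`` is False (and values all zero) when the source epoch
    contained non-finite samples.
    """

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    valid: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValidationError(
                f"feature vector must have length {N_FEATURES}"
            )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _moments(e: np.ndarray) -> np.ndarray:
    """Group A for ENMO blocks of shape (n_epochs, n)."""
    mean = e.mean(axis=1)
    dev = e - mean[:, None]
    dev2 = dev * dev
    m2 = dev2.mean(axis=1)
    m3 = (dev2 * dev).mean(axis=1)
    m4 = (dev2 * dev2).mean(axis=1)
    sd = np.sqrt(m2)
    cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    safe = m2 > 1e-24
    m2s = np.where(safe, m2, 1.0)
    skew = np.where(safe, m3 / m2s**1.5, 0.0)
    kurt = np.where(safe, m4 / m2s**2 - 3.0, 0.0)
    q = np.percentile(e, [25, 50, 75], axis=1)
    mad = np.mean(np.abs(dev), axis=1)
    mpd = m2  # mean power deviation: mean squared deviation from the mean
    return np.column_stack(
        [mean, sd, cv, q[1], e.min(axis=1), e.max(axis=1), q[0], q[2],
         mad, mpd, kurt, skew]
    )


def _spectra(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided (magnitude, power) spectra of mean-subtracted rows."""
    n = x.shape[1]
    mag = np.abs(np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)) / n
    return mag, mag**2


def _dominant(power: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, ...]:
    """(dominant freq, power at dominant, total power); 0s for a dead spectrum."""
    rows = np.arange(power.shape[0])
    total = power.sum(axis=1)
    dead = total < 1e-24
    i1 = power[:, 1:].argmax(axis=1) + 1  # DC bin (zeroed) excluded
    f1 = np.where(dead, 0.0, freqs[i1])
    p1 = np.where(dead, 0.0, power[rows, i1])
    return f1, p1, np.where(dead, 0.0, total), i1, dead


def _spectral_summary(power: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """dominant freq/power, 2nd-dominant freq/power, total power, entropy."""
    rows = np.arange(power.shape[0])
    f1, p1, total, i1, dead = _dominant(power, freqs)
    masked = power[:, 1:].copy()
    masked[rows, i1 - 1] = -1.0
    i2 = masked.argmax(axis=1) + 1
    p2 = power[rows, i2]
    frac = power[:, 1:] / np.where(total > 0, total, 1.0)[:, None]
    np.clip(frac, 1e-30, None, out=frac)  # 0 log 0 -> 0 via the clip
    ent = -np.sum(frac * np.log(frac), axis=1)
    out = np.column_stack(
        [f1, p1, np.where(dead, 0.0, freqs[i2]), np.where(dead, 0.0, p2),
         total, np.where(dead, 0.0, ent)]
    )
    return out


def feature_matrix(blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Features for a batch of epochs.

    Parameters
    ----------
    blocks : ndarray, shape (n_epochs, 3000, 3)
        Raw tri-axial epochs at 100 Hz, in g.

    Returns
    -------
    (features, valid) : ndarray (n_epochs, 126), ndarray (n_epochs,) bool
        Rows of epochs containing non-finite samples are all-zero with
        ``valid`` False.
    """
    blocks = np.asarray(blocks, dtype=np.float64)
    if blocks.ndim != 3 or blocks.shape[1:] != (_SAMPLES_PER_EPOCH, 3):
        raise ValidationError(
            f"expected epochs of shape (n, {_SAMPLES_PER_EPOCH}, 3), "
            f"got {blocks.shape}"
        )
    n_ep = blocks.shape[0]
    valid = np.isfinite(blocks).all(axis=(1, 2))
    safe = blocks if valid.all() else np.where(valid[:, None, None], blocks, 0.0)
    # heavy elementwise work runs in float32 (numpy's pairwise reductions
    # keep the means/variances accurate); the returned matrix is float64
    safe = safe.astype(np.float32)
    x = np.ascontiguousarray(safe[:, :, 0])
    y = np.ascontiguousarray(safe[:, :, 1])
    z = np.ascontiguousarray(safe[:, :, 2])
    enmo = compute_enmo(safe)

    n = _SAMPLES_PER_EPOCH
    freqs = np.fft.rfftfreq(n, d=1.0 / 100.0)
    hz_bins = np.array([int(round(f * EPOCH_SECONDS)) for f in _FFT_HZ])

    cols: list[np.ndarray] = []
    cols.append(_moments(enmo))                                        # A
    enmo_mag, enmo_pow = _spectra(enmo)
    cols.append(enmo_mag[:, hz_bins])                                  # B
    axis_specs = []
    for arr in (x, y, z):                                              # C
        cols.append(
            np.column_stack(
                [arr.mean(axis=1), arr.max(axis=1) - arr.min(axis=1),
                 arr.std(axis=1)]
            )
        )
        axis_specs.append(_spectra(arr))
    for mag, _ in axis_specs:                                          # D
        cols.append(mag[:, hz_bins])
    for a, b in ((x, y), (x, z), (y, z)):                              # E
        cov = (a * b).mean(axis=1) - a.mean(axis=1) * b.mean(axis=1)
        denom = a.std(axis=1) * b.std(axis=1)
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        cols.append(np.column_stack([cov, corr]))
    roll = np.arctan2(y, z)                                            # F
    pitch = np.arctan2(-x, np.sqrt(y**2 + z**2))
    yaw = np.arctan2(y, x)
    for ang in (roll, pitch, yaw):
        cols.append(
            np.column_stack(
                [ang.mean(axis=1), ang.std(axis=1),
                 ang.max(axis=1) - ang.min(axis=1)]
            )
        )
    cols.append(_spectral_summary(enmo_pow, freqs))                    # G
    for _, pw in axis_specs:                                           # H
        f1, p1, _, _, _ = _dominant(pw, freqs)
        cols.append(np.column_stack([f1, p1]))
    band_edges = [
        (np.searchsorted(freqs, b), np.searchsorted(freqs, b + 1))
        for b in range(15)
    ]
    bands = np.column_stack(
        [enmo_pow[:, lo:hi].sum(axis=1) for lo, hi in band_edges]
    )
    cols.append(bands)                                                 # I
    cols.append(                                                       # J
        np.column_stack([pw.sum(axis=1) for _, pw in axis_specs])
    )

    feats = np.column_stack(cols).astype(np.float64)
    assert feats.shape == (n_ep, N_FEATURES)
    feats[~valid] = 0.0
    return feats, valid


def extract_features(epoch: Epoch) -> FeatureVector:
    """Map one 30-s epoch to its canonical 126-feature vector.

    A pure function of the sample values: the epoch's absolute position in
    time never enters.  Raises for a wrong sample count; returns an
    all-zero vector flagged invalid when the epoch holds non-finite values.
    """
    samples = np.asarray(epoch.samples, dtype=np.float64)
    if samples.shape != (_SAMPLES_PER_EPOCH, 3):
        raise ValidationError(
            f"epoch must hold {_SAMPLES_PER_EPOCH}x3 samples, got {samples.shape}"
        )
    values, valid = feature_matrix(samples[None])
    return FeatureVector(values=values[0], valid=bool(valid[0]))


def features_dataframe(
    blocks: np.ndarray,
    subject_id: str,
    epoch_starts,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with subject/epoch metadata columns."""
    feats, valid = feature_matrix(blocks)
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "subject_id", subject_id)
    df.insert(1, "epoch_start", epoch_starts)
    df["valid"] = valid
    return df
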