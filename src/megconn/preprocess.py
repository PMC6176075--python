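"""Sensor-space preprocessing: band-pass FIR filtering and epoching.

The preprocessing chain mirrors a standard resting-state MEG workflow:
the continuous multichannel recording is band-pass filtered with a
high-order linear-phase FIR filter applied forward and backward (zero net
phase shift), cut into consecutive non-overlapping fixed-length trials,
cleaned with a simple amplitude-threshold rejection rule, and the surviving
trials are equalized across subjects by selecting a fixed number of them
uniformly at random.

Artifact handling in real MEG (tSSS, ICA, ocular channels) is out of scope;
the amplitude-threshold rule is a deliberately simple stand-in that
exercises the same trial-count bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    """Invalid input to a preprocessing operation."""


class TrialRejectionError(PreprocessError):
    """Raised when a subject does not yield enough clean trials."""


@dataclass
class SensorRecording:
    """Continuous multichannel sensor time series for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sensor time series; arbitrary units in synthetic mode.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_types : list of str
        One label per channel (a single type by default).
    subject_id : str, optional
    """

    data: np.ndarray
    sampling_rate: float
    channel_types: list[str] = field(default_factory=list)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("recording data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise PreprocessError("sampling_rate must be positive")
        if np.isnan(self.data).any():
            raise PreprocessError("recording contains NaN")
        if not self.channel_types:
            self.channel_types = ["mag"] * self.data.shape[0]
        if len(self.channel_types) != self.data.shape[0]:
            raise PreprocessError("channel_types length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its FIR design parameters."""

    name: str
    low: float
    high: float
    filter_order: int = 1500
    window: str = "hamming"
    passes: int = 2

    def validate(self, sampling_rate: float) -> None:
        if not (0.0 < self.low < self.high):
            raise PreprocessError(f"invalid band edges ({self.low}, {self.high})")
        if self.high >= sampling_rate / 2:
            raise PreprocessError(
                f"band edge {self.high} Hz at or above Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        if self.filter_order < 2 or self.filter_order % 2:
            raise PreprocessError("filter_order must be a positive even integer")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Canonical band definitions used throughout the package.
BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
}


@dataclass
class TrialArray:
    """Band-filtered, epoched data for one subject.

    ``data`` has shape (n_trials, n_channels, n_samples) with
    ``n_samples == trial_length * sampling_rate``.
    """

    data: np.ndarray
    trial_length: float
    sampling_rate: float
    band: BandSpec | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise PreprocessError("trial data must be 3-D (trials x channels x samples)")
        expected = int(round(self.trial_length * self.sampling_rate))
        if self.data.shape[2] != expected:
            raise PreprocessError(
                f"trial has {self.data.shape[2]} samples, expected {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def design_bandpass_fir(band: BandSpec, sampling_rate: float) -> np.ndarray:
    """Design a linear-phase band-pass FIR filter (Hamming window by default).

    Returns the ``filter_order + 1`` symmetric coefficient vector.  With an
    even order the filter is type I, so a true band-pass response (zero gain
    at DC and Nyquist) is achievable.
    """
    band.validate(sampling_rate)
    return signal.firwin(
        band.filter_order + 1,
        [band.low, band.high],
        window=band.window,
        pass_zero=False,
        fs=sampling_rate,
    )


def filter_twopass(recording: SensorRecording, band: BandSpec) -> SensorRecording:
    """Apply the band-pass FIR forward and backward (zero net phase shift).

    Edges are handled by mirror padding with one filter length on each side,
    trimmed after filtering, so the first trial is not contaminated by the
    start-up transient.  The squared magnitude response of the single pass is
    the effective response.
    """
    band.validate(recording.sampling_rate)
    order = band.filter_order
    if recording.n_samples <= 3 * order:
        raise PreprocessError(
            f"recording of {recording.n_samples} samples is too short for a "
            f"two-pass order-{order} filter (need > {3 * order} samples)"
        )
    coefs = design_bandpass_fir(band, recording.sampling_rate)
    filtered = signal.filtfilt(
        coefs, [1.0], recording.data, axis=-1, padtype="even", padlen=order
    )
    return replace(recording, data=filtered)


def epoch_and_equalize(
    recording: SensorRecording,
    trial_length: float,
    n_keep: int = 20,
    seed: int | np.random.Generator | None = None,
    z_threshold: float = 5.0,
    band: BandSpec | None = None,
) -> TrialArray:
    """Cut a recording into trials, reject artifacts, equalize trial count.

    Trials are consecutive, non-overlapping segments of ``trial_length``
    seconds starting at the beginning of the recording (a trailing partial
    segment is dropped).  A trial is rejected when the largest absolute
    per-channel z-score inside it (z computed against the whole-recording
    channel mean and SD) exceeds ``z_threshold``.  Exactly ``n_keep`` of the
    surviving trials are then selected uniformly at random with the given
    seed, preserving chronological order.

    Raises
    ------
    TrialRejectionError
        If fewer than ``n_keep`` clean trials remain; the caller should flag
        and exclude the subject.
    """
    n_per_trial = int(round(trial_length * recording.sampling_rate))
    n_candidates = recording.n_samples // n_per_trial
    if n_candidates == 0:
        raise PreprocessError("recording shorter than one trial")
    x = recording.data[:, : n_candidates * n_per_trial]
    trials = x.reshape(recording.n_channels, n_candidates, n_per_trial)
    trials = np.moveaxis(trials, 0, 1)  # (trials, channels, samples)

    mean = recording.data.mean(axis=1, keepdims=True)
    sd = recording.data.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = np.abs((x - mean) / sd).reshape(recording.n_channels, n_candidates, n_per_trial)
    max_z = z.max(axis=(0, 2))
    clean = np.flatnonzero(max_z <= z_threshold)

    logger.info(
        "subject %s: %d candidate trials, %d rejected, %d clean",
        recording.subject_id,
        n_candidates,
        n_candidates - clean.size,
        clean.size,
    )
    if clean.size < n_keep:
        raise TrialRejectionError(
            f"subject {recording.subject_id}: only {clean.size} clean trials, "
            f"need {n_keep}; subject excluded"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(clean, size=n_keep, replace=False))
    return TrialArray(
        data=trials[chosen],
        trial_length=trial_length,
        sampling_rate=recording.sampling_rate,
        band=band,
        subject_id=recording.subject_id,
    )
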