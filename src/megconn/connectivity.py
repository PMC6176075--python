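"""Phase-locking value (PLV) connectivity between ROI time series.

The PLV between two band-limited series is the modulus of the time-averaged
unit phasor of their instantaneous phase difference,

    PLV = | (1/T) sum_t exp(i (phi_i(t) - phi_j(t))) |,

computed per trial and averaged over trials.  A PLV of 1 means perfect
phase locking (any constant lag); for independent phases the expected value
is the Rayleigh resultant floor ~ sqrt(pi)/(2 sqrt(T)).

Instantaneous phase is extracted from the analytic signal (Hilbert
transform) of the already band-filtered series, per trial.  The first and
last 5% of each trial are excluded from the PLV sum by default to limit
Hilbert edge effects (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .sourcerecon import ROISeries

#: Default fraction of samples dropped at each trial edge.
DEFAULT_EDGE_FRACTION = 0.05


class ConnectivityError(ValueError):
    """Invalid input to a connectivity operation."""


@dataclass
class FCMatrix:
    """Symmetric ROI x ROI PLV matrix for one subject and band."""

    values: np.ndarray
    band: str | None = None
    subject_id: str | None = None
    n_trials: int | None = None
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectivityError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ConnectivityError("FC matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ConnectivityError("PLV values must lie in [0, 1]")


def instantaneous_phase(series: np.ndarray) -> np.ndarray:
    """Phase (radians, wrapped) of the analytic signal, along the last axis.

    The input must be band-limited (upstream guarantee); a constant series
    has no defined phase and is rejected.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x, axis=-1).min() == 0:
        raise ConnectivityError("constant series has undefined phase")
    return np.angle(hilbert(x, axis=-1))


def _trial_plv_from_phases(
    phase_i: np.ndarray, phase_j: np.ndarray, edge_fraction: float
) -> np.ndarray:
    phase_i = np.atleast_2d(phase_i)
    phase_j = np.atleast_2d(phase_j)
    if phase_i.shape != phase_j.shape:
        raise ConnectivityError(
            f"phase arrays differ in shape: {phase_i.shape} vs {phase_j.shape}"
        )
    n = phase_i.shape[-1]
    crop = int(round(edge_fraction * n))
    sl = slice(crop, n - crop) if crop else slice(None)
    delta = phase_i[..., sl] - phase_j[..., sl]
    return np.abs(np.exp(1j * delta).mean(axis=-1))


def plv_pair(
    phase_i: np.ndarray,
    phase_j: np.ndarray,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
    average: str = "trials",
) -> float:
    """PLV between two per-trial phase series.

    ``phase_i``/``phase_j`` are (n_trials, n_samples) arrays (a single trial
    may be passed as 1-D).  With ``average="trials"`` (default) the PLV is
    computed per trial and the per-trial values averaged; with
    ``average="concatenate"`` the phasor sum runs over the concatenated
    trials instead.  Both conventions appear in the literature; the trial
    average matches the 20 x 4 s design this package targets.
    """
    per_trial = _trial_plv_from_phases(phase_i, phase_j, edge_fraction)
    if average == "trials":
        return float(per_trial.mean())
    if average == "concatenate":
        phase_i = np.atleast_2d(phase_i)
        phase_j = np.atleast_2d(phase_j)
        n = phase_i.shape[-1]
        crop = int(round(edge_fraction * n))
        sl = slice(crop, n - crop) if crop else slice(None)
        delta = (phase_i[..., sl] - phase_j[..., sl]).ravel()
        return float(np.abs(np.exp(1j * delta).mean()))
    raise ConnectivityError(f"unknown averaging convention {average!r}")


def fc_from_phases(
    phases: np.ndarray,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
    dtype: np.dtype | type = np.complex128,
) -> np.ndarray:
    """All-pairs trial-averaged PLV from instantaneous phases.

    ``phases`` has shape (n_trials, n_rois, n_samples).  The per-trial PLV
    matrix is |Z Z^H| / T for Z = exp(i phi); passing ``dtype=complex64``
    roughly halves the cost of the matrix products with ~1e-6 relative
    error, which is far below the sampling noise of any PLV estimate.
    """
    phases = np.asarray(phases)
    if phases.ndim != 3:
        raise ConnectivityError("phases must be 3-D (trials x ROIs x samples)")
    n_trials, n_rois, n = phases.shape
    crop = int(round(edge_fraction * n))
    sl = slice(crop, n - crop) if crop else slice(None)
    acc = np.zeros((n_rois, n_rois))
    for t in range(n_trials):
        z = np.exp(1j * phases[t, :, sl]).astype(dtype)
        t_eff = z.shape[1]
        acc += np.abs(z @ z.conj().T) / t_eff
    values = acc / n_trials
    np.fill_diagonal(values, 1.0)
    return np.clip(0.5 * (values + values.T), 0.0, 1.0)


def fc_matrix(
    roiseries: ROISeries,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
) -> FCMatrix:
    """Trial-averaged PLV between all ROI pairs of one subject.

    Phases are extracted per trial from the analytic signal of each ROI
    series; the diagonal is set to 1 by convention.
    """
    if roiseries.n_rois < 2:
        raise ConnectivityError("need at least 2 ROIs")
    try:
        phases = instantaneous_phase(roiseries.data)
    except ConnectivityError as exc:
        flat = np.ptp(roiseries.data, axis=-1).min(axis=0)
        bad = [roiseries.roi_names[k] for k in np.flatnonzero(flat == 0)]
        raise ConnectivityError(f"constant series for ROI(s) {bad}: {exc}") from exc
    values = fc_from_phases(phases, edge_fraction=edge_fraction)
    return FCMatrix(
        values=values,
        band=roiseries.band.name if roiseries.band is not None else None,
        subject_id=roiseries.subject_id,
        n_trials=roiseries.data.shape[0],
        roi_names=list(roiseries.roi_names),
    )
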