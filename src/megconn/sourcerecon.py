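"""LCMV beamformer source reconstruction and ROI parcellation.

A scalar linearly constrained minimum variance (LCMV) beamformer is built
from the trial-averaged sensor covariance and a leadfield with one column
per source.  For source s with leadfield column l_s the spatial filter is

    w_s = (l_s' C_r^-1 l_s)^-1  l_s' C_r^-1,
    C_r = C + reg * (trace(C) / n_sensors) * I,

which minimizes output variance subject to the unit-gain constraint
w_s' l_s = 1.  The regularization fraction follows the Fieldtrip-style
convention where "15%" means 15% of the mean sensor variance added to the
diagonal.  Multi-sensor-type scans are accommodated by normalizing the
leadfield row-blocks per sensor type and applying the same scaling to the
data, which leaves the beamformer output invariant.

ROI representative time series are the first principal component of the
member source series (sign fixed so the component correlates non-negatively
with the mean member series; downstream phase-locking is insensitive to
this sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BandSpec, TrialArray


class SourceReconError(ValueError):
    """Invalid input to a source-reconstruction operation."""


@dataclass
class LeadField:
    """Forward model: linear mapping from sources to sensors.

    ``matrix`` has shape (n_sensors, n_sources); ``sensor_types`` holds one
    label per sensor and ``source_labels`` one label per source (ROI or grid
    node).
    """

    matrix: np.ndarray
    sensor_types: list[str] = field(default_factory=list)
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise SourceReconError("leadfield must be 2-D (sensors x sources)")
        if not np.isfinite(self.matrix).all():
            raise SourceReconError("leadfield contains non-finite entries")
        n_sensors, n_sources = self.matrix.shape
        if not self.sensor_types:
            self.sensor_types = ["mag"] * n_sensors
        if len(self.sensor_types) != n_sensors:
            raise SourceReconError("sensor_types length mismatch")
        if not self.source_labels:
            self.source_labels = [f"src_{k}" for k in range(n_sources)]
        if len(self.source_labels) != n_sources:
            raise SourceReconError("source_labels length mismatch")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BeamformerModel:
    """LCMV spatial filters (one row per source) with their inputs."""

    weights: np.ndarray          # (n_sources, n_sensors)
    regularization: float
    covariance: np.ndarray       # (n_sensors, n_sensors)
    source_labels: list[str] = field(default_factory=list)

    def apply(self, trials: TrialArray) -> np.ndarray:
        """Project epoched sensor data to source space.

        Returns an array of shape (n_trials, n_sources, n_samples).
        """
        return np.einsum("sc,tcn->tsn", self.weights, trials.data)


@dataclass
class ROISeries:
    """Parcellated source time series (trials x ROIs x samples)."""

    data: np.ndarray
    roi_names: list[str]
    band: BandSpec | None = None
    sampling_rate: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise SourceReconError("ROI data must be 3-D (trials x ROIs x samples)")
        if self.data.shape[1] != len(self.roi_names):
            raise SourceReconError(
                f"{self.data.shape[1]} ROI series but {len(self.roi_names)} names"
            )

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def average_trial_covariance(trials: TrialArray) -> np.ndarray:
    """Mean of the per-trial sensor sample covariances (symmetric PSD)."""
    if trials.n_trials < 2:
        raise SourceReconError("need at least 2 trials for the average covariance")
    if np.isnan(trials.data).any():
        raise SourceReconError("NaN in trial data")
    x = trials.data - trials.data.mean(axis=2, keepdims=True)
    n = x.shape[2]
    cov = np.einsum("tcn,tdn->cd", x, x) / (trials.n_trials * (n - 1))
    return 0.5 * (cov + cov.T)


def lcmv_weights(
    covariance: np.ndarray,
    leadfield: LeadField,
    regularization: float = 0.15,
) -> BeamformerModel:
    """Compute LCMV spatial filters with trace-scaled diagonal loading.

    ``regularization`` is the fraction of the mean sensor variance
    (trace(C)/n_sensors) added to the covariance diagonal before inversion;
    0.15 is the conventional "15%" loading.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (leadfield.n_sensors, leadfield.n_sensors):
        raise SourceReconError("covariance / leadfield shape mismatch")
    if regularization < 0:
        raise SourceReconError("regularization must be non-negative")
    col_norms = np.linalg.norm(leadfield.matrix, axis=0)
    if np.any(col_norms == 0):
        raise SourceReconError("leadfield has an all-zero source column")

    loading = regularization * np.trace(cov) / leadfield.n_sensors
    cov_r = cov + loading * np.eye(leadfield.n_sensors)
    try:
        solved = np.linalg.solve(cov_r, leadfield.matrix)  # C_r^-1 L
    except np.linalg.LinAlgError as exc:
        raise SourceReconError(f"regularized covariance is singular: {exc}") from exc
    denom = np.einsum("cs,cs->s", leadfield.matrix, solved)
    if np.any(denom <= 0):
        raise SourceReconError("non-positive beamformer denominator")
    weights = (solved / denom).T
    return BeamformerModel(
        weights=weights,
        regularization=regularization,
        covariance=cov,
        source_labels=list(leadfield.source_labels),
    )


def normalize_leadfield_by_type(
    leadfield: LeadField,
) -> tuple[LeadField, dict[str, float]]:
    """Scale each sensor-type row block to unit Frobenius norm.

    Returns the normalized leadfield and the per-type scaling factors; the
    same factors must be applied to the corresponding sensor data rows (see
    :func:`apply_sensor_scaling`) so that the beamformer output is unchanged.
    """
    matrix = leadfield.matrix.copy()
    factors: dict[str, float] = {}
    types = np.asarray(leadfield.sensor_types)
    for sensor_type in dict.fromkeys(leadfield.sensor_types):
        rows = np.flatnonzero(types == sensor_type)
        block_norm = np.linalg.norm(matrix[rows])
        if block_norm == 0:
            raise SourceReconError(f"all-zero leadfield block for type {sensor_type!r}")
        factors[sensor_type] = 1.0 / block_norm
        matrix[rows] *= factors[sensor_type]
    normalized = LeadField(
        matrix=matrix,
        sensor_types=list(leadfield.sensor_types),
        source_labels=list(leadfield.source_labels),
    )
    return normalized, factors


def apply_sensor_scaling(
    data: np.ndarray, sensor_types: list[str], factors: dict[str, float]
) -> np.ndarray:
    """Apply per-type scaling factors to sensor data rows (channels first)."""
    scaled = np.array(data, dtype=float, copy=True)
    types = np.asarray(sensor_types)
    for sensor_type, factor in factors.items():
        scaled[types == sensor_type] *= factor
    return scaled


def parcellate_pca(
    source_data: np.ndarray,
    roi_map: dict[str, list[int]] | list[list[int]],
    roi_names: list[str] | None = None,
    band: BandSpec | None = None,
    sampling_rate: float | None = None,
    subject_id: str | None = None,
) -> ROISeries:
    """Collapse grid-node series to one representative series per ROI.

    For each ROI the member-node series are concatenated across trials,
    centered, and projected onto their first principal component; the
    component scores are re-split into trials and re-centered per trial.
    The component sign is chosen so that its correlation with the mean
    member series is non-negative.

    ``source_data`` has shape (n_trials, n_nodes, n_samples); ``roi_map``
    maps each ROI to its member node indices (a dict keyed by ROI name, or a
    list parallel to ``roi_names``).
    """
    x = np.asarray(source_data, dtype=float)
    if x.ndim != 3:
        raise SourceReconError("source data must be 3-D (trials x nodes x samples)")
    if isinstance(roi_map, dict):
        names = list(roi_map.keys())
        members = [np.asarray(roi_map[name], dtype=int) for name in names]
    else:
        members = [np.asarray(m, dtype=int) for m in roi_map]
        names = roi_names if roi_names is not None else [
            f"roi_{k}" for k in range(len(members))
        ]
    n_trials, _, n_samples = x.shape
    out = np.empty((n_trials, len(members), n_samples))
    for k, member_idx in enumerate(members):
        if member_idx.size == 0:
            raise SourceReconError(f"ROI {names[k]!r} has no member nodes")
        # (total_time, members) matrix of concatenated trials
        block = x[:, member_idx, :].transpose(0, 2, 1).reshape(-1, member_idx.size)
        block = block - block.mean(axis=0, keepdims=True)
        if member_idx.size == 1:
            scores = block[:, 0]
        else:
            _, _, vt = np.linalg.svd(block, full_matrices=False)
            scores = block @ vt[0]
            mean_series = block.mean(axis=1)
            if np.dot(scores, mean_series) < 0:
                scores = -scores
        out[:, k, :] = scores.reshape(n_trials, n_samples)
    out -= out.mean(axis=2, keepdims=True)
    return ROISeries(
        data=out,
        roi_names=list(names),
        band=band,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
    )
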