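"""From raw sensor recordings to a gamma-band PLV matrix for one subject.

Runs the single-subject chain: two-pass FIR band-pass filter, epoching
with amplitude-based trial rejection and trial-count equalization, LCMV
beamformer inversion, PCA parcellation, and all-pairs phase-locking values.
"""

import numpy as np

from megconn import (
    BANDS,
    SimulationConfig,
    average_trial_covariance,
    epoch_and_equalize,
    fc_matrix,
    filter_twopass,
    generate_cohort,
    lcmv_weights,
    normalize_leadfield_by_type,
    parcellate_pca,
)
from megconn.sourcerecon import apply_sensor_scaling

config = SimulationConfig(
    n_group_a=2, n_group_b=1, n_rois=16, n_sensors=32,
    sampling_rate=250.0, n_trials=10, n_trials_margin=2,
    planted_links=[(0, 8), (1, 9)], coupling_a=0.6, coupling_b=0.1,
    seed=1,
)
cohort = generate_cohort(config)
recording = cohort.recordings[0]
band = BANDS["gamma"]

filtered = filter_twopass(recording, band)
leadfield, factors = normalize_leadfield_by_type(cohort.leadfield)
filtered.data = apply_sensor_scaling(filtered.data, recording.channel_types, factors)
trials = epoch_and_equalize(filtered, trial_length=4.0, n_keep=10, seed=0, band=band)
print(f"kept {trials.n_trials} x {trials.trial_length:.0f} s trials")

cov = average_trial_covariance(trials)
model = lcmv_weights(cov, leadfield, regularization=0.15)
gain = np.abs(np.einsum("sc,cs->s", model.weights, leadfield.matrix) - 1).max()
print(f"beamformer unit-gain violation: {gain:.2e}")

roi_series = parcellate_pca(
    model.apply(trials), [[k] for k in range(config.n_rois)],
    roi_names=leadfield.source_labels, band=band,
)
fc = fc_matrix(roi_series)
iu = np.triu_indices(config.n_rois, k=1)
print(f"PLV over {iu[0].size} ROI pairs: median {np.median(fc.values[iu]):.3f}")
print(f"planted pair (0,8) PLV: {fc.values[0, 8]:.3f}  "
      f"(subject is in the strongly coupled group)")
# The planted pair sits above the background PLV; the contrast is milder
# than at the raw phase level because the narrow gamma passband removes part
# of the oscillators' phase noise, raising background phase locking.
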