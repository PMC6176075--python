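"""Synthetic two-group MEG cohorts with a planted connectivity difference.

The generator emulates a resting-state study design of 36 older
participants split by genotype into a reference group ("Val/Val", n=20)
and a test group ("Val/Met", n=16), with a planted antero-posterior
subnetwork whose phase coupling is weaker in the test group ("diminished
FC"), an age covariate, and cognitive scores positively tied to the planted
subnetwork's connectivity.

Oscillator model
----------------
Each ROI r carries a narrowband oscillator

    x_r(t) = cos( 2*pi*f_c*t + theta_r + delta_r(t) ),

where f_c is the band center and delta_r is a stationary Gaussian phase
deviation with variance v_r (rad^2) and a short coherence time tau
(AR(1) latents).  Phase coupling on a planted link (i, j) with strength
kappa in [0, 1] is introduced linearly: both ROIs load a common
unit-variance latent with variance fraction kappa,

    delta_r = sqrt(v_r) * ( sum_L sqrt(kappa_L) xi_L + sqrt(1 - sum_L kappa_L) xi_r ),

so the phase difference of a planted pair has variance
v_i + v_j - 2*kappa*sqrt(v_i*v_j) and the model PLV is

    PLV(i, j) ~= exp( -(v_i + v_j - 2*kappa*sqrt(v_i*v_j)) / 2 ).

kappa = 1 gives identical phases (PLV = 1); kappa = 0 gives independent
oscillators; expected PLV is increasing in kappa.  Because the phase
deviation is parametrized per unit *time* (variance + coherence time), the
PLV operating point depends on the trial duration in seconds but not on
the sampling rate, so scaled-down sampling rates sample the same
population.

Between-subject structure comes from log-normal jitter of the phase
deviation variance: a global per-subject factor (overall synchrony level)
and a per-subject/per-ROI factor (regional SNR), both of which move many
links of a subject together -- the kind of shared variance that real
group-permutation nulls exhibit.

Sensor mixing is plain linear projection through a leadfield plus white
Gaussian sensor noise.  No head modelling, 1/f background or artifact
simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from . import connectivity
from .nbs import SubjectTable
from .preprocess import SensorRecording
from .rois import default_roi_labels, roi_index
from .sourcerecon import LeadField

import pandas as pd


class SynthError(ValueError):
    """Invalid simulation configuration or inputs."""


#: Calibrated defaults: phase-deviation variance and planted couplings such
#: that, at the 20-trial x 4-s design, the measured trial-averaged PLV is
#: ~0.110 on unplanted pairs, ~0.149 on planted links in the reference
#: group and ~0.123 in the test group (the Val/Val vs Val/Met operating
#: point).  Obtained with :func:`calibrate_coupling` / :func:`calibrate_baseline`.
DEFAULT_PHASE_DEV_VAR = 2.2325
DEFAULT_COUPLING_A = 0.1416
DEFAULT_COUPLING_B = 0.0536

_SCORE_SPECS = (
    ("score_fds", 8.4),    # forward digit span
    ("score_bds", 5.7),    # backward digit span
    ("score_phf", 14.3),   # phonemic fluency
)


def default_planted_links(labels: Sequence[str] | None = None) -> list[tuple[int, int]]:
    """The default planted subnetwork: an 8-node antero-posterior motif.

    Both lateral superior occipital hubs couple to each of six
    frontal/prefrontal ROIs (superior frontal, orbital superior frontal,
    supplementary motor, gyrus rectus, anterior cingulate), i.e. a complete
    posterior-to-anterior bipartite motif of 12 links over 8 nodes in which
    every planted link is a long-range antero-posterior connection -- the
    topology the analysis is designed to detect.  The hubs are not directly
    linked to each other.
    """
    labels = list(labels) if labels is not None else default_roi_labels()
    hubs = ("lLSOcc", "rLSOcc")
    frontal = ("rSFG", "lSFo", "rSFo", "rMotor", "lRectus", "lACC")
    links = []
    for hub in hubs:
        for front in frontal:
            i, j = roi_index(hub, labels), roi_index(front, labels)
            links.append((min(i, j), max(i, j)))
    return sorted(links)


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort (the study conditions).

    All randomness flows from ``seed`` through a fixed seed-splitting
    scheme (subject-level streams are spawned in subject order), so equal
    configs give byte-identical cohorts.
    """

    n_group_a: int = 20                  # reference group (Val/Val analogue)
    n_group_b: int = 16                  # test group (Val/Met analogue)
    n_rois: int = 72
    n_sensors: int = 96
    sampling_rate: float = 1000.0        # Hz
    trial_length: float = 4.0            # seconds
    n_trials: int = 20
    n_trials_margin: int = 4             # extra trials recorded for rejection headroom
    band: tuple[float, float] = (30.0, 45.0)
    band_name: str = "gamma"
    planted_links: list[tuple[int, int]] = field(default_factory=default_planted_links)
    coupling_a: float = DEFAULT_COUPLING_A
    coupling_b: float = DEFAULT_COUPLING_B
    phase_dev_var: float = DEFAULT_PHASE_DEV_VAR   # v0, rad^2
    coherence_time: float = 0.0025       # s, AR(1) latent time constant
    global_jitter_sd: float = 0.006      # per-subject log-variance jitter
    node_jitter_sd: float = 0.005        # per-subject x ROI log-variance jitter
    coupling_jitter_sd: float = 0.0      # per-subject x link coupling jitter
    sensor_noise_sd: float = 0.2         # additive white noise, signal units
    two_sensor_types: bool = False
    age_range: tuple[float, float] = (60.0, 80.0)
    age_group_gap: float = 0.0           # years added to test-group ages (confound mode)
    age_fc_slope: float = 0.0            # log-variance change per year (confound mode)
    score_effect: float = 75.0           # score units per unit of model strength
    score_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.sampling_rate))

    @property
    def carrier_freq(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])

    def validate(self) -> None:
        low, high = self.band
        if not (0.0 < low < high < self.sampling_rate / 2):
            raise SynthError(
                f"invalid band {self.band} for sampling rate {self.sampling_rate}"
            )
        for name in ("coupling_a", "coupling_b"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SynthError(f"{name}={value} outside [0, 1]")
        if min(self.n_group_a, self.n_group_b) < 1:
            raise SynthError("both groups need at least one subject")
        if self.phase_dev_var <= 0 or self.coherence_time <= 0:
            raise SynthError("phase_dev_var and coherence_time must be positive")
        if abs(self.trial_length * self.sampling_rate - self.n_samples) > 1e-9:
            raise SynthError("trial_length x sampling_rate must be an integer")
        node_load = np.zeros(self.n_rois)
        for i, j in self.planted_links:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise SynthError(f"planted link ({i}, {j}) outside ROI range")
            if i >= j:
                raise SynthError(
                    f"planted link ({i}, {j}) must be canonical (i < j, no self-loops)"
                )
            node_load[[i, j]] += 1
        if len(set(self.planted_links)) != len(self.planted_links):
            raise SynthError("duplicate planted links")
        kappa_max = max(self.coupling_a, self.coupling_b) + 4 * self.coupling_jitter_sd
        if node_load.max() * kappa_max > 1.0:
            raise SynthError(
                "per-node coupling budget exceeded: a ROI's planted couplings "
                "must sum to at most 1"
            )


@dataclass
class SyntheticCohort:
    """A fully generated cohort: recordings, metadata, forward model, truth."""

    recordings: list[SensorRecording]
    metadata: SubjectTable
    leadfield: LeadField
    ground_truth: dict
    config: SimulationConfig
    sources: np.ndarray | None = None


# ---------------------------------------------------------------------------
# latent cohort structure (shared between metadata and signal generation)
# ---------------------------------------------------------------------------

@dataclass
class _CohortLatents:
    groups: np.ndarray          # str array, length S
    ages: np.ndarray
    education: np.ndarray
    node_log_var: np.ndarray    # (S, R) log-variance offsets incl. global jitter
    kappas: np.ndarray          # (S, L) per-subject link couplings
    score_noise: np.ndarray     # (S, n_scores)
    true_strength: np.ndarray   # (S,) model PLV averaged over planted links


def _root_streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    latent_ss, leadfield_ss, subjects_ss, noise_ss = root.spawn(4)
    return latent_ss, leadfield_ss, subjects_ss, noise_ss


def _draw_latents(config: SimulationConfig) -> _CohortLatents:
    latent_ss, _, _, _ = _root_streams(config)
    rng = np.random.default_rng(latent_ss)
    s, r = config.n_subjects, config.n_rois
    links = config.planted_links
    groups = np.array(
        ["Val/Val"] * config.n_group_a + ["Val/Met"] * config.n_group_b
    )
    ages = rng.uniform(*config.age_range, size=s)
    ages[groups == "Val/Met"] += config.age_group_gap
    education = np.clip(rng.normal(12.0, 4.5, size=s), 4.0, 20.0)
    gamma = rng.normal(0.0, config.global_jitter_sd, size=s)
    eta = rng.normal(0.0, config.node_jitter_sd, size=(s, r))
    kappa_jitter = rng.normal(0.0, config.coupling_jitter_sd, size=(s, len(links)))
    score_noise = rng.normal(0.0, config.score_noise_sd, size=(s, len(_SCORE_SPECS)))

    node_log_var = (
        gamma[:, None]
        + eta
        + config.age_fc_slope * (ages[:, None] - np.mean(config.age_range))
    )
    base = np.where(groups == "Val/Met", config.coupling_b, config.coupling_a)
    kappas = np.clip(base[:, None] + kappa_jitter, 0.0, 1.0)
    # keep each ROI's total latent load within budget
    for subj in range(s):
        load = np.zeros(r)
        for l, (i, j) in enumerate(links):
            load[[i, j]] += kappas[subj, l]
        worst = load.max()
        if worst > 1.0:
            kappas[subj] *= 1.0 / worst

    v = config.phase_dev_var * np.exp(node_log_var)  # (S, R)
    strength = np.empty(s)
    for subj in range(s):
        plvs = [
            np.exp(
                -0.5
                * (
                    v[subj, i]
                    + v[subj, j]
                    - 2 * kappas[subj, l] * np.sqrt(v[subj, i] * v[subj, j])
                )
            )
            for l, (i, j) in enumerate(links)
        ]
        strength[subj] = np.mean(plvs) if plvs else np.nan
    return _CohortLatents(
        groups=groups,
        ages=ages,
        education=education,
        node_log_var=node_log_var,
        kappas=kappas,
        score_noise=score_noise,
        true_strength=strength,
    )


# ---------------------------------------------------------------------------
# oscillator signal generation
# ---------------------------------------------------------------------------

def _ar1_unit(rng: np.random.Generator, n_series: int, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) latents, standardized per realization.

    Each series is scaled to exact zero empirical mean and unit empirical
    variance over the generated stretch, so the finite-sample power wobble
    of individual latent realizations does not leak into between-subject
    connectivity variance: all between-subject structure flows from the
    explicit jitter parameters of the config.
    """
    x0 = rng.standard_normal(n_series)
    white = rng.standard_normal((n_series, n))
    innov_sd = np.sqrt(1.0 - rho**2)
    with np.errstate(under="ignore"):
        decay = np.power(rho, np.arange(n))
    driven = lfilter([1.0], [1.0, -rho], innov_sd * white, axis=-1)
    series = x0[:, None] * decay[None, :] + driven
    series -= series.mean(axis=-1, keepdims=True)
    series /= series.std(axis=-1, keepdims=True)
    return series


def _subject_phases(
    config: SimulationConfig,
    rng: np.random.Generator,
    node_log_var: np.ndarray,
    kappas: np.ndarray,
    n_total: int,
) -> np.ndarray:
    """Continuous phases (n_rois, n_total) for one subject."""
    r = config.n_rois
    links = config.planted_links
    n_lat = len(links)
    rho = float(np.exp(-1.0 / (config.coherence_time * config.sampling_rate)))
    latents = _ar1_unit(rng, n_lat + r, n_total, rho)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=r)

    own = np.ones(r)
    weights = np.zeros((r, n_lat + r))
    for l, (i, j) in enumerate(links):
        weights[i, l] = weights[j, l] = np.sqrt(kappas[l])
        own[i] -= kappas[l]
        own[j] -= kappas[l]
    weights[np.arange(r), n_lat + np.arange(r)] = np.sqrt(np.clip(own, 0.0, None))

    sd = np.sqrt(config.phase_dev_var * np.exp(node_log_var))
    delta = weights @ latents
    # pin each ROI's realized deviation power to its configured value, so
    # between-subject/-node variance is exactly the explicit jitter structure
    delta *= sd[:, None] / delta.std(axis=-1, keepdims=True)
    t = np.arange(n_total) / config.sampling_rate
    return 2.0 * np.pi * config.carrier_freq * t[None, :] + theta0[:, None] + delta


def _subject_rngs(config: SimulationConfig) -> list[np.random.Generator]:
    _, _, subjects_ss, _ = _root_streams(config)
    return [np.random.default_rng(ss) for ss in subjects_ss.spawn(config.n_subjects)]


def simulate_source_phases(
    config: SimulationConfig, include_margin: bool = False
) -> np.ndarray:
    """Instantaneous source phases, shape (subjects, trials, ROIs, samples).

    Phases are continuous across trial boundaries (trials are consecutive
    cuts of one recording).  Intended for small problems and for the
    phase-level fast path; memory grows as S*T*R*N.
    """
    latents = _draw_latents(config)
    n_trials = config.n_trials + (config.n_trials_margin if include_margin else 0)
    n_total = n_trials * config.n_samples
    out = np.empty(
        (config.n_subjects, n_trials, config.n_rois, config.n_samples)
    )
    for subj, rng in enumerate(_subject_rngs(config)):
        phases = _subject_phases(
            config, rng, latents.node_log_var[subj], latents.kappas[subj], n_total
        )
        out[subj] = phases.reshape(
            config.n_rois, n_trials, config.n_samples
        ).transpose(1, 0, 2)
    return out


def simulate_sources(config: SimulationConfig) -> np.ndarray:
    """Band-limited oscillatory source series (subjects x trials x ROIs x samples)."""
    total = (
        config.n_subjects * config.n_trials * config.n_rois * config.n_samples
    )
    if total > 4e8:
        raise SynthError(
            "source array would exceed ~3 GB; generate per subject instead "
            "(simulate_source_phases / cohort_plv_stack stream subjects)"
        )
    return np.cos(simulate_source_phases(config))


def cohort_plv_stack(
    config: SimulationConfig,
    edge_fraction: float = 0.0,
    dtype: np.dtype | type = np.complex64,
) -> np.ndarray:
    """Per-subject PLV matrices straight from the source phases.

    Streams one subject at a time (memory stays at one subject's phases)
    and computes the trial-averaged PLV stack (subjects x ROIs x ROIs).
    This is the phase-level fast path used by the Monte-Carlo experiment
    drivers; the sensor -> beamformer -> Hilbert chain is exercised by the
    full pipeline instead.
    """
    latents = _draw_latents(config)
    n_total = config.n_trials * config.n_samples
    stack = np.empty((config.n_subjects, config.n_rois, config.n_rois))
    for subj, rng in enumerate(_subject_rngs(config)):
        phases = _subject_phases(
            config, rng, latents.node_log_var[subj], latents.kappas[subj], n_total
        )
        trials = phases.reshape(
            config.n_rois, config.n_trials, config.n_samples
        ).transpose(1, 0, 2)
        stack[subj] = connectivity.fc_from_phases(
            trials, edge_fraction=edge_fraction, dtype=dtype
        )
    return stack


# ---------------------------------------------------------------------------
# leadfield and sensor mixing
# ---------------------------------------------------------------------------

def make_leadfield(config: SimulationConfig) -> LeadField:
    """Random dense leadfield with unit-norm source columns.

    In two-sensor-type mode the second half of the sensors ("grad") is
    scaled by 100 relative to the first half ("mag"), exercising the
    per-type leadfield normalization.
    """
    _, leadfield_ss, _, _ = _root_streams(config)
    rng = np.random.default_rng(leadfield_ss)
    matrix = rng.standard_normal((config.n_sensors, config.n_rois))
    matrix /= np.linalg.norm(matrix, axis=0, keepdims=True)
    if config.two_sensor_types:
        half = config.n_sensors // 2
        matrix[half:] *= 100.0
        types = ["mag"] * half + ["grad"] * (config.n_sensors - half)
    else:
        types = ["mag"] * config.n_sensors
    return LeadField(
        matrix=matrix,
        sensor_types=types,
        source_labels=default_roi_labels()[: config.n_rois]
        if config.n_rois <= 72
        else [f"roi_{k}" for k in range(config.n_rois)],
    )


def mix_to_sensors(
    sources: np.ndarray,
    leadfield: LeadField,
    sensor_noise_sd: float,
    sampling_rate: float,
    seed: int | np.random.SeedSequence | None = None,
) -> list[SensorRecording]:
    """Project source series through the leadfield and add sensor noise.

    ``sources`` has shape (subjects, trials, n_sources, samples); trials
    are concatenated back into one continuous recording per subject.
    Deterministic given ``seed``.
    """
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 4:
        raise SynthError("sources must be 4-D (subjects x trials x sources x samples)")
    if sources.shape[2] != leadfield.n_sources:
        raise SynthError(
            f"{sources.shape[2]} sources but leadfield has {leadfield.n_sources} columns"
        )
    n_subjects, n_trials, _, n_samples = sources.shape
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    recordings = []
    for subj, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        continuous = sources[subj].transpose(1, 0, 2).reshape(
            leadfield.n_sources, n_trials * n_samples
        )
        data = leadfield.matrix @ continuous
        if sensor_noise_sd > 0:
            data = data + rng.normal(0.0, sensor_noise_sd, size=data.shape)
        recordings.append(
            SensorRecording(
                data=data,
                sampling_rate=sampling_rate,
                channel_types=list(leadfield.sensor_types),
                subject_id=f"sub-{subj + 1:03d}",
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# metadata and full cohorts
# ---------------------------------------------------------------------------

def generate_metadata(config: SimulationConfig) -> SubjectTable:
    """Subject table: group, age, education and cognitive scores.

    Ages are uniform over ``age_range`` (independent of group unless
    ``age_group_gap`` is set); each cognitive score is
    ``intercept + score_effect * (subject's model subnetwork strength,
    centered) + Gaussian noise``, giving the downstream Spearman
    correlations a known positive sign.
    """
    latents = _draw_latents(config)
    centered = latents.true_strength - np.nanmean(latents.true_strength)
    frame = pd.DataFrame(
        {
            "subject_id": [f"sub-{k + 1:03d}" for k in range(config.n_subjects)],
            "group": latents.groups,
            "age": latents.ages,
            "education": latents.education,
        }
    )
    for idx, (name, intercept) in enumerate(_SCORE_SPECS):
        frame[name] = (
            intercept
            + config.score_effect * centered
            + latents.score_noise[:, idx]
        )
    return SubjectTable(frame=frame)


def generate_cohort(
    config: SimulationConfig, keep_sources: bool = False
) -> SyntheticCohort:
    """Generate the full cohort: sensor recordings, metadata, leadfield, truth.

    Recordings contain ``n_trials + n_trials_margin`` trials' worth of
    continuous signal so that the preprocessing stage has rejection
    headroom while still keeping exactly ``n_trials`` per subject.
    """
    latents = _draw_latents(config)
    leadfield = make_leadfield(config)
    _, _, _, noise_ss = _root_streams(config)
    n_trials = config.n_trials + config.n_trials_margin
    n_total = n_trials * config.n_samples
    sources = np.empty((config.n_subjects, n_trials, config.n_rois, config.n_samples))
    for subj, rng in enumerate(_subject_rngs(config)):
        phases = _subject_phases(
            config, rng, latents.node_log_var[subj], latents.kappas[subj], n_total
        )
        sources[subj] = np.cos(
            phases.reshape(config.n_rois, n_trials, config.n_samples).transpose(1, 0, 2)
        )
    recordings = mix_to_sensors(
        sources, leadfield, config.sensor_noise_sd, config.sampling_rate, noise_ss
    )
    metadata = generate_metadata(config)
    labels = leadfield.source_labels
    ground_truth = {
        "planted_links": [[int(i), int(j)] for i, j in config.planted_links],
        "planted_link_labels": [
            [labels[i], labels[j]] for i, j in config.planted_links
        ],
        "coupling_a": config.coupling_a,
        "coupling_b": config.coupling_b,
        "model_plv_a": float(
            np.exp(-config.phase_dev_var * (1.0 - config.coupling_a))
        ),
        "model_plv_b": float(
            np.exp(-config.phase_dev_var * (1.0 - config.coupling_b))
        ),
        "true_strength": latents.true_strength.tolist(),
        "seed": config.seed,
    }
    return SyntheticCohort(
        recordings=recordings,
        metadata=metadata,
        leadfield=leadfield,
        ground_truth=ground_truth,
        config=config,
        sources=sources if keep_sources else None,
    )


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

def measured_pair_plv(
    kappa: float,
    config: SimulationConfig,
    n_reps: int = 150,
    seed: int = 12345,
) -> float:
    """Mean measured (trial-averaged) PLV of a single planted pair.

    Simulates ``n_reps`` independent subjects carrying one planted link with
    coupling ``kappa`` and no between-subject jitter, at the config's trial
    design, and returns the grand mean PLV -- the quantity the calibration
    targets.
    """
    pair_config = replace(
        config,
        n_rois=2,
        planted_links=[(0, 1)] if kappa > 0 else [],
        coupling_a=min(kappa, 1.0) if kappa > 0 else 0.0,
        coupling_b=min(kappa, 1.0) if kappa > 0 else 0.0,
        global_jitter_sd=0.0,
        node_jitter_sd=0.0,
        coupling_jitter_sd=0.0,
    )
    rng = np.random.default_rng(seed)
    n_total = pair_config.n_trials * pair_config.n_samples
    kappas = np.array([kappa]) if kappa > 0 else np.array([])
    plvs = np.empty(n_reps)
    for rep in range(n_reps):
        phases = _subject_phases(
            pair_config, rng, np.zeros(2), kappas, n_total
        )
        trials = phases.reshape(2, pair_config.n_trials, pair_config.n_samples)
        plvs[rep] = connectivity.plv_pair(trials[0], trials[1], edge_fraction=0.0)
    return float(plvs.mean())


def calibrate_coupling(
    target_plv: float,
    config: SimulationConfig,
    n_reps: int = 150,
    seed: int = 12345,
    tol: float = 5e-4,
) -> float:
    """Coupling kappa whose measured pair PLV matches ``target_plv``.

    Monotone bisection on kappa in [0, 0.98] against
    :func:`measured_pair_plv`; used once to fix the packaged defaults and
    available for re-calibration under different trial designs.
    """
    lo, hi = 0.0, 0.98
    f_lo = measured_pair_plv(lo, config, n_reps, seed)
    if target_plv <= f_lo:
        return lo
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        f_mid = measured_pair_plv(mid, config, n_reps, seed)
        if abs(f_mid - target_plv) < tol:
            return mid
        if f_mid < target_plv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_baseline(
    target_plv: float,
    config: SimulationConfig,
    n_reps: int = 150,
    seed: int = 12345,
    tol: float = 5e-4,
) -> float:
    """Phase-deviation variance v0 whose unplanted-pair PLV matches target."""
    lo, hi = 0.3, 8.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        plv = measured_pair_plv(0.0, replace(config, phase_dev_var=mid), n_reps, seed)
        if abs(plv - target_plv) < tol:
            return mid
        if plv > target_plv:   # less noise -> higher PLV; increase variance
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
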