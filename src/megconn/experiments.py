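"""Monte-Carlo validation experiments for the whole analysis chain.

These drivers quantify, on synthetic cohorts, the statistical properties
the pipeline is supposed to have: family-wise error control of the NBS
permutation test under a null cohort, power and subnetwork recovery under
the planted two-group effect at the study's PLV gap (~0.026), the Rayleigh
floor of the PLV estimator, LCMV source recovery, agreement of the ANCOVA
F with an independent normal-equations oracle, and the behaviour of the
LOO logistic classifier on label-shuffled (null) features.

Problem sizes: the drivers keep the full 20 x 4 s trial design of the
study but run at reduced sampling rates (the generator's PLV operating
point is invariant to the rate; see `megconn.synth`): 250 Hz for the power
experiment and 125 Hz for the 200-repetition FWER calibration, which keeps
both inside a desktop compute budget.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .connectivity import plv_pair
from .downstream import loo_logistic_classify
from .nbs import Subnetwork, nbs_permutation
from .sourcerecon import LeadField, lcmv_weights
from .synth import SimulationConfig, _draw_latents, cohort_plv_stack, generate_metadata


def study_config(sampling_rate: float = 250.0, seed: int = 0, **overrides) -> SimulationConfig:
    """The packaged study conditions (36 subjects, 72 ROIs, planted subnetwork)."""
    return SimulationConfig(sampling_rate=sampling_rate, seed=seed, **overrides)


def null_config(sampling_rate: float = 250.0, seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions with no planted group effect (equal couplings)."""
    cfg = study_config(sampling_rate=sampling_rate, seed=seed, **overrides)
    return replace(cfg, coupling_a=cfg.coupling_b)


def _spawn_ints(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2**31 - 1, size=n)


def fwer_calibration(
    n_reps: int = 200,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> dict:
    """Fraction of null cohorts on which NBS declares any subnetwork.

    Each repetition draws a fresh null cohort (no planted effect), computes
    the PLV stack at the phase level and runs the full NBS permutation test;
    a repetition counts as a rejection when any subnetwork reaches
    ``p_fwer < alpha``.  Under valid FWER control the rejection fraction
    should sit at or just below ``alpha``.
    """
    if base_config is None:
        base_config = null_config(sampling_rate=125.0)
    rng = np.random.default_rng(seed)
    cohort_seeds = _spawn_ints(rng, n_reps)
    perm_seeds = _spawn_ints(rng, n_reps)
    rejections = 0
    for rep in range(n_reps):
        cfg = replace(base_config, seed=int(cohort_seeds[rep]))
        fc = cohort_plv_stack(cfg)
        table = generate_metadata(cfg)
        result = nbs_permutation(
            fc, table, n_perm=n_perm, seed=int(perm_seeds[rep])
        )
        if any(p < alpha for p in result.p_fwer):
            rejections += 1
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "n_perm": n_perm,
        "alpha": alpha,
    }


def link_jaccard(subnetwork: Subnetwork, planted: list[tuple[int, int]]) -> float:
    """Jaccard index between a subnetwork's link set and the planted links."""
    found = subnetwork.link_set()
    truth = {(min(i, j), max(i, j)) for i, j in planted}
    union = found | truth
    return len(found & truth) / len(union) if union else 0.0


def power_recovery(
    n_reps: int = 50,
    n_perm: int = 500,
    alpha: float = 0.05,
    jaccard_threshold: float = 0.7,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> dict:
    """Detection and recovery of the planted subnetwork across cohorts.

    A repetition is a *detection* when some diminished-direction subnetwork
    reaches ``p_fwer < alpha``; it is a *recovery* when additionally the
    best such subnetwork's link set overlaps the planted links with a
    Jaccard index above ``jaccard_threshold``.  Also reports the measured
    group-mean subnetwork strengths (reference vs test group PLV levels).
    """
    if base_config is None:
        base_config = study_config()
    planted = base_config.planted_links
    rows = np.array([i for i, _ in planted])
    cols = np.array([j for _, j in planted])
    rng = np.random.default_rng(seed)
    cohort_seeds = _spawn_ints(rng, n_reps)
    perm_seeds = _spawn_ints(rng, n_reps)
    detections = recoveries = 0
    jaccards = []
    strengths_a = []
    strengths_b = []
    for rep in range(n_reps):
        cfg = replace(base_config, seed=int(cohort_seeds[rep]))
        fc = cohort_plv_stack(cfg)
        table = generate_metadata(cfg)
        strength = fc[:, rows, cols].mean(axis=1)
        is_b = table.group_indicator.astype(bool)
        strengths_a.append(strength[~is_b].mean())
        strengths_b.append(strength[is_b].mean())
        result = nbs_permutation(
            fc, table, n_perm=n_perm, seed=int(perm_seeds[rep])
        )
        hits = [
            s
            for s in result.subnetworks
            if s.p_fwer is not None and s.p_fwer < alpha and s.direction < 0
        ]
        if hits:
            detections += 1
            best = max(hits, key=lambda s: s.network_stat)
            jac = link_jaccard(best, planted)
            jaccards.append(jac)
            if jac > jaccard_threshold:
                recoveries += 1
    return {
        "detection_rate": detections / n_reps,
        "recovery_rate": recoveries / n_reps,
        "mean_jaccard": float(np.mean(jaccards)) if jaccards else 0.0,
        "group_a_strength": float(np.mean(strengths_a)),
        "group_b_strength": float(np.mean(strengths_b)),
        "n_reps": n_reps,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# estimator-level checks
# ---------------------------------------------------------------------------

def rayleigh_floor(
    n_samples: int = 4000, n_trials: int = 400, seed: int = 0
) -> dict:
    """Mean PLV of independent uniform phases vs the Rayleigh resultant floor.

    For T iid uniform phase differences the expected resultant length is
    E[R] = sqrt(pi) / (2 sqrt(T)); the measured per-trial mean should match
    it within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    phase_i = rng.uniform(0, 2 * np.pi, size=(n_trials, n_samples))
    phase_j = rng.uniform(0, 2 * np.pi, size=(n_trials, n_samples))
    measured = plv_pair(phase_i, phase_j, edge_fraction=0.0)
    theory = np.sqrt(np.pi) / (2.0 * np.sqrt(n_samples))
    return {"measured": float(measured), "theory": float(theory), "T": n_samples}


def lcmv_recovery(
    n_sensors: int = 20,
    n_sources: int = 5,
    n_samples: int = 4000,
    snr: float = 10.0,
    seed: int = 0,
) -> dict:
    """Beamformer round trip on a known mixing problem.

    Uncorrelated unit-variance sources are mixed through a random
    unit-column leadfield at the given per-channel SNR (signal variance /
    noise variance); reports the worst unit-gain violation and the worst
    correlation between reconstructed and true sources.
    """
    rng = np.random.default_rng(seed)
    mixing = rng.standard_normal((n_sensors, n_sources))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    sources = rng.standard_normal((n_sources, n_samples))
    signal = mixing @ sources
    noise_sd = np.sqrt(signal.var() / snr)
    data = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    cov = np.cov(data)
    model = lcmv_weights(cov, LeadField(matrix=mixing), regularization=0.15)
    recon = model.weights @ data
    gain_err = np.abs(np.einsum("sc,cs->s", model.weights, mixing) - 1.0).max()
    corrs = [
        np.corrcoef(recon[k], sources[k])[0, 1] for k in range(n_sources)
    ]
    return {
        "max_unit_gain_error": float(gain_err),
        "min_source_correlation": float(min(corrs)),
    }


def ancova_f_oracle(y: np.ndarray, group: np.ndarray, age: np.ndarray) -> float:
    """Drop-one group F via explicit normal equations (independent oracle).

    Fits FC ~ 1 + group + age and FC ~ 1 + age by solving the normal
    equations directly and forms F = (SSE_red - SSE_full) / (SSE_full /
    (n - 3)).  Shares no code path with `megconn.nbs.link_ancova`.
    """
    n = y.size
    x_full = np.column_stack([np.ones(n), group, age])
    x_red = np.column_stack([np.ones(n), age])
    beta_full = np.linalg.inv(x_full.T @ x_full) @ (x_full.T @ y)
    beta_red = np.linalg.inv(x_red.T @ x_red) @ (x_red.T @ y)
    sse_full = np.sum((y - x_full @ beta_full) ** 2)
    sse_red = np.sum((y - x_red @ beta_red) ** 2)
    return float((sse_red - sse_full) / (sse_full / (n - 3)))


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho by brute-force mid-rank computation (independent oracle)."""
    def midranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size, dtype=float)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def null_classifier_accuracy(
    n_sims: int = 1000,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> dict:
    """Mean LOO logistic accuracy on label-shuffled (null) features.

    Each simulation draws a fresh cohort's model subnetwork strength as the
    feature and shuffles the group labels, so the feature carries no group
    information.  An intercept-only classifier would score the
    majority-class rate (20/36 for the study design); the exact-MLE LOO
    logistic scores systematically *below* it, because the slope fitted to
    pure noise in each training fold anti-correlates with the held-out
    subject (the pessimistic bias of leave-one-out on null features).
    """
    if base_config is None:
        base_config = study_config()
    labels = np.array(
        [0] * base_config.n_group_a + [1] * base_config.n_group_b
    )
    rng = np.random.default_rng(seed)
    accuracies = np.empty(n_sims)
    for sim in range(n_sims):
        cfg = replace(base_config, seed=int(rng.integers(0, 2**31 - 1)))
        feature = _draw_latents(cfg).true_strength
        shuffled = rng.permutation(labels)
        report = loo_logistic_classify(feature, shuffled)
        accuracies[sim] = report.accuracy
    majority = max(base_config.n_group_a, base_config.n_group_b) / base_config.n_subjects
    return {
        "mean_accuracy": float(accuracies.mean()),
        "majority_rate": float(majority),
        "n_sims": n_sims,
    }
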