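"""Link ANCOVA, component extraction, and the NBS permutation test."""

import numpy as np
import pandas as pd
import pytest

from megconn.experiments import ancova_f_oracle
from megconn.nbs import (
    LinkStatMap,
    NBSError,
    SubjectTable,
    extract_components,
    link_ancova,
    min_subnetwork_size,
    nbs_permutation,
)
from megconn.downstream import strength_ancova
from megconn.synth import SimulationConfig, cohort_plv_stack, generate_metadata


def _random_dataset(g, n=12, n_rois=4):
    fc = g.uniform(0.05, 0.3, size=(n, n_rois, n_rois))
    fc = 0.5 * (fc + fc.transpose(0, 2, 1))
    for k in range(n):
        np.fill_diagonal(fc[k], 1.0)
    n_b = n // 3
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["Val/Val"] * (n - n_b) + ["Val/Met"] * n_b,
            "age": g.uniform(60, 80, size=n),
        }
    )
    return fc, SubjectTable(frame=frame)


class TestSubjectTable:
    def test_missing_column_rejected(self):
        with pytest.raises(NBSError, match="age"):
            SubjectTable(pd.DataFrame({"subject_id": ["a"], "group": ["Val/Val"]}))

    def test_duplicate_ids_rejected(self):
        frame = pd.DataFrame(
            {"subject_id": ["a", "a"], "group": ["Val/Val", "Val/Met"],
             "age": [60.0, 61.0]}
        )
        with pytest.raises(NBSError, match="duplicate"):
            SubjectTable(frame)

    def test_missing_age_reported_with_row(self):
        frame = pd.DataFrame(
            {"subject_id": ["a", "b"], "group": ["Val/Val", "Val/Met"],
             "age": [60.0, np.nan]}
        )
        with pytest.raises(NBSError, match="rows \\[2\\]"):
            SubjectTable(frame)

    def test_empty_group_rejected(self):
        frame = pd.DataFrame(
            {"subject_id": ["a", "b"], "group": ["Val/Val", "Val/Val"],
             "age": [60.0, 61.0]}
        )
        with pytest.raises(NBSError, match="Val/Met"):
            SubjectTable(frame)


class TestLinkAncova:
    def test_matches_normal_equations_oracle(self):
        g = np.random.default_rng(123)
        for _ in range(100):
            fc, table = _random_dataset(g, n=int(g.integers(8, 20)))
            stats = link_ancova(fc, table)
            group = table.group_indicator
            age = table.age
            iu = np.triu_indices(fc.shape[1], k=1)
            for i, j in zip(*iu):
                expected = ancova_f_oracle(fc[:, i, j], group, age)
                assert stats.F[i, j] == pytest.approx(
                    expected, abs=1e-10 * max(1.0, abs(expected))
                )

    def test_matches_statsmodels_anova(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        g = np.random.default_rng(7)
        fc, table = _random_dataset(g, n=16)
        stats = link_ancova(fc, table)
        frame = pd.DataFrame(
            {
                "y": fc[:, 0, 1],
                "grp": table.group_indicator,
                "age": table.age,
            }
        )
        fit = ols("y ~ grp + age", data=frame).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        assert stats.F[0, 1] == pytest.approx(anova.loc["grp", "F"], rel=1e-8)
        assert stats.p[0, 1] == pytest.approx(anova.loc["grp", "PR(>F)"], rel=1e-8)

    def test_scale_invariance_of_f(self):
        g = np.random.default_rng(11)
        fc, table = _random_dataset(g, n=14)
        base = link_ancova(fc, table)
        rescaled_frame = table.frame.copy()
        rescaled_frame["age"] = table.age * 12.0 - 300.0
        rescaled = link_ancova(
            fc * 7.5 + 0.2, SubjectTable(frame=rescaled_frame)
        )
        assert np.allclose(base.F, rescaled.F, rtol=1e-9)

    def test_constant_link_yields_zero_f_unit_p(self):
        g = np.random.default_rng(5)
        fc, table = _random_dataset(g, n=10)
        fc[:, 0, 1] = fc[:, 1, 0] = 0.2
        stats = link_ancova(fc, table)
        assert stats.F[0, 1] == 0.0
        assert stats.p[0, 1] == 1.0

    def test_pure_age_link_has_zero_group_effect(self):
        g = np.random.default_rng(6)
        fc, table = _random_dataset(g, n=12)
        fc[:, 0, 1] = fc[:, 1, 0] = 0.01 * table.age  # fully explained by age
        stats = link_ancova(fc, table)
        assert stats.F[0, 1] == pytest.approx(0.0, abs=1e-18)
        assert stats.p[0, 1] == 1.0

    def test_direction_sign_follows_test_group_mean(self):
        g = np.random.default_rng(8)
        fc, table = _random_dataset(g, n=12)
        is_b = table.group_indicator.astype(bool)
        fc[is_b, 0, 1] += 0.5
        fc[is_b, 1, 0] += 0.5
        fc[~is_b, 0, 2] += 0.5
        fc[~is_b, 2, 0] += 0.5
        stats = link_ancova(fc, table)
        assert stats.direction[0, 1] == 1    # enhanced in test group
        assert stats.direction[0, 2] == -1   # diminished in test group

    def test_misaligned_stack_rejected(self, toy_table):
        with pytest.raises(NBSError, match="metadata"):
            link_ancova(np.zeros((5, 3, 3)), toy_table)


def _statmap(n_rois, sig_links, direction=-1):
    f = np.zeros((n_rois, n_rois))
    p = np.ones((n_rois, n_rois))
    d = np.zeros((n_rois, n_rois), dtype=np.int8)
    for (i, j), f_val in sig_links.items():
        f[i, j] = f[j, i] = f_val
        p[i, j] = p[j, i] = 0.001
        d[i, j] = d[j, i] = direction
    return LinkStatMap(F=f, p=p, direction=d, df_denom=33)


class TestExtractComponents:
    def test_ten_percent_rule_on_72_rois(self):
        assert min_subnetwork_size(72) == 7
        assert min_subnetwork_size(90) == 9
        assert min_subnetwork_size(40) == 4

    def test_chain_of_six_links_meets_min_size_seven(self):
        links = {(k, k + 1): 10.0 + k for k in range(6)}  # 7 nodes
        comps = extract_components(_statmap(72, links), min_size=7)
        assert len(comps) == 1
        assert comps[0].n_nodes == 7
        assert comps[0].network_stat == pytest.approx(sum(links.values()))
        assert comps[0].direction == -1

    def test_two_small_triangles_yield_nothing(self):
        links = {(0, 1): 9.0, (1, 2): 9.0, (0, 2): 9.0,
                 (5, 6): 9.0, (6, 7): 9.0, (5, 7): 9.0}
        assert extract_components(_statmap(72, links), min_size=7) == []

    def test_direction_consistency_splits_components(self):
        f = np.zeros((10, 10))
        p = np.ones((10, 10))
        d = np.zeros((10, 10), dtype=np.int8)
        chain = [(k, k + 1) for k in range(6)]
        for idx, (i, j) in enumerate(chain):
            f[i, j] = f[j, i] = 10.0
            p[i, j] = p[j, i] = 0.001
            sign = -1 if idx == 3 else 1  # one opposite-direction link
            d[i, j] = d[j, i] = sign
        sm = LinkStatMap(F=f, p=p, direction=d, df_denom=33)
        assert extract_components(sm, min_size=5) == []  # broken into <5-node runs
        merged = extract_components(sm, min_size=5, direction_consistent=False)
        assert len(merged) == 1 and merged[0].n_nodes == 7

    def test_node_relabeling_equivariance(self):
        g = np.random.default_rng(3)
        links = {(0, 1): 12.0, (1, 2): 11.0, (2, 3): 10.0, (3, 4): 9.5,
                 (4, 5): 9.0, (5, 6): 8.5}
        sm = _statmap(30, links)
        perm = g.permutation(30)
        sm_perm = LinkStatMap(
            F=sm.F[np.ix_(perm, perm)],
            p=sm.p[np.ix_(perm, perm)],
            direction=sm.direction[np.ix_(perm, perm)],
            df_denom=33,
        )
        a = extract_components(sm, min_size=7)
        b = extract_components(sm_perm, min_size=7)
        assert len(a) == len(b) == 1
        assert a[0].network_stat == pytest.approx(b[0].network_stat)
        inverse = np.argsort(perm)
        assert sorted(inverse[n] for n in a[0].nodes) == sorted(b[0].nodes)

    def test_bad_threshold_rejected(self):
        with pytest.raises(NBSError, match="threshold"):
            extract_components(_statmap(10, {}), p_threshold=1.5)


class TestNBSPermutation:
    def test_deterministic_given_seed(self):
        g = np.random.default_rng(21)
        fc, table = _random_dataset(g, n=14, n_rois=6)
        a = nbs_permutation(fc, table, n_perm=200, seed=5, min_size=2)
        b = nbs_permutation(fc, table, n_perm=200, seed=5, min_size=2)
        assert np.array_equal(a.null_max_stats, b.null_max_stats)
        assert a.p_fwer == b.p_fwer

    def test_observed_above_all_nulls_gives_zero_p(self):
        g = np.random.default_rng(22)
        fc, table = _random_dataset(g, n=20, n_rois=8)
        is_b = table.group_indicator.astype(bool)
        # overwhelming planted effect on a 3-node path
        for i, j in [(0, 1), (1, 2)]:
            fc[is_b, i, j] -= 0.65
            fc[is_b, j, i] -= 0.65
        result = nbs_permutation(fc, table, n_perm=200, seed=9, min_size=3)
        assert result.subnetworks, "planted component not found"
        assert result.p_fwer[0] == 0.0
        corrected = nbs_permutation(
            fc, table, n_perm=200, seed=9, min_size=3,
            small_sample_correction=True,
        )
        assert corrected.p_fwer[0] == pytest.approx(1 / 201)

    def test_small_n_perm_warns(self):
        g = np.random.default_rng(23)
        fc, table = _random_dataset(g, n=12, n_rois=4)
        with pytest.warns(UserWarning, match="coarse"):
            nbs_permutation(fc, table, n_perm=50, seed=1, min_size=2)

    def test_null_vector_length_and_range(self):
        g = np.random.default_rng(24)
        fc, table = _random_dataset(g, n=12, n_rois=5)
        result = nbs_permutation(fc, table, n_perm=150, seed=2, min_size=2)
        assert result.null_max_stats.shape == (150,)
        assert np.all(result.null_max_stats >= 0)
        for p in result.p_fwer:
            assert 0.0 <= p <= 1.0

    def test_age_confound_absorbed_by_covariate(self):
        """A pure age artifact must not masquerade as a group effect."""
        cfg = SimulationConfig(
            sampling_rate=250.0,
            trial_length=2.0,
            n_trials=10,
            coupling_a=SimulationConfig().coupling_b,  # no planted group gap
            age_group_gap=12.0,
            age_fc_slope=-0.04,  # PLV declines with age
            global_jitter_sd=0.0,
            node_jitter_sd=0.0,
            seed=31,
        )
        fc = cohort_plv_stack(cfg)
        table = generate_metadata(cfg)
        rows = np.array([i for i, _ in cfg.planted_links])
        cols = np.array([j for _, j in cfg.planted_links])
        strength = fc[:, rows, cols].mean(axis=1)
        is_b = table.group_indicator.astype(bool)
        # raw group difference is clearly present...
        from scipy import stats as sps

        t_raw, p_raw = sps.ttest_ind(strength[~is_b], strength[is_b])
        assert p_raw < 0.01
        # ...but the age-adjusted ANCOVA does not call it a group effect
        f_adj, p_adj = strength_ancova(strength, table)
        assert p_adj > 0.05
        assert f_adj < t_raw**2
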