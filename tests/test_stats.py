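"""Node-wise t-tests, max-T / Bonferroni FWE control, summary tables."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

import tractometry as tm


def oracle_t_and_p(a, b):
    """Closed-form equal-variance two-sample t and two-sided p.

    p via the regularized incomplete beta function — independent of the
    scipy.stats t-test code path.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = betainc(df / 2.0, 0.5, df / (df + t**2))
    return t, p


class TestNodewiseTtest:
    def test_printed_toy_example(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        b = a + 2.0  # {3,4,5,6,7}
        t, p, _ = tm.nodewise_ttest(a, b)
        t_o, p_o = oracle_t_and_p(a.ravel(), b.ravel())
        assert abs(t[0] - (-2.0)) < 1e-12
        assert abs(t[0] - t_o) < 1e-12
        assert abs(p[0] - p_o) < 1e-12
        assert abs(p[0] - 0.0805) < 5e-4  # df = 8

    def test_copied_group_gives_t0_p1(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(5, 8))
        t, p, degenerate = tm.nodewise_ttest(a, a.copy())
        assert np.allclose(t, 0.0) and np.allclose(p, 1.0)
        assert not degenerate.any()  # within-group variance is nonzero

    def test_zero_pooled_variance_flagged(self):
        a = np.full((4, 6), 0.3)
        t, p, degenerate = tm.nodewise_ttest(a, a.copy())
        assert np.all(t == 0.0) and np.all(p == 1.0)
        assert degenerate.all()

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 20))
        b = rng.normal(0.3, size=(7, 20))
        t_ab, p_ab, _ = tm.nodewise_ttest(a, b)
        t_ba, p_ba, _ = tm.nodewise_ttest(b, a)
        assert np.allclose(t_ab, -t_ba)
        assert np.allclose(p_ab, p_ba)

    def test_random_nodes_match_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(9, 15))
        b = rng.normal(0.5, 1.3, size=(11, 15))
        t, p, _ = tm.nodewise_ttest(a, b)
        for j in range(15):
            t_o, p_o = oracle_t_and_p(a[:, j], b[:, j])
            assert abs(t[j] - t_o) < 1e-10 and abs(p[j] - p_o) < 1e-10


class TestBonferroni:
    def test_arithmetic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 100))
        b = rng.normal(size=(10, 100))
        res = tm.fwe_correct(a, b, method="bonferroni")
        expected = np.minimum(1.0, 100 * res.p_raw)
        assert np.allclose(res.p_fwe, np.maximum(expected, res.p_raw))
        # the spec arithmetic: raw 0.0003 with 100 nodes -> adjusted 0.03
        assert abs(min(1.0, 100 * 0.0003) - 0.03) < 1e-15

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 60))
        b = rng.normal(0.2, size=(8, 60))
        res = tm.fwe_correct(a, b, method="bonferroni")
        order = np.argsort(res.p_raw)
        assert np.all(np.diff(res.p_fwe[order]) >= -1e-15)


def brute_force_maxT(a, b):
    """Independent exhaustive max-T: enumerate all label splits directly."""
    data = np.vstack([a, b])
    n, n_a = len(data), len(a)
    t_obs, _, _ = tm.nodewise_ttest(a, b)
    null = []
    for combo in itertools.combinations(range(n), n_a):
        idx_a = list(combo)
        idx_b = [i for i in range(n) if i not in combo]
        t_perm, _, _ = tm.nodewise_ttest(data[idx_a], data[idx_b])
        null.append(np.abs(t_perm).max())
    null = np.asarray(null)
    return np.array([(null >= abs(t) - 1e-12).mean() for t in t_obs])


class TestPermutationMaxT:
    def test_exhaustive_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 12))
        b = rng.normal(1.0, size=(3, 12))
        res = tm.fwe_correct(a, b, method="permutation_maxT", n_perm=None)
        expected = np.maximum(brute_force_maxT(a, b), res.p_raw)
        assert np.allclose(res.p_fwe, expected, atol=1e-12)
        # 3 + 3 subjects -> exactly C(6, 3) = 20 label splits
        assert res.n_perm == 20

    def test_all_null_gives_no_flags(self):
        a = np.tile(np.arange(5.0), (30, 1)).T.reshape(5, 30)
        res = tm.fwe_correct(a, a.copy(), method="permutation_maxT",
                             n_perm=500)
        assert np.all(res.p_fwe == 1.0)
        assert not res.significant.any()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(10, 50))
        b = rng.normal(0.4, size=(10, 50))
        r1 = tm.fwe_correct(a, b, n_perm=800, rng_seed=42)
        r2 = tm.fwe_correct(a, b, n_perm=800, rng_seed=42)
        assert np.array_equal(r1.p_fwe, r2.p_fwe)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(12, 80))
        b = rng.normal(0.3, size=(12, 80))
        for method in ("permutation_maxT", "bonferroni"):
            res = tm.fwe_correct(a, b, method=method, n_perm=600)
            assert np.all(res.p_fwe >= res.p_raw - 1e-15)
            assert np.array_equal(res.significant, res.p_fwe < res.alpha)

    def test_low_n_perm_warns_and_size_one_group_fatal(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(5, 10))
        b = rng.normal(size=(5, 10))
        with pytest.warns(UserWarning, match="very low"):
            tm.fwe_correct(a, b, n_perm=50)
        with pytest.raises(tm.DataError):
            tm.fwe_correct(a[:1], b[:1])


class TestPowerAndSpecificity:
    def test_effect_detected_and_null_tracts_clean(self):
        """Standardized mean difference 1.5 on nodes 40-60 at n = 15/group:
        the affected node range is flagged in >= 80% of replicates while
        unaffected profile sets rarely acquire any flag."""
        n_rep = 25
        detected = 0
        null_flags = 0
        for rep in range(n_rep):
            a, b = tm.simulate_profile_cohort(
                n_per_group=15, subject_sd=0.03, node_sd=0.02,
                effect_delta=1.5 * 0.03, effect_nodes=(40, 60),
                rng_seed=1000 + rep)
            res = tm.fwe_correct(a, b, n_perm=500, rng_seed=rep)
            if res.significant[39:60].any():
                detected += 1
            na, nb = tm.simulate_profile_cohort(
                n_per_group=15, subject_sd=0.03, node_sd=0.02,
                rng_seed=5000 + rep)
            nres = tm.fwe_correct(na, nb, n_perm=500, rng_seed=rep)
            if nres.significant.any():
                null_flags += 1
        assert detected / n_rep >= 0.8
        assert null_flags / n_rep <= 0.15  # ~alpha plus Monte-Carlo slack


def toy_profiles(effect_nodes=None, n_subjects=4, n_nodes=100, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("patient", "control"):
        for s in range(n_subjects):
            for tract in ("SLF_II", "SLF_III"):
                base = 0.5 + rng.normal(0, 0.02, n_nodes)
                if effect_nodes and group == "patient" and tract == "SLF_II":
                    lo, hi = effect_nodes
                    base[lo - 1:hi] += 0.3
                rows.append(pd.DataFrame({
                    "subject_id": f"{group}{s}", "group": group,
                    "tract": tract, "hemisphere": "L",
                    "node": np.arange(1, n_nodes + 1),
                    "fa": base, "md": base * 1e-3, "ad": base * 1.5e-3,
                    "rd": base * 0.75e-3}))
    return pd.concat(rows, ignore_index=True)


class TestModelAndSummary:
    def test_single_subject_constant_cell_format(self):
        df = toy_profiles(n_subjects=1, seed=1)
        df[["fa"]] = 0.5
        summary = tm.summarize_table(df, {}, min_sig_nodes=10)
        cell = summary[(summary.metric == "fa")
                       & (summary.group == "patient")].iloc[0]["cell"]
        assert cell == "0.50 ± 0.00"

    def test_star_only_on_affected_tract(self):
        df = toy_profiles(effect_nodes=(30, 55), n_subjects=8, seed=2)
        model = tm.NodewiseGroupComparison(df, "patient", "control")
        res = model.fit(n_perm=400, rng_seed=0)
        summary = res.summary(min_sig_nodes=10)
        starred = summary[summary.significant]
        assert set(starred.tract) == {"SLF_II"}
        # the effect spans 26 nodes > the 10-node star threshold
        assert res[("SLF_II", "L", "fa")].n_significant > 10

    def test_no_effect_no_stars(self):
        df = toy_profiles(effect_nodes=None, n_subjects=6, seed=3)
        model = tm.NodewiseGroupComparison(df, "patient", "control")
        res = model.fit(n_perm=400, rng_seed=0)
        assert not res.summary(min_sig_nodes=10).significant.any()

    def test_unknown_group_fatal(self):
        df = toy_profiles(n_subjects=2)
        with pytest.raises(tm.DataError):
            tm.NodewiseGroupComparison(df, "patient", "martians")
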