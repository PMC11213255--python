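"""Group statistics: ANOVA, Tukey HSD, compact letter display, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from leafkin.stats import anova, binned_stats, compact_letter_display, summarize, tukey_hsd


def _groups(means, sds, ns, seed=0, factor="treatment"):
    rng = np.random.default_rng(seed)
    rows = []
    for g, (mu, sd, n) in enumerate(zip(means, sds, ns)):
        for v in rng.normal(mu, sd, n):
            rows.append({factor: f"g{g}", "value": v})
    return pd.DataFrame(rows)


class TestAnova:
    def test_two_group_f_equals_t_squared(self):
        df = _groups([0, 1], [1, 1], [10, 10], seed=1)
        table = anova(df)
        a = df.loc[df.treatment == "g0", "value"]
        b = df.loc[df.treatment == "g1", "value"]
        t, _ = scipy.stats.ttest_ind(a, b)
        assert table["F"].iloc[0] == pytest.approx(t ** 2, abs=1e-9)

    def test_null_rarely_rejects(self):
        # identically-drawn groups: p > 0.05 in >= 90% of 100 seeded replicates
        hits = sum(
            anova(_groups([0, 0], [1, 1], [10, 10], seed=s))["p"].iloc[0] > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_huge_effect_detected(self):
        df = _groups([0, 10], [1, 1], [10, 10], seed=2)
        assert anova(df)["p"].iloc[0] < 1e-6

    def test_group_with_single_observation_rejected(self):
        df = _groups([0, 1], [1, 1], [10, 1], seed=3)
        with pytest.raises(ValueError, match="g1"):
            anova(df)

    def test_single_group_rejected(self):
        df = _groups([0], [1], [10])
        with pytest.raises(ValueError, match="levels"):
            anova(df)

    def test_two_way_with_null_second_factor_matches_one_way(self):
        rng = np.random.default_rng(7)
        df = _groups([0, 0.5, 1.0], [1, 1, 1], [20, 20, 20], seed=7)
        df["genotype"] = rng.permutation(["Col0", "pif7"] * 30)
        f1 = anova(df, factors=["treatment"])["F"].iloc[0]
        two = anova(df, factors=["treatment", "genotype"])
        f2 = two.loc[two.effect == "treatment", "F"].iloc[0]
        assert f2 == pytest.approx(f1, rel=0.2)
        assert set(two["effect"]) == {"treatment", "genotype", "interaction"}


class TestTukey:
    def test_identical_groups_all_nonsignificant(self):
        df = pd.DataFrame({
            "treatment": ["a"] * 5 + ["b"] * 5 + ["c"] * 5,
            "value": list(range(5)) * 3,
        })
        _, p = tukey_hsd(df)
        off = p[~np.eye(3, dtype=bool)]
        assert (off >= 0.99).all()
        assert np.allclose(np.diag(p), 1.0)
        assert np.allclose(p, p.T)

    def test_separated_group_pattern(self):
        df = _groups([0, 0, 10], [1, 1, 1], [10, 10, 10], seed=4)
        labels, p = tukey_hsd(df)
        i = {g: k for k, g in enumerate(labels)}
        assert p[i["g0"], i["g2"]] < 0.001
        assert p[i["g1"], i["g2"]] < 0.001
        assert p[i["g0"], i["g1"]] > 0.05

    def test_two_groups_reduce_to_pooled_t_test(self):
        # studentized range with k=2: q = t*sqrt(2), so adjusted p equals
        # the unadjusted pooled two-sample t-test p
        df = _groups([0, 0.8], [1, 1.2], [12, 9], seed=5)
        _, p = tukey_hsd(df)
        a = df.loc[df.treatment == "g0", "value"]
        b = df.loc[df.treatment == "g1", "value"]
        _, p_t = scipy.stats.ttest_ind(a, b)
        assert p[0, 1] == pytest.approx(p_t, abs=1e-6)


def _brute_force_sharing_ok(p, letters, groups, alpha):
    """Oracle: letter sharing must equal the non-significance relation."""
    for i, j in itertools.combinations(range(len(groups)), 2):
        share = bool(set(letters[groups[i]]) & set(letters[groups[j]]))
        assert share == (p[i, j] >= alpha), (i, j, p[i, j], letters)


def _cliques_cover_exists(p, alpha, n_letters):
    """Brute force: is there a cover of all groups by <= n_letters cliques of
    the non-significance graph such that every n.s. pair shares a clique?"""
    k = p.shape[0]
    nodes = list(range(k))
    ns_pairs = {(i, j) for i, j in itertools.combinations(nodes, 2) if p[i, j] >= 0.05}
    cliques = []
    for r in range(1, k + 1):
        for sub in itertools.combinations(nodes, r):
            if all(p[a, b] >= 0.05 for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    for r in range(1, n_letters + 1):
        for cover in itertools.combinations(cliques, r):
            if set().union(*cover) == set(nodes) and all(
                any({a, b} <= c for c in cover) for a, b in ns_pairs
            ):
                return True
    return False


class TestCompactLetterDisplay:
    def test_all_nonsignificant_single_letter(self):
        p = np.ones((3, 3))
        letters = compact_letter_display(p, ["a", "b", "c"])
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        letters = compact_letter_display(p, ["x", "y", "z"],
                                         means={"x": 3.0, "y": 2.0, "z": 1.0})
        assert sorted(letters.values()) == ["a", "b", "c"]
        assert letters["x"] == "a"  # largest mean gets the first letter

    def test_chain_structure_four_groups(self):
        # 1~2, 2~3, 3~4 n.s.; 1-3, 1-4, 2-4 significant
        p = np.ones((4, 4))
        for i, j in [(0, 2), (0, 3), (1, 3)]:
            p[i, j] = p[j, i] = 0.01
        groups = ["g1", "g2", "g3", "g4"]
        letters = compact_letter_display(p, groups)
        _brute_force_sharing_ok(p, letters, groups, 0.05)

    def test_random_structures_against_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = 6
            p = np.ones((k, k))
            for i, j in itertools.combinations(range(k), 2):
                p[i, j] = p[j, i] = rng.choice([0.001, 0.5])
            groups = [f"g{i}" for i in range(k)]
            means = {g: float(rng.normal()) for g in groups}
            letters = compact_letter_display(p, groups, means=means)
            _brute_force_sharing_ok(p, letters, groups, 0.05)
            n_used = len(set("".join(letters.values())))
            assert _cliques_cover_exists(p, 0.05, n_used)

    def test_asymmetric_matrix_rejected(self):
        p = np.ones((3, 3))
        p[0, 1] = 0.01
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(p, ["a", "b", "c"])

    def test_deterministic(self):
        p = np.ones((4, 4))
        p[0, 3] = p[3, 0] = 0.01
        groups = ["a", "b", "c", "d"]
        l1 = compact_letter_display(p, groups)
        l2 = compact_letter_display(p, groups)
        assert l1 == l2


class TestSummarize:
    def test_single_plant_sem_missing(self):
        df = pd.DataFrame({"treatment": ["WL"], "zt_h": [2.0], "value": [4.2]})
        out = summarize(df)
        assert out["mean"].iloc[0] == 4.2
        assert np.isnan(out["sem"].iloc[0])

    def test_two_values_mean_and_sem(self):
        df = pd.DataFrame({"treatment": ["WL"] * 2, "zt_h": [2.0] * 2, "value": [1.0, 3.0]})
        out = summarize(df)
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sem"].iloc[0] == pytest.approx(1.0)

    def test_sem_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 2, 10)
        df = pd.DataFrame({"treatment": "WL", "zt_h": 2.0, "value": v})
        out = summarize(df)
        assert out["sem"].iloc[0] == pytest.approx(np.std(v, ddof=1) / np.sqrt(10), abs=1e-12)


class TestBinnedStats:
    def test_separated_groups_get_distinct_letters_each_bin(self):
        rng = np.random.default_rng(8)
        rows = []
        for g, mu in (("WL", 0.0), ("FRw", 12.0)):
            for plant in range(6):
                for b in (0.0, 2.0):
                    rows.append({"plant_id": f"{g}{plant}", "treatment": g,
                                 "bin_start_zt_h": b, "metric": "petiole_angle_deg",
                                 "mean": rng.normal(mu, 1.0), "n": 120})
        binned = pd.DataFrame(rows)
        summary, anova_table = binned_stats(binned, "petiole_angle_deg")
        for _, sub in summary.groupby("bin_start_zt_h"):
            letters = dict(zip(sub["group"], sub["letter"]))
            assert not set(letters["WL"]) & set(letters["FRw"])
        assert (anova_table["p"] < 0.001).all()

    def test_unknown_metric_rejected(self):
        binned = pd.DataFrame({"plant_id": [], "treatment": [], "bin_start_zt_h": [],
                               "metric": [], "mean": [], "n": []})
        with pytest.raises(ValueError):
            binned_stats(binned, "petiole_angle_deg")
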