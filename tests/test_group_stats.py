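"""Statistical layer vs independent oracles (scipy, sklearn, statsmodels,
brute-force enumeration and textbook re-implementations)."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cest_subtyper import group_stats as gs


# --------------------------------------------------------------------------
# sign test
# --------------------------------------------------------------------------

class TestSignTest:
    def test_eight_positive_closed_form(self):
        assert gs.sign_test([1.0] * 8) == 2 * 0.5 ** 8 == 0.0078125

    def test_five_three_binomial_enumeration(self):
        expected = 2 * sum(math.comb(8, j) for j in (5, 6, 7, 8)) / 2 ** 8
        assert gs.sign_test([1] * 5 + [-1] * 3) == pytest.approx(expected)
        assert round(expected, 4) == 0.7266

    def test_balanced_signs_capped_at_one(self):
        assert gs.sign_test([1] * 4 + [-1] * 4) == 1.0

    def test_ties_dropped(self):
        assert gs.sign_test([1, 1, 0, 0, -1]) == gs.sign_test([1, 1, -1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            gs.sign_test([0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 25), st.integers(0, 25))
    def test_matches_binomial_two_sided(self, n_pos, n_neg):
        diffs = [1.0] * n_pos + [-1.0] * n_neg
        ref = sps.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
        assert gs.sign_test(diffs) == pytest.approx(ref, abs=1e-12)


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def mw_brute_force(x, y):
    """Exact two-tailed p by enumerating all rank labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    u_lo = min(u_obs, n1 * len(y) - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        xx, yy = pooled[sel], pooled[~sel]
        u = sum((xi > yi) for xi in xx for yi in yy)
        total += 1
        count += u <= u_lo + 1e-12
    return min(1.0, 2.0 * count / total)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = gs.mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        _, p = gs.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_six_vs_six_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        y = rng.normal(0.8, size=6)
        _, p = gs.mann_whitney(x, y)
        assert p == pytest.approx(mw_brute_force(x, y), abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            gs.mann_whitney([1.0], [2.0, 3.0])

    def test_exact_matches_scipy_sweep(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            _, p = gs.mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact",
                                   alternative="two-sided").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_tie_corrected_normal_branch(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(1, 5, size=25).astype(float)
        _, p = gs.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic",
                               alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


# --------------------------------------------------------------------------
# Kruskal-Wallis + Conover-Iman
# --------------------------------------------------------------------------

def conover_oracle(groups, adjust=None):
    """Independent textbook-formula implementation of the post hoc t."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    k = len(arrays)
    ranks = sps.rankdata(pooled)
    h = sps.kruskal(*arrays).statistic        # scipy's H, tie-corrected
    sizes = [a.size for a in arrays]
    ends = np.cumsum(sizes)
    starts = ends - np.asarray(sizes)
    rbar = [ranks[s:e].mean() for s, e in zip(starts, ends)]
    s2 = (np.sum(ranks ** 2) - n * (n + 1) ** 2 / 4) / (n - 1)
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        denom = math.sqrt(s2 * ((n - 1 - h) / (n - k))
                          * (1 / sizes[i] + 1 / sizes[j]))
        t = (rbar[i] - rbar[j]) / denom
        out[(i, j)] = min(1.0, 2 * sps.t.sf(abs(t), n - k))
    return out


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = gs.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_textbook_arithmetic(self):
        h, _ = gs.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        expected = 12 / (6 * 7) * (3 ** 2 / 2 + 7 ** 2 / 2 + 11 ** 2 / 2) - 3 * 7
        assert h == pytest.approx(expected, abs=1e-12)
        assert h == pytest.approx(4.5714, abs=1e-4)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        groups = [rng.integers(0, 6, size=12).astype(float) for _ in range(4)]
        h, p = gs.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            gs.kruskal_wallis([[1.0], [2.0, 3.0]])


class TestConoverIman:
    def test_gatekeeping(self):
        groups = [[1.0, 2.0], [1.5, 2.5], [1.2, 2.2]]
        with pytest.raises(ValueError, match="significant"):
            gs.conover_iman(groups)
        table = gs.conover_iman(groups, override_gate=True)
        assert not table.attrs["gated"]

    def test_identical_groups_all_p_one(self):
        groups = [[1.0, 2.0, 3.0]] * 3
        table = gs.conover_iman(groups, override_gate=True)
        assert (table["p_adj"] == 1.0).all()

    def test_monotone_in_rank_separation(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [100.0, 101.0]]
        table = gs.conover_iman(groups, override_gate=True).set_index(["i", "j"])
        assert table.loc[(0, 1), "p_adj"] > table.loc[(0, 2), "p_adj"]

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(3, 5))
            groups = [rng.normal(rng.normal(0, 1), 1, size=rng.integers(3, 9))
                      for _ in range(k)]
            table = gs.conover_iman(groups, adjust="none", override_gate=True)
            ref = conover_oracle(groups)
            for _, row in table.iterrows():
                assert row["p_raw"] == pytest.approx(
                    ref[(int(row["i"]), int(row["j"]))], abs=1e-10)


# --------------------------------------------------------------------------
# Fisher's exact
# --------------------------------------------------------------------------

def fisher_brute_force(table):
    """Probability-mass two-tailed p via direct binomial-coefficient sums."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom
    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1)
                        if prob(x) <= p_obs * (1 + 1e-7)))


class TestFisherExact:
    def test_uniform_table(self):
        assert gs.fisher_exact([[1, 1], [1, 1]]) == 1.0

    def test_diagonal_table(self):
        assert gs.fisher_exact([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_zero_margin_convention(self):
        assert gs.fisher_exact([[0, 0], [2, 3]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gs.fisher_exact([[1, -1], [0, 2]])

    @settings(derandomize=True, max_examples=150)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        p = gs.fisher_exact(table)
        assert p == pytest.approx(fisher_brute_force(table), abs=1e-12)
        if min(a + b, c + d, a + c, b + d) > 0:
            assert p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-9)


# --------------------------------------------------------------------------
# Shapiro-Wilk screen
# --------------------------------------------------------------------------

class TestShapiroWilk:
    def test_exact_normal_quantiles_near_one(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        w, p = gs.shapiro_wilk(q)
        assert w > 0.99

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="range"):
            gs.shapiro_wilk([2.0] * 10)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            gs.shapiro_wilk([1.0, 2.0])

    def test_bimodal_sample_detected(self):
        x = np.array([-1.0] * 10 + [1.0] * 10) + np.linspace(0, 1e-3, 20)
        w, p = gs.shapiro_wilk(x)
        ref = sps.shapiro(x)
        assert p < 0.05
        assert w == pytest.approx(ref.statistic, abs=1e-4)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(4, 50))
    def test_matches_reference_implementation(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        w, p = gs.shapiro_wilk(x)
        ref = sps.shapiro(x)
        assert w == pytest.approx(ref.statistic, abs=2e-4)
        assert p == pytest.approx(ref.pvalue, abs=2e-3)


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

class TestRocAnalysis:
    def test_perfect_separation(self):
        r = gs.roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (r.auc, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)
        assert r.cut_point == pytest.approx(0.5)

    def test_pair_counting(self):
        assert gs.roc_analysis([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75

    def test_all_tied_scores(self):
        assert gs.roc_analysis([1, 1, 1, 1], [0, 1, 0, 1]).auc == 0.5

    def test_direction_flip_recorded(self):
        r = gs.roc_analysis([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert r.direction == "less"
        assert r.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            gs.roc_analysis([1, 2, 3], [1, 1, 1])

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(y, 1.2), 1)
            r = gs.roc_analysis(s, y)
            ref = roc_auc_score(y, s)
            assert r.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)


# --------------------------------------------------------------------------
# Holm adjustment
# --------------------------------------------------------------------------

class TestHolm:
    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=12))
    def test_monotone_and_dominates_raw(self, pvals):
        adj = gs.holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 0.2, size=9)
        ref = multipletests(p, method="holm")[1]
        assert np.allclose(gs.holm_adjust(p), ref, atol=1e-12)


# --------------------------------------------------------------------------
# Report layer
# --------------------------------------------------------------------------

def _toy_table(rng=None, constant=False):
    rng = rng or np.random.default_rng(0)
    rows = []
    layout = [("IDH-wildtype", "wt", "n/a", False, 5),
              ("IDHmut-ret-mismatch", "mut", "ret", True, 6),
              ("IDHmut-ret-nomismatch", "mut", "ret", False, 5),
              ("IDHmut-codel", "mut", "codel", False, 5)]
    means = {"IDH-wildtype": 1.8, "IDHmut-ret-mismatch": 1.2,
             "IDHmut-ret-nomismatch": 1.5, "IDHmut-codel": 1.3}
    for group, idh, codel, mm, n in layout:
        for i in range(n):
            base = 1.0 if constant else means[group] + rng.normal(0, 0.1)
            rows.append({
                "subject_id": f"s{len(rows)}", "group": group, "idh": idh,
                "codel": codel, "abfs_mismatch": mm, "t2flair_mismatch": mm,
                **{m: base + j * 0.01 for j, m in enumerate(
                    ["ab_amide", "fs_amide", "abfs_amide", "ab_amine",
                     "fs_amine", "abfs_amine", "ab_ratio", "fs_ratio",
                     "abfs_ratio"])},
                "nawm_abfs_amide": 0.0, "nawm_abfs_amine": 0.0,
            })
    return pd.DataFrame(rows)


class TestRunGroupComparisons:
    def test_constant_cohort_has_no_significant_rows(self):
        out = gs.run_group_comparisons(_toy_table(constant=True))
        assert not out["significant"].any()
        assert out["auc"].isna().all()

    def test_missing_group_rejected(self):
        table = _toy_table()
        table = table[table["codel"] != "codel"]
        with pytest.raises(ValueError, match="fewer than 2|group"):
            gs.run_group_comparisons(table, partitions=("three",))

    def test_partition_selection(self):
        out = gs.run_group_comparisons(_toy_table(), partitions=("two",))
        assert set(out["partition"]) == {"two"}

    def test_significant_pairs_carry_roc(self):
        out = gs.run_group_comparisons(_toy_table())
        sig = out[out["significant"]]
        assert len(sig) > 0
        assert sig["auc"].notna().all()
        assert ((sig["auc"] >= 0.5) & (sig["auc"] <= 1.0)).all()


class TestAgreement:
    def test_perfect_agreement(self):
        table = _toy_table()
        table.loc[table["codel"] == "ret", "abfs_amine"] = np.where(
            table.loc[table["codel"] == "ret", "t2flair_mismatch"], 0.5, 0.05)
        res = gs.abfs_t2flair_agreement(table)
        assert res.channels["abfs_amine"]["sensitivity"] == 1.0
        assert res.channels["abfs_amine"]["specificity"] == 1.0
        assert res.fisher_p < 0.05
        assert res.contingency.sum() == res.n

    def test_no_positive_labels_rejected(self):
        table = _toy_table()
        table["t2flair_mismatch"] = False
        with pytest.raises(ValueError, match="positive"):
            gs.abfs_t2flair_agreement(table)

    def test_permuted_labels_rarely_agree(self):
        """With metrics independent of the labels (permutation null) the
        median Fisher p stays well above the significance level, at the
        size of the default retained subgroup (n = 22, 15 positive)."""
        rng = np.random.default_rng(8)
        n, n_pos = 22, 15
        ps = []
        for _ in range(500):
            ret = pd.DataFrame({
                "idh": ["mut"] * n, "codel": ["ret"] * n,
                "abfs_amine": rng.normal(size=n),
                "abfs_amide": rng.normal(size=n),
                "t2flair_mismatch": rng.permutation(
                    [True] * n_pos + [False] * (n - n_pos)),
            })
            ps.append(gs.abfs_t2flair_agreement(ret).fisher_p)
        assert np.median(ps) > 0.3

    def test_derived_cut_point_tracks_generator_boundary(self, processed_cohort):
        """On a phantom cohort with the mismatch label tied to the fluid
        fraction, the ROC-derived amine cut point lands within 30% of the
        boundary the generator implies (the AB-FS amine value at the
        label's fluid-fraction threshold, from a linear fit)."""
        from cest_subtyper.synthetic_cohort import default_presets, GROUP_RET_MM
        table = processed_cohort["table"].merge(
            processed_cohort["cohort"].table[["subject_id", "fluid_fraction_gt"]],
            on="subject_id")
        ret = table[(table["idh"] == "mut") & (table["codel"] == "ret")]
        res = gs.abfs_t2flair_agreement(table)
        derived = res.channels["abfs_amine"]["cut_point"]
        slope, intercept = np.polyfit(ret["fluid_fraction_gt"],
                                      ret["abfs_amine"], 1)
        threshold = default_presets()[GROUP_RET_MM].t2flair_fluid_threshold
        implied = slope * threshold + intercept
        assert implied > 0
        assert abs(derived - implied) <= 0.30 * implied
        assert res.fisher_p < 0.05


class TestAbVsFsReport:
    def test_shapes_and_signs(self, processed_cohort):
        rep = gs.ab_vs_fs_report(processed_cohort["table"])
        assert "NAWM" in set(rep["group"])
        tum = rep[rep["group"] != "NAWM"]
        # fluid contamination inflates AB over FS in tumours...
        assert (tum["abfs_amine_median"] > 0).all()
        # ...and makes the amide/amine ratio lower under AB than FS
        assert (tum["abfs_ratio_median"] < 0).all()
        nawm = rep[rep["group"] == "NAWM"].iloc[0]
        assert abs(nawm["abfs_amine_median"]) < 0.01
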