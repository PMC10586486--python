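"""ANOVA, Holm-Sidak, post hoc contrasts, t-maps, clusters, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from petvt import (ValidationError, extract_clusters, holm_sidak_adjust,
                   pearson_correlation, posthoc_group_by_region, two_way_anova,
                   voxelwise_two_sample_map)


def make_table(group_sizes, regions, effect=None, noise=0.0, seed=0, base=4.0):
    """Cohort V_T table; ``effect`` maps (group, region) -> added mean."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in group_sizes.items():
        for i in range(n):
            animal = f"{group}_{i}"
            for region in regions:
                mu = base + (effect or {}).get((group, region), 0.0)
                rows.append({"animal": animal, "group": group, "region": region,
                             "vt": mu + noise * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_constant_data_gives_zero_f(self):
        table = make_table({"buffer": 3, "85Q": 3}, ["a", "b"])
        res = two_way_anova(table)
        assert np.allclose(res.effects["F"], 0.0, atol=1e-20)

    def test_balanced_2x2_matches_bruteforce_sums_of_squares(self):
        """Textbook balanced two-way ANOVA computed from cell means."""
        table = make_table({"buffer": 4, "85Q": 4}, ["a", "b"],
                           effect={("85Q", "a"): 1.0, ("85Q", "b"): 2.0,
                                   ("buffer", "b"): 0.5},
                           noise=0.3, seed=1)
        res = two_way_anova(res_table := table)
        y = res_table["vt"].to_numpy()
        g = res_table["group"].to_numpy()
        r = res_table["region"].to_numpy()
        grand = y.mean()
        n_per_cell = 4
        groups, regions = np.unique(g), np.unique(r)
        cell = {(gg, rr): y[(g == gg) & (r == rr)].mean()
                for gg in groups for rr in regions}
        gm = {gg: y[g == gg].mean() for gg in groups}
        rm = {rr: y[r == rr].mean() for rr in regions}
        n_g = {gg: (g == gg).sum() for gg in groups}
        n_r = {rr: (r == rr).sum() for rr in regions}
        ss_a = sum(n_g[gg] * (gm[gg] - grand) ** 2 for gg in groups)
        ss_b = sum(n_r[rr] * (rm[rr] - grand) ** 2 for rr in regions)
        ss_ab = sum(n_per_cell * (cell[(gg, rr)] - gm[gg] - rm[rr] + grand) ** 2
                    for gg in groups for rr in regions)
        ss_e = sum((y[(g == gg) & (r == rr)] - cell[(gg, rr)]) ** 2
                   for gg in groups for rr in regions).sum()
        df_e = y.size - len(groups) * len(regions)
        eff = res.effects.set_index("effect")
        assert eff.loc["group", "F"] == pytest.approx(
            (ss_a / 1) / (ss_e / df_e), rel=1e-8)
        assert eff.loc["region", "F"] == pytest.approx(
            (ss_b / 1) / (ss_e / df_e), rel=1e-8)
        assert eff.loc["group x region", "F"] == pytest.approx(
            (ss_ab / 1) / (ss_e / df_e), rel=1e-8)

    def test_unbalanced_design_degrees_of_freedom(self):
        """3 groups (5/4/5) x 68 regions: df (2,748), (67,748), (134,748)."""
        regions = [f"r{i:02d}" for i in range(68)]
        table = make_table({"buffer": 5, "10Q": 4, "85Q": 5}, regions,
                           noise=0.1, seed=2)
        res = two_way_anova(table)
        eff = res.effects.set_index("effect")
        assert eff.loc["group", "df"] == 2
        assert eff.loc["region", "df"] == 67
        assert eff.loc["group x region", "df"] == 134
        assert res.df_error == 748

    def test_empty_cell_rejected(self):
        table = make_table({"buffer": 3, "85Q": 3}, ["a", "b"])
        table = table[~((table["group"] == "85Q") & (table["region"] == "b"))]
        with pytest.raises(ValidationError, match="empty cell"):
            two_way_anova(table)


class TestHolmSidak:
    def test_single_test_unchanged(self):
        assert holm_sidak_adjust([0.03])[0] == pytest.approx(0.03)

    def test_enumerated_example(self):
        adj = holm_sidak_adjust([0.01, 0.04, 0.03])
        assert adj[0] == pytest.approx(1 - 0.99 ** 3)        # 0.029701
        assert adj[2] == pytest.approx(1 - 0.97 ** 2)        # 0.0591
        assert adj[1] == pytest.approx(adj[2])               # monotonized

    def test_zero_p_stays_zero(self):
        assert holm_sidak_adjust([0.0, 0.5, 0.9])[0] == 0.0

    def test_matches_direct_formula_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            adj = holm_sidak_adjust(p)
            order = np.argsort(p, kind="stable")
            running = 0.0
            for rank, idx in enumerate(order):
                raw = 1 - (1 - p[idx]) ** (p.size - rank)
                running = min(max(running, raw), 1.0)
                assert adj[idx] == pytest.approx(running, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(22)
        p = rng.uniform(0, 1, 9)
        adj = holm_sidak_adjust(p)
        ref = multipletests(p, method="holm-sidak")[1]
        assert np.allclose(adj, ref, atol=1e-12)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0, 1, 10)
        adj = holm_sidak_adjust(p)
        single_step = 1 - (1 - p) ** p.size
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= single_step + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValidationError):
            holm_sidak_adjust([0.1, 0.2], m=1)


class TestPosthoc:
    def test_identical_groups_give_zero_t(self):
        table = make_table({"buffer": 4, "10Q": 4, "85Q": 4}, ["a", "b"],
                           noise=0.0)
        # zero MSE: guard by adding region effect only (groups identical)
        table.loc[table["region"] == "b", "vt"] += 1.0
        rng = np.random.default_rng(3)
        per_animal = {a: rng.normal(0, 0.1) for a in table["animal"].unique()}
        # same animal-level offsets copied across groups keep contrasts at 0
        offsets = [per_animal[f"buffer_{i}"] for i in range(4)]
        for g in ("buffer", "10Q", "85Q"):
            for i in range(4):
                table.loc[table["animal"] == f"{g}_{i}", "vt"] += offsets[i]
        ph = posthoc_group_by_region(table)
        assert np.allclose(ph["t"], 0.0, atol=1e-10)

    def test_large_effect_detected(self):
        effect = {("85Q", "a"): 2.0}
        table = make_table({"buffer": 5, "10Q": 4, "85Q": 5}, ["a", "b"],
                           effect=effect, noise=0.2, seed=5)
        ph = posthoc_group_by_region(table)
        hit = ph[(ph["region"] == "a") & (ph["contrast"] == "85Q vs buffer")]
        assert bool(hit["significant"].iloc[0])

    def test_null_type_i_control(self):
        """FWER of the per-region post hoc family under the global null."""
        n_reps, alpha = 300, 0.05
        regions = ["a", "b", "c"]
        n_families = 0
        n_fp_families = 0
        for rep in range(n_reps):
            table = make_table({"buffer": 5, "10Q": 4, "85Q": 5}, regions,
                               noise=0.5, seed=1000 + rep)
            ph = posthoc_group_by_region(table, alpha=alpha)
            for _, sub in ph.groupby("region"):
                n_families += 1
                n_fp_families += int(sub["significant"].any())
        assert n_fp_families / n_families <= 0.06


class TestTwoSampleMap:
    def test_identical_groups_give_zero_t(self):
        a = [np.full((3, 3, 3), 2.0) for _ in range(3)]
        t, df = voxelwise_two_sample_map(a, [x.copy() for x in a])
        assert df == 4
        assert np.allclose(t, 0.0)

    def test_zero_variance_nonzero_diff_is_infinite(self):
        a = [np.full((2, 2, 2), 3.0)] * 2
        b = [np.full((2, 2, 2), 1.0)] * 2
        t, _ = voxelwise_two_sample_map(a, b)
        assert np.all(np.isinf(t)) and np.all(t > 0)

    def test_matches_scipy_loop_oracle(self):
        rng = np.random.default_rng(8)
        a = [rng.normal(5, 1, (3, 2, 2)) for _ in range(4)]
        b = [rng.normal(4, 1, (3, 2, 2)) for _ in range(5)]
        t, df = voxelwise_two_sample_map(a, b)
        for idx in np.ndindex(3, 2, 2):
            ref = scipy.stats.ttest_ind([x[idx] for x in a],
                                        [x[idx] for x in b], equal_var=True)
            assert t[idx] == pytest.approx(ref.statistic, rel=1e-10)
        assert df == 7


class TestClusters:
    def test_no_suprathreshold_voxels(self):
        res = extract_clusters(np.zeros((5, 5, 5)), df=10)
        assert len(res.table) == 0

    def test_single_block(self):
        tmap = np.zeros((9, 9, 9))
        tmap[3:6, 3:6, 3:6] = 10.0
        res = extract_clusters(tmap, df=10, k_min=10)
        assert len(res.table) == 1
        assert res.table["size"].iloc[0] == 27

    def test_strict_threshold_excludes_exact_k(self):
        tmap = np.zeros((9, 9, 9))
        tmap[0, 0:2, 0:5] = 10.0  # exactly 10 voxels
        assert len(extract_clusters(tmap, df=10, k_min=10, strict=True).table) == 0
        assert len(extract_clusters(tmap, df=10, k_min=10, strict=False).table) == 1

    def test_corner_touching_blocks_connectivity(self):
        """Corner contact joins under 26- but not 18-connectivity."""
        tmap = np.zeros((8, 8, 6))
        tmap[0:3, 0:3, 0:2] = 9.0
        tmap[3:6, 3:6, 2:4] = 9.0
        res18 = extract_clusters(tmap, df=12, k_min=10, connectivity=18)
        res26 = extract_clusters(tmap, df=12, k_min=10, connectivity=26)
        assert len(res18.table) == 2
        assert len(res26.table) == 1

    def test_matches_bruteforce_flood_fill(self):
        rng = np.random.default_rng(14)
        tmap = rng.normal(0, 2.0, (8, 8, 8))
        res = extract_clusters(tmap, df=12, p_thresh=0.05, k_min=2,
                               connectivity=18)
        crit = scipy.stats.t.isf(0.05, 12)
        supra = tmap > crit

        def neighbors(v):
            out = []
            for d in np.ndindex(3, 3, 3):
                off = np.array(d) - 1
                if np.abs(off).sum() == 0 or np.all(np.abs(off) == 1):
                    continue  # skip self and pure corners (18-connectivity)
                w = v + off
                if np.all(w >= 0) and np.all(w < 8):
                    out.append(tuple(w))
            return out

        seen = set()
        sizes = []
        for v in map(tuple, np.argwhere(supra)):
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                u = stack.pop()
                if u in comp or not supra[u]:
                    continue
                comp.add(u)
                stack.extend(neighbors(np.array(u)))
            seen |= comp
            if len(comp) > 2:
                sizes.append(len(comp))
        assert sorted(sizes) == sorted(res.table["size"].tolist())

    def test_threshold_monotone(self):
        """Loosening the peak threshold never shrinks surviving clusters."""
        rng = np.random.default_rng(15)
        tmap = scipy.ndimage.gaussian_filter(rng.normal(0, 3.0, (10, 10, 10)), 1.0) \
            if hasattr(scipy, "ndimage") else rng.normal(0, 3.0, (10, 10, 10))
        strict = extract_clusters(tmap, df=12, p_thresh=0.005, k_min=2)
        loose = extract_clusters(tmap, df=12, p_thresh=0.05, k_min=2)
        loose_mask = loose.labels > 0
        for cid, coords in strict.voxels.items():
            assert loose_mask[tuple(coords.T)].all()


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_hand_computed_half(self):
        r, _ = pearson_correlation([1, 2, 3], [2, 1, 3])
        assert r == pytest.approx(0.5)

    def test_anti_monotone(self):
        r, _ = pearson_correlation([1, 2, 3], [5, 4, 3])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_p_value_from_t_distribution(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0, 1, 12)
        r, p = pearson_correlation(x, y)
        t = r * np.sqrt((12 - 2) / (1 - r * r))
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t), 10), rel=1e-9)
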