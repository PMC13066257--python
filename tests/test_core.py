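import itertools

import numpy as np
import pytest
from scipy import stats

from vlsm import (
    LesionVolume,
    OverlapMap,
    PermutationNull,
    StatMap,
    SymptomDesign,
    TemplateGrid,
    apply_threshold,
    build_design,
    eligible_mask,
    extract_clusters,
    involvement_vs_frequency,
    label_involvement,
    overlap_map,
    permutation_null,
    power_map,
    voxelwise_glm,
)
from vlsm.core import T_CAP

from conftest import make_record, random_masks


def ols_oracle(X, y, j):
    """Independent normal-equations fit: beta_j, t_j with classical SE."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[j, j])
    return beta[j], beta[j] / se


def random_cohort(n, rng):
    return [
        make_record(
            subject_id=f"s{i}",
            score=int(rng.integers(0, 5)),
            age=float(rng.uniform(16, 68)),
            sex=int(rng.random() < 0.6),
            volume=float(rng.uniform(5, 200)),
        )
        for i in range(n)
    ]


class TestBuildDesign:
    def test_score_column_from_categories(self):
        recs = [make_record(subject_id=f"s{i}", score=s, age=30 + i, volume=10 + i * i,
                            sex=i % 2)
                for i, s in enumerate([0, 1, 2, 4, 3, 0])]
        d = build_design(recs)
        # none/rare/monthly/daily/weekly map to 0/1/2/4/3
        np.testing.assert_array_equal(d.X[:, d.score_index], [0, 1, 2, 4, 3, 0])
        assert d.columns == ["frequency_score", "sex", "age", "tumor_volume", "intercept"]
        # nuisance columns are centered, intercept is ones
        assert d.X[:, 1:4].mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)
        np.testing.assert_array_equal(d.X[:, -1], 1.0)

    def test_constant_sex_dropped_with_warning(self):
        recs = [make_record(subject_id=f"s{i}", score=i % 3, sex=0, age=30 + i,
                            volume=10 + i * i) for i in range(8)]
        with pytest.warns(UserWarning, match="sex"):
            d = build_design(recs)
        assert "sex" not in d.columns

    def test_missing_covariate_names_subject(self):
        recs = [make_record(subject_id=f"s{i}", score=i % 3, age=30 + i,
                            volume=10 + i * i) for i in range(5)]
        recs[2].age = float("nan")
        with pytest.raises(ValueError, match="s2"):
            build_design(recs)

    def test_centering_leaves_frequency_t_unchanged(self, rng):
        """FWL check against the uncentered design via the oracle solver."""
        recs = random_cohort(25, rng)
        d = build_design(recs)
        y = rng.random(25) < 0.5
        y = y.astype(float)
        # uncentered design, same column order
        X_raw = np.column_stack([
            [r.frequency_score for r in recs],
            [r.sex for r in recs],
            [r.age for r in recs],
            [r.tumor_volume for r in recs],
            np.ones(25),
        ])
        _, t_raw = ols_oracle(X_raw, y, 0)
        _, t_centered = ols_oracle(d.X, y, 0)
        assert t_centered == pytest.approx(t_raw, rel=1e-10)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            SymptomDesign(np.ones((5, 2)), ["a", "b"], [f"s{i}" for i in range(5)])


class TestVoxelwiseGLM:
    def test_symmetric_cancellation_gives_zero_t(self):
        grid = TemplateGrid((1, 1, 1))
        lesion = [1, 0, 0, 1]
        recs = [make_record(subject_id=f"s{i}", score=s, age=40, sex=1, volume=50)
                for i, s in enumerate([0, 1, 2, 3])]
        with pytest.warns(UserWarning):  # constant nuisance columns dropped
            d = build_design(recs)
        masks = [LesionVolume(f"s{i}", np.full(grid.dims, v, np.uint8), grid)
                 for i, v in enumerate(lesion)]
        sm = voxelwise_glm(masks, d)
        assert sm.t[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_exact_fit_capped_and_flagged(self):
        grid = TemplateGrid((1, 1, 1))
        scores = [0, 0, 2, 2]
        lesion = [0, 0, 1, 1]  # deterministic function of the score
        recs = [make_record(subject_id=f"s{i}", score=s, age=40, sex=1, volume=50)
                for i, s in enumerate(scores)]
        with pytest.warns(UserWarning):
            d = build_design(recs)
        masks = [LesionVolume(f"s{i}", np.full(grid.dims, v, np.uint8), grid)
                 for i, v in enumerate(lesion)]
        sm = voxelwise_glm(masks, d)
        assert sm.t[0, 0, 0] == T_CAP
        assert sm.deterministic[0, 0, 0]

    def test_matches_normal_equations_oracle(self, rng):
        grid = TemplateGrid((5, 5, 4))
        n = 30
        recs = random_cohort(n, rng)
        d = build_design(recs)
        masks = random_masks(grid, n, rng)
        sm = voxelwise_glm(masks, d)
        L = np.stack([m.data for m in masks]).reshape(n, -1).astype(float)
        checked = 0
        for v in np.flatnonzero(sm.eligible.ravel()):
            beta_o, t_o = ols_oracle(d.X, L[:, v], d.score_index)
            assert sm.beta.ravel()[v] == pytest.approx(beta_o, rel=1e-8, abs=1e-12)
            assert sm.t.ravel()[v] == pytest.approx(t_o, rel=1e-8, abs=1e-10)
            checked += 1
        assert checked > 50

    def test_constant_voxels_marked_ineligible(self, rng):
        grid = TemplateGrid((2, 2, 1))
        n = 10
        recs = random_cohort(n, rng)
        d = build_design(recs)
        data = [np.zeros(grid.dims, np.uint8) for _ in range(n)]
        for arr in data:
            arr[0, 0, 0] = 1  # constant-1 voxel
        data[0][1, 0, 0] = 1  # varying voxel
        masks = [LesionVolume(f"s{i}", a, grid) for i, a in enumerate(data)]
        sm = voxelwise_glm(masks, d)
        assert not sm.eligible[0, 0, 0]
        assert sm.eligible[1, 0, 0]
        assert np.isnan(sm.t[0, 0, 0])

    def test_nuisance_shift_and_rescale_invariance(self, rng):
        recs = random_cohort(25, rng)
        grid = TemplateGrid((4, 4, 3))
        masks = random_masks(grid, 25, rng)
        d1 = build_design(recs)
        for r in recs:
            r.age = r.age * 12.0 + 7.0  # months plus offset
            r.tumor_volume = r.tumor_volume * 1000.0  # mm^3
        d2 = build_design(recs)
        t1 = voxelwise_glm(masks, d1).t
        t2 = voxelwise_glm(masks, d2).t
        np.testing.assert_allclose(t1, t2, rtol=1e-8, equal_nan=True)


class TestPowerMap:
    def _overlap(self, counts, n, grid):
        return OverlapMap(np.asarray(counts).reshape(grid.dims), n, grid)

    def test_no_contrast_voxels_have_zero_power(self):
        grid = TemplateGrid((3, 1, 1))
        ov = self._overlap([0, 5, 10], 10, grid)
        pm = power_map(ov, effect_size=1.0, alpha=0.05)
        assert pm.power[0, 0, 0] == 0.0
        assert pm.power[2, 0, 0] == 0.0  # lesioned in all subjects
        # balanced 5/10 split at d=1: Phi(sqrt(2.5) - 1.96) ~ 0.35
        assert pm.power[1, 0, 0] == pytest.approx(0.352, abs=0.01)

    def test_balanced_split_formula(self):
        grid = TemplateGrid((1, 1, 1))
        ov = self._overlap([50], 100, grid)
        pm = power_map(ov, effect_size=1.0, alpha=0.05)
        expected = stats.norm.cdf(np.sqrt(50 * 50 / 100) - stats.norm.ppf(0.975))
        assert pm.power[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        # cross-check against the noncentral-t power at this large n
        df = 98
        nc = 1.0 * np.sqrt(50 * 50 / 100)
        tcrit = stats.t.ppf(0.975, df)
        power_nct = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        assert pm.power[0, 0, 0] == pytest.approx(power_nct, abs=5e-3)

    def test_power_maximal_at_balanced_split(self):
        grid = TemplateGrid((11, 1, 1))
        ov = self._overlap(np.arange(0, 101, 10), 100, grid)
        pm = power_map(ov)
        assert np.nanargmax(pm.power) == 5  # k = 50 of 100

    def test_eligibility_strictness_and_monotonicity(self):
        grid = TemplateGrid((3, 1, 1))
        pm = power_map(self._overlap([3, 10, 50], 100, grid))
        pm.power = np.array([0.79, 0.80, 0.81]).reshape(grid.dims)
        elig = eligible_mask(pm, 0.8)
        np.testing.assert_array_equal(elig.ravel(), [False, False, True])
        # raising the threshold never adds voxels
        low = eligible_mask(pm, 0.5)
        assert not (elig & ~low).any()


def _tiny_setup(rng, n=12, dims=(3, 2, 2), scores=None):
    grid = TemplateGrid(dims)
    recs = [make_record(subject_id=f"s{i}",
                        score=int(rng.integers(0, 5)) if scores is None else scores[i],
                        age=float(rng.uniform(20, 60)),
                        sex=int(rng.random() < 0.5),
                        volume=float(rng.uniform(10, 100)))
            for i in range(n)]
    design = build_design(recs)
    masks = random_masks(grid, n, rng)
    elig = np.ones(grid.dims, bool)
    return grid, design, masks, elig


class TestPermutationNull:
    def test_seed_determinism_bit_identical(self, rng):
        grid, design, masks, elig = _tiny_setup(rng)
        a = permutation_null(masks, design, elig, n_permutations=50, seed=9)
        b = permutation_null(masks, design, elig, n_permutations=50, seed=9)
        np.testing.assert_array_equal(a.threshold, b.threshold)

    def test_explicit_seed_required(self, rng):
        grid, design, masks, elig = _tiny_setup(rng)
        with pytest.raises(ValueError, match="seed"):
            permutation_null(masks, design, elig, n_permutations=20)

    def test_too_few_permutations_warns(self, rng):
        grid, design, masks, elig = _tiny_setup(rng)
        with pytest.warns(UserWarning, match="cannot resolve"):
            permutation_null(masks, design, elig, n_permutations=5, alpha=0.05, seed=1)

    def test_converges_to_exhaustive_enumeration(self, rng):
        """Sampled thresholds approach the full-enumeration order statistic."""
        n = 6
        grid = TemplateGrid((3, 2, 2))
        scores = [0, 1, 2, 2, 3, 4]
        recs = [make_record(subject_id=f"s{i}", score=s, age=40, sex=1, volume=50)
                for i, s in enumerate(scores)]
        with pytest.warns(UserWarning):  # constant nuisance dropped
            design = build_design(recs)
        masks = random_masks(grid, n, rng)
        elig = np.ones(grid.dims, bool)

        # oracle: explicit normal-equations t over all 6! score permutations
        L = np.stack([m.data for m in masks]).reshape(n, -1).astype(float)
        nonconst = L.min(axis=0) != L.max(axis=0)
        alpha = 0.05
        all_t = []
        for perm in itertools.permutations(range(n)):
            X = design.X.copy()
            X[:, design.score_index] = np.asarray(scores, float)[list(perm)]
            ts = []
            for v in np.flatnonzero(nonconst):
                _, t = ols_oracle(X, L[:, v], design.score_index)
                ts.append(t)
            all_t.append(ts)
        all_t = np.array(all_t)  # (720, V)
        k = int(np.ceil((1 - alpha) * all_t.shape[0]))
        exact_thr = np.sort(all_t, axis=0)[k - 1]

        def supdiff(m):
            null = permutation_null(masks, design, elig, n_permutations=m,
                                    alpha=alpha, seed=77)
            sampled = null.threshold.ravel()[nonconst]
            return float(np.max(np.abs(sampled - exact_thr)))

        d_small, d_large = supdiff(100), supdiff(20000)
        # tolerance: local spacing of the exhaustive order statistics
        spread = np.sort(all_t, axis=0)
        gap = float(np.max(spread[min(k + 6, 719)] - spread[k - 7]))
        assert d_large <= max(gap, 1e-9)
        assert d_large <= d_small + 1e-9

    def test_max_stat_threshold_is_constant_and_higher(self, rng):
        grid, design, masks, elig = _tiny_setup(rng, n=16)
        vox = permutation_null(masks, design, elig, n_permutations=100, seed=3)
        fwe = permutation_null(masks, design, elig, n_permutations=100, seed=3,
                               mode="max_stat")
        tv = vox.threshold[vox.eligible]
        tf = fwe.threshold[fwe.eligible]
        assert np.unique(tf).size == 1
        assert tf[0] >= tv.max() - 1e-12

    def test_freedman_lane_scheme_runs_deterministically(self, rng):
        grid, design, masks, elig = _tiny_setup(rng, n=16)
        a = permutation_null(masks, design, elig, n_permutations=40, seed=5,
                             scheme="freedman_lane")
        b = permutation_null(masks, design, elig, n_permutations=40, seed=5,
                             scheme="freedman_lane")
        np.testing.assert_array_equal(a.threshold, b.threshold)
        assert np.isfinite(a.threshold[a.eligible]).all()


class TestApplyThreshold:
    def _pair(self, t_obs, thr, grid):
        elig = np.ones(grid.dims, bool)
        stat = StatMap(beta=np.zeros(grid.dims), t=np.asarray(t_obs).reshape(grid.dims),
                       eligible=elig, n_subjects=10, df_residual=5, grid=grid)
        null = PermutationNull(threshold=np.asarray(thr).reshape(grid.dims),
                               eligible=elig, n_permutations=100, alpha=0.05,
                               seed=0, scheme="score", mode="voxelwise", grid=grid)
        return stat, null

    def test_strictly_greater_required(self):
        grid = TemplateGrid((3, 1, 1))
        stat, null = self._pair([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], grid)
        np.testing.assert_array_equal(
            apply_threshold(stat, null).ravel(), [False, False, True]
        )

    def test_below_threshold_everywhere_empty(self):
        grid = TemplateGrid((2, 2, 1))
        stat, null = self._pair(np.zeros(4), np.ones(4), grid)
        assert not apply_threshold(stat, null).any()


def flood_fill_oracle(mask, connectivity):
    """Brute-force component labelling by BFS over the chosen neighbourhood."""
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(v) for v in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offsets.append(d)
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for start in np.argwhere(mask):
        if labels[tuple(start)]:
            continue
        nxt += 1
        stack = [tuple(start)]
        labels[tuple(start)] = nxt
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)):
                    if mask[nb] and not labels[nb]:
                        labels[nb] = nxt
                        stack.append(nb)
    return labels


class TestClusters:
    def test_single_voxel(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 2, 3] = True
        t = np.where(mask, 2.5, np.nan)
        res = extract_clusters(mask, t)
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert (c.size, c.peak, c.peak_t) == (1, (1, 2, 3), 2.5)

    def test_connectivity_semantics(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True  # face-adjacent pair
        t = np.ones((4, 4, 4))
        assert len(extract_clusters(mask, t, 6).clusters) == 1
        mask2 = np.zeros((4, 4, 4), bool)
        mask2[0, 0, 0] = mask2[1, 1, 1] = True  # corner-diagonal pair
        assert len(extract_clusters(mask2, t, 6).clusters) == 2
        assert len(extract_clusters(mask2, t, 26).clusters) == 1

    def test_empty_mask_is_empty_result(self):
        res = extract_clusters(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3)))
        assert res.clusters == []
        assert res.to_table().empty

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labels_match_flood_fill_oracle(self, rng, connectivity):
        mask = rng.random((10, 10, 10)) < 0.25
        t = rng.random((10, 10, 10))
        res = extract_clusters(mask, t, connectivity)
        oracle = flood_fill_oracle(mask, connectivity)
        # same partition: label images agree up to renaming
        assert res.labels.astype(bool).sum() == oracle.astype(bool).sum()
        for lab in range(1, res.labels.max() + 1):
            where = res.labels == lab
            oracle_labs = np.unique(oracle[where])
            assert oracle_labs.size == 1
            assert (oracle == oracle_labs[0]).sum() == where.sum()

    def test_sorted_by_peak_t_descending(self, rng):
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        t = np.zeros((8, 8, 8))
        t[0, 0, 0], t[4, 4, 4] = 1.0, 5.0
        res = extract_clusters(mask, t)
        assert res.clusters[0].peak == (4, 4, 4)
        assert res.clusters[0].label == 1


class TestInvolvement:
    def test_peak_membership(self, small_grid, rng):
        masks = random_masks(small_grid, 15, rng)
        peak = (2, 3, 1)
        inv = label_involvement(masks, peak)
        ov = overlap_map(masks)
        assert inv.sum() == ov.counts[peak]
        for m, flag in zip(masks, inv):
            assert flag == bool(m.data[peak])

    def test_peak_outside_grid_rejected(self, small_grid, rng):
        masks = random_masks(small_grid, 3, rng)
        with pytest.raises(ValueError):
            label_involvement(masks, (99, 0, 0))

    def test_complete_separation(self):
        inv = np.array([True] * 5 + [False] * 5)
        scores = np.array([4] * 5 + [0] * 5)
        res = involvement_vs_frequency(inv, scores)
        assert res.p_value < 0.01

    def test_equal_distributions_p_near_one(self):
        inv = np.array([True] * 4 + [False] * 4)
        scores = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        res = involvement_vs_frequency(inv, scores)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            involvement_vs_frequency(np.ones(4, bool), np.arange(4))
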