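"""Permutation inference: AUC summaries, p-value properties, hubs."""
import numpy as np
import pandas as pd
import pytest

from covnet import (
    ComparisonSettings,
    DensityRange,
    SyntheticSpec,
    bridge_correlation,
    compare_hubs,
    compare_nodal,
    generate_cohort,
    metric_curves,
    permute_groups,
)

FAST = ComparisonSettings(
    global_metrics=("clustering_coefficient", "characteristic_path_length", "modularity")
)
GRID = DensityRange(0.15, 0.40, 0.05)


def swap_labels(table):
    """Reorder rows so the second group appears first and becomes group 1."""
    first = table["group"].iloc[0]
    other = next(g for g in table["group"] if g != first)
    return pd.concat(
        [table[table["group"] == other], table[table["group"] == first]],
        ignore_index=True,
    )


class TestAUC:
    def test_constant_curve(self, small_cohort):
        curves = metric_curves(small_cohort, GRID, FAST)
        c = curves["clustering_coefficient"]
        const = np.full_like(c.values["patient"], 0.7)
        auc = np.trapezoid(const, c.grid)
        assert auc == pytest.approx(0.7 * (0.40 - 0.15))

    def test_linear_curve_exact(self):
        grid = DensityRange(0.15, 0.40, 0.01).grid
        vals = 2.0 + 3.0 * grid
        auc = np.trapezoid(vals, grid)
        exact = 2.0 * 0.25 + 1.5 * (0.40**2 - 0.15**2)
        assert auc == pytest.approx(exact, abs=1e-12)

    def test_auc_matches_fine_grid_oracle(self, small_cohort):
        """Trapezoid on the analysis grid is within the trapezoid error
        bound of a 10x-finer numerical integration of the same curve."""
        coarse = metric_curves(small_cohort, DensityRange(0.15, 0.40, 0.05), FAST)
        fine = metric_curves(small_cohort, DensityRange(0.15, 0.40, 0.005), FAST)
        for m in FAST.global_metrics:
            a_c = coarse[m].auc["patient"]
            a_f = fine[m].auc["patient"]
            spread = np.ptp(fine[m].values["patient"])
            assert abs(a_c - a_f) <= 0.05 * spread + 1e-9


class TestPermutation:
    def test_observed_difference_reproduces_curves(self, small_cohort):
        curves = metric_curves(small_cohort, GRID, FAST)
        res = permute_groups(small_cohort, GRID, FAST, n_perm=5, seed=0)
        for m in FAST.global_metrics:
            expected = curves[m].values["patient"] - curves[m].values["control"]
            np.testing.assert_allclose(res[m].observed, expected, atol=1e-12)
            assert res[m].observed_auc == pytest.approx(
                curves[m].auc["patient"] - curves[m].auc["control"]
            )

    def test_identical_groups_give_p_one(self, small_cohort):
        """Duplicating one group as both groups: observed difference is 0,
        so every permuted |difference| >= |observed| and p = 1."""
        g1 = small_cohort[small_cohort["group"] == "patient"].copy()
        g2 = g1.copy()
        g2["group"] = "control"
        g2["subject_id"] = g2["subject_id"] + "b"
        table = pd.concat([g1, g2], ignore_index=True)
        res = permute_groups(table, GRID, FAST, n_perm=20, seed=1)
        for m in FAST.global_metrics:
            assert res[m].observed_auc == pytest.approx(0.0, abs=1e-12)
            assert res[m].p_auc >= 0.9

    def test_seeded_determinism(self, small_cohort):
        r1 = permute_groups(small_cohort, GRID, FAST, n_perm=20, seed=5)
        r2 = permute_groups(small_cohort, GRID, FAST, n_perm=20, seed=5)
        for m in FAST.global_metrics:
            assert r1[m].p_auc == r2[m].p_auc
            np.testing.assert_array_equal(r1[m].null, r2[m].null)

    def test_p_invariant_under_label_swap(self, small_cohort):
        """Two-sidedness: which group is subtracted from which must not
        matter.  Reversing the group order negates the observed difference
        exactly and leaves the p-value statistically unchanged."""
        r1 = permute_groups(small_cohort, GRID, FAST, n_perm=60, seed=2)
        r2 = permute_groups(swap_labels(small_cohort), GRID, FAST, n_perm=60, seed=2)
        for m in FAST.global_metrics:
            assert r1[m].observed_auc == pytest.approx(
                -r2[m].observed_auc, abs=1e-10
            )
            assert abs(r1[m].p_auc - r2[m].p_auc) < 0.2

    def test_null_roughly_symmetric(self, small_cohort):
        res = permute_groups(small_cohort, GRID, FAST, n_perm=100, seed=3)
        null = res["clustering_coefficient"].null_auc
        null = null[np.isfinite(null)]
        assert abs(np.mean(null)) < 3 * np.std(null) / np.sqrt(len(null)) + 0.01

    def test_p_values_in_unit_interval(self, small_cohort):
        res = permute_groups(small_cohort, GRID, FAST, n_perm=20, seed=4)
        for m, r in res.items():
            assert 0 < r.p_auc <= 1
            assert np.all((r.p_per_density > 0) & (r.p_per_density <= 1))

    def test_zero_permutations_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="n_perm"):
            permute_groups(small_cohort, GRID, FAST, n_perm=0, seed=0)


class TestNodal:
    def test_planted_region_ranks_high_in_degree_difference(self):
        """A single region whose within-block correlation is inflated in
        group 1 only ranks in the top decile of observed nodal-degree AUC
        differences.  (Inflating a whole block instead would reshape the
        subject global mean and be washed out by its removal.)"""
        n, k = 40, 4
        part = np.arange(n) % k
        loadings = np.zeros((n, 1 + k))
        loadings[:, 0] = np.sqrt(0.1)
        for b in range(k):
            loadings[part == b, 1 + b] = np.sqrt(0.2)
        c2 = loadings @ loadings.T
        np.fill_diagonal(c2, 1.0)
        boosted = loadings.copy()
        boosted[0, 1] = np.sqrt(0.9)  # region 0 couples tightly to its block
        c1 = boosted @ boosted.T
        np.fill_diagonal(c1, 1.0)
        spec = SyntheticSpec(
            n_regions=n,
            group_sizes=(100, 100),
            correlation_override=(c1, c2),
            seed=900,
        )
        cohort = generate_cohort(spec)
        settings = ComparisonSettings(global_metrics=(), nodal_metrics=("degree",))
        # low densities, where the planted region's extra edges stand out
        grid = DensityRange(0.05, 0.15, 0.05)
        _, summary = compare_nodal(cohort, grid, settings, n_perm=1, seed=0)
        ranked = summary.sort_values("auc_difference", ascending=False)
        assert spec.region_names[0] in set(ranked["region"].head(4))

    def test_zero_permutations_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="n_perm"):
            compare_nodal(small_cohort, GRID, n_perm=0, seed=0)

    def test_bh_adjustment_monotone(self, small_cohort):
        settings = ComparisonSettings(global_metrics=(), nodal_metrics=("degree",))
        _, summary = compare_nodal(
            small_cohort, GRID, settings, n_perm=20, seed=1, adjust=True
        )
        assert (summary["p_bh"] >= summary["p_uncorrected"] - 1e-12).all()


class TestHubComparison:
    def test_identical_groups_identical_hubs(self, small_cohort):
        g1 = small_cohort[small_cohort["group"] == "patient"].copy()
        g2 = g1.copy()
        g2["group"] = "control"
        table = pd.concat([g1, g2], ignore_index=True)
        hc = compare_hubs(table, GRID)
        assert hc.hub_sets["patient"].regions == hc.hub_sets["control"].regions
        assert hc.only_in("patient") == []

    def test_bridge_region_hub_in_affected_group_only(self):
        n = 68
        part = np.arange(n) % 4
        c1 = bridge_correlation(part, 0.4, 0.0, bridge=0, bridge_strength=0.7)
        c2 = np.where(part[:, None] == part[None, :], 0.4, 0.0)
        np.fill_diagonal(c2, 1.0)
        spec = SyntheticSpec(
            group_sizes=(60, 60), correlation_override=(c1, c2), seed=23
        )
        cohort = generate_cohort(spec)
        hc = compare_hubs(cohort, GRID)
        bridge = spec.region_names[0]
        assert bridge in hc.hub_sets["patient"].regions
        assert bridge not in hc.hub_sets["control"].regions

    def test_majority_mode_runs(self, small_cohort):
        hc = compare_hubs(small_cohort, DensityRange(0.2, 0.3, 0.05), mode="majority")
        assert hc.mode == "majority"
        for g in hc.groups:
            assert isinstance(hc.hub_sets[g].regions, list)

    def test_unknown_mode(self, small_cohort):
        with pytest.raises(ValueError, match="mode"):
            compare_hubs(small_cohort, GRID, mode="weird")
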