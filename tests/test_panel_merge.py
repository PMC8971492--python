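"""Cross-panel imputation and single-channel salvage."""

import numpy as np
import pandas as pd
import pytest

from cytobatch import (
    CytometryDataset,
    ValidationError,
    find_marker_overlap,
    impute_across_panels,
    salvage_channel,
    silverman_bandwidth,
    write_fcs,
)

from conftest import make_dataset


class TestOverlap:
    def test_set_algebra(self):
        plan = find_marker_overlap(["x", "y", "z"], ["y", "z", "w"])
        assert plan.overlap_markers == ["y", "z"]
        assert plan.missing_in_A == ["w"]
        assert plan.missing_in_B == ["x"]

    def test_identical_panels(self):
        plan = find_marker_overlap(["a", "b"], ["b", "a"])
        assert plan.missing_in_A == [] and plan.missing_in_B == []

    def test_disjoint_panels_error(self):
        with pytest.raises(ValidationError):
            find_marker_overlap(["a"], ["b"])


def two_panels(n=600, seed=0, extra_sd=0.3, r=0.0):
    """Panels sharing 3 markers; B additionally measures m4 (and m5 when
    r != 0, correlated with m4 at r)."""
    rng = np.random.default_rng(seed)
    shared_a = rng.normal(0, 1, (n, 3))
    shared_b = rng.normal(0, 1, (n, 3))
    m4 = rng.normal(2, extra_sd, (n, 1))
    cols_b = {"m1": shared_b[:, 0], "m2": shared_b[:, 1], "m3": shared_b[:, 2],
              "m4": m4[:, 0]}
    if r:
        noise = rng.normal(0, extra_sd, n)
        cols_b["m5"] = 2 + r * (m4[:, 0] - 2) + np.sqrt(1 - r**2) * noise * 1.0
    ds_a = make_dataset(shared_a, ["pa"] * n, markers=["m1", "m2", "m3"])
    ds_b = make_dataset(
        np.column_stack(list(cols_b.values())), ["pb"] * n,
        markers=list(cols_b),
    )
    return ds_a, ds_b


class TestImputation:
    def test_sparse_nodes_get_missing_sentinel(self):
        ds_a, ds_b = two_panels(n=200, seed=1)
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, grid_x=8, grid_y=8,
            min_donors=50, seed=0,
        )
        merged = impute_across_panels(ds_a, ds_b, plan)
        # 200 donors over 64 nodes: every node is below the donor floor
        col = merged.marker_names.index("m4")
        rows_a = merged.cell_meta["panel"] == "A"
        assert np.isnan(merged.expression[rows_a.to_numpy(), col]).all()

    def test_zero_bandwidth_copies_donor_value_exactly(self):
        ds_a, ds_b = two_panels(n=300, seed=2, extra_sd=0.0)
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, grid_x=2, grid_y=2,
            min_donors=10, seed=0,
        )
        merged = impute_across_panels(ds_a, ds_b, plan)
        col = merged.marker_names.index("m4")
        rows_a = (merged.cell_meta["panel"] == "A").to_numpy()
        vals = merged.expression[rows_a, col]
        np.testing.assert_allclose(vals[~np.isnan(vals)], 2.0)

    def test_measured_values_never_modified(self):
        ds_a, ds_b = two_panels(n=500, seed=3)
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, grid_x=2, grid_y=2,
            min_donors=5, seed=1,
        )
        merged = impute_across_panels(ds_a, ds_b, plan)
        rows_a = (merged.cell_meta["panel"] == "A").to_numpy()
        for m in ["m1", "m2", "m3"]:
            np.testing.assert_array_equal(
                merged.expression[rows_a, merged.marker_names.index(m)],
                ds_a.expression[:, ds_a.marker_index(m)],
            )

    def test_per_node_frequencies_preserved(self):
        ds_a, ds_b = two_panels(n=500, seed=4)
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, grid_x=4, grid_y=4,
            min_donors=5, seed=1,
        )
        merged = impute_across_panels(ds_a, ds_b, plan)
        assert (merged.cell_meta["panel"] == "A").sum() == ds_a.n_cells
        assert (merged.cell_meta["panel"] == "B").sum() == ds_b.n_cells

    def test_single_donor_draw_preserves_coexpression(self):
        # two imputed markers correlated at r=0.9 among donors must stay
        # correlated after imputation (joint draws from one donor)
        n = 5000
        ds_a, ds_b = two_panels(n=n, seed=5, extra_sd=1.0, r=0.9)
        r_donor = np.corrcoef(
            ds_b.expression[:, ds_b.marker_index("m4")],
            ds_b.expression[:, ds_b.marker_index("m5")],
        )[0, 1]
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, grid_x=2, grid_y=2,
            min_donors=50, seed=2,
        )
        merged = impute_across_panels(ds_a, ds_b, plan)
        rows_a = (merged.cell_meta["panel"] == "A").to_numpy()
        i4 = merged.marker_names.index("m4")
        i5 = merged.marker_names.index("m5")
        v4, v5 = merged.expression[rows_a, i4], merged.expression[rows_a, i5]
        ok = ~np.isnan(v4)
        r_imp = np.corrcoef(v4[ok], v5[ok])[0, 1]
        assert abs(r_imp - r_donor) < 0.05

    def test_deterministic_under_seed(self):
        ds_a, ds_b = two_panels(n=400, seed=6)
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, grid_x=2, grid_y=2,
            min_donors=5, seed=3,
        )
        m1 = impute_across_panels(ds_a, ds_b, plan)
        m2 = impute_across_panels(ds_a, ds_b, plan)
        np.testing.assert_array_equal(
            np.nan_to_num(m1.expression), np.nan_to_num(m2.expression)
        )

    def test_sentinels_refused_by_fcs_writer(self, tmp_path):
        ds_a, ds_b = two_panels(n=200, seed=7)
        plan = find_marker_overlap(
            ds_a.marker_names, ds_b.marker_names, min_donors=50, seed=0
        )
        merged = impute_across_panels(ds_a, ds_b, plan)
        assert np.isnan(merged.expression).any()
        with pytest.raises(ValidationError):
            write_fcs(merged, tmp_path / "merged.fcs")


class TestSalvage:
    def _dataset(self, n_per_batch=400, seed=0, zero_bad=True):
        rng = np.random.default_rng(seed)
        pops = rng.integers(0, 2, 3 * n_per_batch)
        means = np.array([[0.3, 0.2, 3.0, 1.0], [3.5, 2.8, 0.4, 1.0]])
        x = means[pops] + rng.normal(0, 0.3, (3 * n_per_batch, 4))
        batches = np.repeat(["b1", "b2", "b3"], n_per_batch)
        if zero_bad:
            x[batches == "b3", 3] = 0.0  # mis-stained channel in b3
            means_by_pop = means.copy()
        return make_dataset(x, batches, markers=["m1", "m2", "m3", "m4"]), pops

    def test_no_bad_batches_is_identity(self):
        ds, _ = self._dataset()
        out = salvage_channel(ds, "m4", [], seed=0)
        np.testing.assert_array_equal(out.expression, ds.expression)

    def test_only_target_channel_in_bad_batches_changes(self):
        ds, _ = self._dataset(seed=1)
        out = salvage_channel(ds, "m4", ["b3"], grid_x=2, grid_y=2,
                              seed=0, min_donors=10)
        bad = ds.batches == "b3"
        np.testing.assert_array_equal(
            out.expression[:, :3], ds.expression[:, :3]
        )
        np.testing.assert_array_equal(
            out.expression[~bad, 3], ds.expression[~bad, 3]
        )
        assert not np.array_equal(out.expression[bad, 3], ds.expression[bad, 3])

    def test_imputed_values_match_good_batch_population_means(self):
        rng = np.random.default_rng(9)
        n = 1000
        pops = rng.integers(0, 2, 3 * n)
        means = np.array([[0.3, 0.2, 3.0, 0.5], [3.5, 2.8, 0.4, 2.5]])
        x = means[pops] + rng.normal(0, 0.25, (3 * n, 4))
        batches = np.repeat(["b1", "b2", "b3"], n)
        bad = batches == "b3"
        x[bad, 3] = 0.0
        ds = make_dataset(x, batches, markers=["m1", "m2", "m3", "m4"])
        out = salvage_channel(ds, "m4", ["b3"], grid_x=2, grid_y=2,
                              seed=1, min_donors=20)
        for p in (0, 1):
            good_mean = x[~bad & (pops == p), 3].mean()
            rows = bad & (pops == p)
            imputed = out.expression[rows, 3]
            imputed = imputed[~np.isnan(imputed)]
            assert abs(imputed.mean() - good_mean) < 0.1

    def test_all_batches_bad_error(self):
        ds, _ = self._dataset()
        with pytest.raises(ValidationError):
            salvage_channel(ds, "m4", ["b1", "b2", "b3"])


def test_silverman_bandwidth_degenerate_cases():
    assert silverman_bandwidth(np.array([1.0])) == 0.0
    assert silverman_bandwidth(np.full(100, 3.3)) == 0.0
    assert silverman_bandwidth(np.random.default_rng(0).normal(0, 1, 500)) > 0
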