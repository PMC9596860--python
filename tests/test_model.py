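import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.stats import linregress, pearsonr

from d2nuc import core, markers, model, plot2d, synth
from d2nuc.model import (
    AreaModel,
    activation_index,
    classify_modes,
    cluster_states,
    high_density_profile,
    per_bin_stochasticity,
    periphery_lad_correlation,
    property_strength,
)
from d2nuc.plot2d import D2Plot, OccupancyMatrix, standard_diploid_bounds

import oracles


class TestClusterStates:
    def test_ward_merge_sequence_matches_brute_force(self):
        points = np.array([0.0, 0.4, 3.0, 3.3, 10.0, 10.9])
        Z = hierarchy.linkage(points[:, None], method="ward")
        got = oracles.scipy_merge_sequence(Z, len(points))
        expected = oracles.ward_merge_sequence(points)
        assert got == expected

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array(
            [[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 0], [0, 0, 0, 10]], dtype=float
        )
        rows, truth = [], []
        for ci, c in enumerate(centers):
            for _ in range(8):
                rows.append(c + rng.normal(scale=0.05, size=4))
                truth.append(ci)
        e = pd.DataFrame(rows, index=range(len(rows)), columns=list("abcd"))
        areas = cluster_states(e, k=4, active_markers=["a"])
        df = pd.DataFrame({"truth": truth, "cluster": areas.cluster})
        # each true blob maps to exactly one cluster
        assert (df.groupby("truth")["cluster"].nunique() == 1).all()
        assert df.groupby("cluster")["truth"].nunique().eq(1).all()

    def test_k1_single_cluster(self):
        e = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 3)), columns=list("xyz"))
        areas = cluster_states(e, k=1)
        assert set(areas.cluster) == {1}

    def test_too_many_clusters_rejected(self):
        e = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_states(e, k=4)

    def test_area_labels_follow_marker_structure(self):
        # 4 blobs: high-active / mid-active / high-histone / high-repeat
        rng = np.random.default_rng(2)
        blocks = {
            "active": {"act": 2.0, "hist": -1.0, "rep": -1.0},
            "intermediate": {"act": 0.8, "hist": -0.5, "rep": -0.5},
            "repress_histone": {"act": -1.0, "hist": 2.0, "rep": -1.0},
            "repress_repeat": {"act": -1.0, "hist": -1.0, "rep": 2.0},
        }
        rows, expected = [], []
        for label, means in blocks.items():
            for _ in range(6):
                rows.append(
                    [means["act"] + rng.normal(0, 0.05),
                     means["hist"] + rng.normal(0, 0.05),
                     means["rep"] + rng.normal(0, 0.05)]
                )
                expected.append(label)
        e = pd.DataFrame(rows, columns=["act", "hist", "rep"])
        areas = cluster_states(
            e, k=4, active_markers=["act"], histone_markers=["hist"],
            repeat_markers=["rep"],
        )
        assert list(areas.labels) == expected


class TestPropertyStrength:
    def _plot_with_states(self, states):
        counts = np.zeros(225)
        counts[states] = 200
        return D2Plot(standard_diploid_bounds(), 15, counts)

    def test_exact_linear_slope(self):
        # one DisTP row (distp_bin=0), E linear in density center, slope -0.5
        states = np.array([d * 15 for d in range(5)])  # density bins 0..4, distp 0
        plot = self._plot_with_states(states)
        centers = plot.state_coords(states)["density_center"].to_numpy()
        e = pd.DataFrame({"m": -0.5 * centers}, index=states)
        s = property_strength(e, plot, active_markers=["m"])
        assert s.loc[0, "density"] == pytest.approx(-0.5)

    def test_constant_gives_zero_slope(self):
        states = np.array([d * 15 for d in range(5)])
        plot = self._plot_with_states(states)
        e = pd.DataFrame({"m": np.ones(5)}, index=states)
        s = property_strength(e, plot, active_markers=["m"])
        assert s.loc[0, "density"] == pytest.approx(0.0)

    def test_matches_closed_form_slope(self):
        rng = np.random.default_rng(3)
        states = np.array([d * 15 + 2 for d in range(5)])  # distp row 2
        plot = self._plot_with_states(states)
        x = plot.state_coords(states)["density_center"].to_numpy()
        y = rng.normal(size=5)
        e = pd.DataFrame({"m": y}, index=states)
        s = property_strength(e, plot, active_markers=["m"])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert s.loc[2, "density"] == pytest.approx(expected)

    def test_single_state_row_is_nan(self):
        states = np.array([0])
        plot = self._plot_with_states(states)
        e = pd.DataFrame({"m": [1.0]}, index=states)
        s = property_strength(e, plot, active_markers=["m"])
        assert np.isnan(s.loc[0, "density"])

    def test_distp_slope_uses_neighbor_rows(self):
        # states in distp rows 4,5,6 with E linear in distp center, slope 2.0
        states = np.array([4, 5, 6])
        plot = self._plot_with_states(states)
        centers = plot.state_coords(states)["distp_center"].to_numpy()
        e = pd.DataFrame({"m": 2.0 * centers}, index=states)
        s = property_strength(e, plot, active_markers=["m"])
        assert s.loc[5, "distp"] == pytest.approx(2.0)


def _occ_from_dense(P, n_cells=4, resolution=20_000):
    n = P.shape[0]
    segments = pd.DataFrame({"chrom": ["1"] * n, "hap": ["none"] * n, "bin": range(n)})
    from scipy import sparse

    return OccupancyMatrix(segments, sparse.csr_matrix(P), n_cells, resolution)


class TestActivationIndex:
    def _areas(self, active, intermediate, others):
        states = np.array(active + intermediate + others)
        labels = (
            ["active"] * len(active)
            + ["intermediate"] * len(intermediate)
            + ["repress_repeat"] * len(others)
        )
        return AreaModel(
            states=states,
            cluster=np.arange(len(states)) + 1,
            labels=np.array(labels),
        )

    def test_always_active_is_one(self):
        P = np.zeros((1, 225))
        P[0, 3] = 1.0
        ai = activation_index(_occ_from_dense(P), self._areas([3], [7], [11]))
        assert ai.iloc[0] == 1.0

    def test_never_active_is_zero(self):
        P = np.zeros((1, 225))
        P[0, 11] = 1.0
        ai = activation_index(_occ_from_dense(P), self._areas([3], [7], [11]))
        assert ai.iloc[0] == 0.0

    def test_partial_sum(self):
        P = np.zeros((1, 225))
        P[0, 3], P[0, 7], P[0, 11] = 0.3, 0.2, 0.5
        ai = activation_index(_occ_from_dense(P), self._areas([3], [7], [11]))
        assert ai.iloc[0] == pytest.approx(0.5)

    def test_monotone_under_area_growth(self):
        rng = np.random.default_rng(4)
        P = rng.random((20, 225)) * 0.004
        occ = _occ_from_dense(P)
        small = self._areas([3], [7], [11])
        bigger = self._areas([3, 50, 60], [7, 80], [11])
        ai_small = activation_index(occ, small)
        ai_big = activation_index(occ, bigger)
        assert (ai_big >= ai_small - 1e-12).all()

    def test_grid_mismatch_rejected(self):
        P = np.zeros((1, 225))
        occ = _occ_from_dense(P)
        bad = AreaModel(
            states=np.array([500]), cluster=np.array([1]), labels=np.array(["active"])
        )
        with pytest.raises(ValueError, match="grid"):
            activation_index(occ, bad)


class TestClassifyModes:
    def _ai(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2", "s3"], dtype=float)

    def test_worked_examples(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.3, 0.6, size=(100, 3))
        base[0] = [0.99, 0.99, 0.99]  # CA
        base[1] = [0.45, 0.5, 0.98]  # RA: medium, medium, top decile
        base[2] = [0.01, 0.01, 0.01]  # CR
        modes = classify_modes(self._ai(base), q=0.10)
        assert modes["mode"].iloc[0] == "CA"
        assert modes["mode"].iloc[1] == "RA"
        assert modes["mode"].iloc[2] == "CR"

    def test_quantile_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        ai = self._ai(rng.random((200, 3)))
        m1 = classify_modes(ai, q=0.10)["mode"]
        m2 = classify_modes(np.exp(3 * ai), q=0.10)["mode"]
        assert (m1 == m2).all()

    def test_two_stage_minimum(self):
        with pytest.raises(ValueError):
            classify_modes(pd.DataFrame({"s1": [0.1, 0.2]}), q=0.1)

    def test_boundary_value_included(self):
        ai = pd.DataFrame({"s1": np.arange(10.0), "s2": np.arange(10.0)})
        modes = classify_modes(ai, q=0.10)
        # the exact 90th-percentile value counts as active (>= threshold)
        hi = ai["s1"].quantile(0.9)
        assert (modes.loc[ai["s1"] >= hi, "mode"] == "CA").all()


def _cell_table(density, distp, resolution=100_000):
    n = len(density)
    t = pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "hap": ["none"] * n,
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
            "density": density,
            "distp": distp,
        }
    )
    t.attrs["resolution"] = resolution
    return t


class TestPeripheryLadCorrelation:
    def test_identity_track_r_one(self, small_tables, small_ensemble):
        cfg, _, _ = small_ensemble
        res = cfg.resolution
        pooled = pd.concat(
            [
                t.assign(bin=t["start"] // res)[["chrom", "hap", "bin", "distp"]]
                for t in small_tables
            ]
        )
        cut = float(pooled["distp"].median())
        prob = (
            pooled.assign(below=pooled["distp"] < cut)
            .groupby(["chrom", "bin"], as_index=False)["below"]
            .sum()
        )
        prob["value"] = prob["below"] / len(small_tables)
        track = markers.MarkerTrack(
            "lad", "coverage_fraction", prob[["chrom", "bin", "value"]]
        )
        r, p, n = periphery_lad_correlation(
            small_tables, track, distp_cut=cut, agg_bp=res * 5, resolution=res
        )
        assert r == pytest.approx(1.0)
        assert n >= 3

    def test_all_cells_below_cut_gives_probability_one(self):
        # bins 0..9 always peripheral, bins 10..19 split across cells
        distp = np.concatenate([np.ones(10), np.full(10, 5.0)])
        distp_alt = np.concatenate([np.ones(10), np.full(10, 1.0)])
        cells = [
            _cell_table(np.full(20, 2.0), distp),
            _cell_table(np.full(20, 2.0), distp_alt),
        ]
        expected_prob = np.concatenate([np.ones(10), np.full(10, 0.5)])
        values = pd.DataFrame(
            {"chrom": ["1"] * 20, "bin": range(20), "value": expected_prob}
        )
        track = markers.MarkerTrack("lad", "coverage_fraction", values)
        r, _, n = periphery_lad_correlation(
            cells, track, distp_cut=2.0, agg_bp=100_000, resolution=100_000
        )
        assert r == pytest.approx(1.0)
        assert n == 20

    def test_constant_probability_rejected(self):
        cells = [_cell_table([2.0] * 20, [1.0] * 20) for _ in range(3)]
        values = pd.DataFrame(
            {"chrom": ["1"] * 20, "bin": range(20), "value": np.linspace(0, 1, 20)}
        )
        track = markers.MarkerTrack("lad", "coverage_fraction", values)
        with pytest.raises(ValueError, match="variance"):
            # every probability is exactly 1 -> zero variance on x
            periphery_lad_correlation(cells, track, agg_bp=100_000)

    def test_outlier_bin_trimmed(self):
        rng = np.random.default_rng(7)
        n = 60
        prob_signal = np.clip(rng.normal(0.5, 0.1, n), 0, 1)
        distp = np.where(rng.random((3, n)) < prob_signal, 1.0, 5.0)
        cells = [_cell_table(np.full(n, 2.0), distp[i]) for i in range(3)]
        lad_vals = prob_signal + rng.normal(0, 0.02, n)
        lad_vals[0] = 50.0  # contrived 10-sigma outlier
        values = pd.DataFrame({"chrom": ["1"] * n, "bin": range(n), "value": lad_vals})
        track = markers.MarkerTrack("lad", "coverage_fraction", values)
        r, p, kept = periphery_lad_correlation(
            cells, track, agg_bp=100_000, resolution=100_000
        )
        assert kept == n - 1
        # oracle: trim by hand, then plain pearson
        per_bin = (distp < 2.0).mean(axis=0)
        x, y = per_bin[1:], lad_vals[1:]
        assert r == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)


class TestHighDensityProfile:
    def test_uniform_density_flat_profile(self):
        rng = np.random.default_rng(8)
        n = 50_000
        cells = [_cell_table(rng.random(n), rng.uniform(1, 8, n))]
        prof = high_density_profile(cells, top_frac=0.05)
        big = prof[prof["n"] > 1000]
        np.testing.assert_allclose(big["fraction"], 0.05, atol=0.01)

    def test_threshold_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        density = rng.gamma(2.0, 1.0, 10_001)
        cells = [_cell_table(density, rng.uniform(1, 5, 10_001))]
        prof = high_density_profile(cells, top_frac=0.05)
        assert prof.attrs["threshold"] == pytest.approx(
            oracles.sort_quantile(density, 0.95), abs=1e-12
        )

    def test_chromocenters_tilt_profile_inward(self):
        def slope_of(cfg):
            cells, _ = synth.generate_ensemble(cfg)
            prof = high_density_profile(core.score_ensemble(cells))
            prof = prof[prof["n"] > 200]
            return linregress(prof.index.to_numpy(), prof["fraction"]).slope

        base = dict(n_cells=4, n_chroms=2, particles_per_chrom=1000, seed=10,
                    radial_bias={})
        s_cc = slope_of(synth.SynthConfig(chromocenter_fraction=0.25, **base))
        s_plain = slope_of(synth.SynthConfig(chromocenter_fraction=0.0, **base))
        assert s_cc > 0  # high density increasingly interior
        assert s_cc > s_plain


class TestPerBinStochasticity:
    def test_identical_cells_sd_zero(self):
        cells = [_cell_table([1.0, 2.0], [3.0, 4.0]) for _ in range(3)]
        out, _ = per_bin_stochasticity(cells)
        np.testing.assert_allclose(out["density_sd"], 0.0)
        np.testing.assert_allclose(out["distp_sd"], 0.0)

    def test_two_cell_population_sd(self):
        cells = [_cell_table([1.0], [5.0]), _cell_table([3.0], [7.0])]
        out, _ = per_bin_stochasticity(cells)
        assert out["density_mean"].iloc[0] == 2.0
        assert out["density_sd"].iloc[0] == 1.0  # population SD
        assert out["distp_sd"].iloc[0] == 1.0

    def test_matches_columnwise_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.random((5, 30))
        ddata = rng.random((5, 30)) * 4 + 1
        cells = [_cell_table(data[i], ddata[i]) for i in range(5)]
        out, (r, p) = per_bin_stochasticity(cells)
        np.testing.assert_allclose(out["density_mean"], data.mean(axis=0))
        np.testing.assert_allclose(out["density_sd"], data.std(axis=0))
        np.testing.assert_allclose(out["distp_sd"], ddata.std(axis=0))
        expected_r = pearsonr(data.mean(axis=0), data.std(axis=0)).statistic
        assert r == pytest.approx(expected_r)

    def test_segment_in_single_cell_sd_missing(self):
        c1 = _cell_table([1.0, 2.0], [3.0, 4.0])
        c2 = _cell_table([1.0], [3.0])  # second segment unobserved
        out, _ = per_bin_stochasticity([c1, c2])
        assert np.isnan(out.loc[out["bin"] == 1, "density_sd"]).all()

    def test_ensemble_distp_sd_positive(self, small_tables):
        out, _ = per_bin_stochasticity(small_tables)
        seen = out[out["n_cells"] >= 2]
        assert (seen["distp_sd"] > 0).mean() > 0.95

    def test_periphery_anchored_more_stable(self, small_tables, small_ensemble):
        _, _, truth = small_ensemble
        out, _ = per_bin_stochasticity(small_tables)
        merged = out.merge(truth.segments, on=["chrom", "hap", "bin"])
        med = merged.groupby("class")["distp_sd"].median()
        assert med[synth.CLASS_REPRESSED] < med[synth.CLASS_ACTIVE]
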