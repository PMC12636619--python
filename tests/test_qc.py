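import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from mfsyn import qc
from mfsyn.errors import ValidationError
from .conftest import make_table


def _record(efo_hz, cfr, tid=0, dcr=0.5):
    return pd.DataFrame({
        "fov_id": ["f"], "tid": [tid], "t_s": [0.0], "x_nm": [0.0], "y_nm": [0.0],
        "z_nm": [0.0], "efo_hz": [efo_hz], "cfr": [cfr], "dcr": [dcr],
    })


class TestRecordFilter:
    @pytest.mark.parametrize("efo_khz,cfr,kept", [
        (200, 0.5, True),    # inside both windows
        (99, 0.5, False),    # below EFO window
        (200, 0.95, False),  # above CFR window
        (100, 0.9, True),    # closed interval boundaries retained
    ])
    def test_default_thresholds(self, efo_khz, cfr, kept):
        res = qc.filter_records(_record(efo_khz * 1000.0, cfr))
        assert (res.n_retained == 1) == kept

    def test_vacuous_filter_is_identity(self, rng):
        table = make_table(rng, 200)
        thr = qc.QCThresholds(1e-9, np.inf, 0.0, np.inf, 0)
        res = qc.filter_records(table, thr)
        pd.testing.assert_frame_equal(res.table, table)

    def test_rejection_counts_partition_input(self, rng):
        table = make_table(rng, 500)
        table["efo_hz"] = rng.uniform(50_000, 400_000, 500)
        table["cfr"] = rng.uniform(0, 1.2, 500)
        res = qc.filter_records(table)
        assert res.n_retained + sum(res.rejected.values()) == res.n_input == 500

    def test_filtering_is_idempotent(self, rng):
        table = make_table(rng, 300)
        table["efo_hz"] = rng.uniform(50_000, 400_000, 300)
        once = qc.filter_records(table).table
        twice = qc.filter_records(once).table
        pd.testing.assert_frame_equal(once, twice)


class TestTraceLengthFilter:
    def test_strictly_greater_than_len_min(self):
        t3 = pd.concat([_record(2e5, 0.5, tid=1)] * 3, ignore_index=True)
        t4 = pd.concat([_record(2e5, 0.5, tid=2)] * 4, ignore_index=True)
        out = qc.filter_trace_length(pd.concat([t3, t4], ignore_index=True), 3)
        assert set(out["tid"]) == {2}

    def test_empty_table_passes_through(self):
        out = qc.filter_trace_length(_record(2e5, 0.5).iloc[:0], 3)
        assert len(out) == 0

    def test_survivors_match_brute_force_group_scan(self, rng):
        table = make_table(rng, 400, n_traces=60)
        out = qc.filter_trace_length(table, 5)
        expected = {tid for tid, grp in table.groupby("tid") if len(grp) > 5}
        assert set(out["tid"]) == expected


class TestDcrMixture:
    def test_parameter_recovery_on_stated_mixture(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([
            np.clip(rng.normal(0.25, 0.05, 5000), 0, 1),
            np.clip(rng.normal(0.60, 0.07, 5000), 0, 1),
        ])
        mix = qc.fit_dcr_mixture(x)
        assert abs(mix.mu1 - 0.25) <= 0.02
        assert abs(mix.mu2 - 0.60) <= 0.02
        assert abs(mix.w1 - 0.5) <= 0.05

    def test_tight_clumps_give_means_and_interior_boundary(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.2, 0.005, 200), rng.normal(0.7, 0.005, 200)])
        mix = qc.fit_dcr_mixture(np.clip(x, 0, 1))
        assert abs(mix.mu1 - 0.2) < 0.01 and abs(mix.mu2 - 0.7) < 0.01
        assert mix.mu1 < mix.boundary < mix.mu2

    def test_boundary_equals_grid_search_crossing(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([
            np.clip(rng.normal(0.25, 0.05, 3000), 0, 1),
            np.clip(rng.normal(0.60, 0.07, 3000), 0, 1),
        ])
        mix = qc.fit_dcr_mixture(x)
        grid = np.arange(mix.mu1, mix.mu2, 1e-4)
        diff = np.abs(
            mix.w1 * qc._norm_pdf(grid, mix.mu1, mix.sigma1)
            - mix.w2 * qc._norm_pdf(grid, mix.mu2, mix.sigma2))
        assert abs(mix.boundary - grid[np.argmin(diff)]) <= 2e-4

    def test_matches_sklearn_mixture_oracle(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(9)
        x = np.concatenate([
            np.clip(rng.normal(0.25, 0.05, 4000), 0, 1),
            np.clip(rng.normal(0.60, 0.07, 4000), 0, 1),
        ])
        mix = qc.fit_dcr_mixture(x)
        gm = sklearn.GaussianMixture(2, random_state=0).fit(x[:, None])
        mus = np.sort(gm.means_.ravel())
        assert abs(mix.mu1 - mus[0]) < 0.01 and abs(mix.mu2 - mus[1]) < 0.01

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            qc.fit_dcr_mixture(np.linspace(0, 1, 49))


class TestAssignChannels:
    @pytest.fixture
    def mix(self):
        return qc.DcrMixture(0.5, 0.5, 0.25, 0.60, 0.05, 0.07, boundary=0.4)

    def test_record_at_component_mean_goes_low(self, mix, rng):
        table = make_table(rng, 4, n_traces=1)
        table["dcr"] = mix.mu1
        labeled, discarded = qc.assign_channels(table, mix)
        assert len(discarded) == 0
        assert (labeled["channel"] == qc.CH_LOW).all()

    def test_boundary_record_is_discarded(self, mix, rng):
        table = make_table(rng, 1, n_traces=1)
        table["dcr"] = mix.boundary
        labeled, discarded = qc.assign_channels(table, mix)
        assert len(labeled) == 0 and len(discarded) == 1

    def test_partition_is_exact(self, mix, rng):
        table = make_table(rng, 300, n_traces=40)
        labeled, discarded = qc.assign_channels(table, mix)
        assert len(labeled) + len(discarded) == len(table)

    def test_misassignment_below_bayes_error_plus_margin(self, mix):
        rng = np.random.default_rng(77)
        n = 20_000
        true = rng.uniform(size=n) < 0.5
        d = np.where(true, rng.normal(0.60, 0.07, n), rng.normal(0.25, 0.05, n))
        table = pd.DataFrame({
            "fov_id": "f", "tid": np.arange(n, dtype=np.int64), "t_s": 0.0,
            "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0, "efo_hz": 2e5, "cfr": 0.5,
            "dcr": np.clip(d, 0, 1),
        })
        labeled, _ = qc.assign_channels(table, mix)
        truth = dict(zip(table["tid"], np.where(true, qc.CH_HIGH, qc.CH_LOW)))
        wrong = sum(ch != truth[tid] for tid, ch in zip(labeled["tid"], labeled["channel"]))
        rate = wrong / len(labeled)
        bayes, _ = quad(lambda v: min(0.5 * qc._norm_pdf(v, 0.25, 0.05),
                                      0.5 * qc._norm_pdf(v, 0.60, 0.07)), -1, 2)
        assert rate <= bayes + 0.01


class TestZCorrection:
    def test_scales_z_only(self, rng):
        table = make_table(rng, 10)
        out = qc.correct_z(table, 0.7)
        np.testing.assert_allclose(out["z_nm"], table["z_nm"] * 0.7)
        np.testing.assert_array_equal(out["x_nm"], table["x_nm"])
        # the quoted example: 100 nm measured -> 70 nm corrected
        one = qc.correct_z(_record(2e5, 0.5).assign(z_nm=100.0))
        assert one["z_nm"].iloc[0] == pytest.approx(70.0)

    def test_linearity_and_identity(self, rng):
        table = make_table(rng, 20)
        ab = qc.correct_z(qc.correct_z(table, 0.8), 0.5)
        direct = qc.correct_z(table, 0.4)
        pd.testing.assert_frame_equal(ab, direct)
        pd.testing.assert_frame_equal(qc.correct_z(table, 1.0), table)

    def test_commutes_with_filtering(self, rng):
        table = make_table(rng, 200)
        a = qc.correct_z(qc.filter_records(table).table, 0.7)
        b = qc.filter_records(qc.correct_z(table, 0.7)).table
        pd.testing.assert_frame_equal(a, b)


class TestAggregation:
    def test_identical_points_zero_spread(self):
        table = pd.concat([_record(2e5, 0.5, tid=7)] * 4, ignore_index=True)
        table[["x_nm", "y_nm", "z_nm"]] = 5.0
        tr = qc.aggregate_traces(table)
        assert tr.loc[0, ["sd_x_nm", "sd_y_nm", "sd_z_nm"]].tolist() == [0, 0, 0]
        assert tr.loc[0, "x_nm"] == 5.0

    def test_two_point_trace_forced_by_n_minus_1(self):
        table = pd.concat([_record(2e5, 0.5, tid=1)] * 2, ignore_index=True)
        table.loc[1, "x_nm"] = 2.0
        tr = qc.aggregate_traces(table)
        assert tr.loc[0, "x_nm"] == pytest.approx(1.0)
        assert tr.loc[0, "sd_x_nm"] == pytest.approx(np.sqrt(2))

    def test_centroids_match_brute_force_means(self, rng):
        table = make_table(rng, 300, n_traces=30)
        table = qc.filter_trace_length(table, 1)
        tr = qc.aggregate_traces(table).set_index("tid")
        for tid, grp in table.groupby("tid"):
            if len(grp) < 2:
                continue
            assert tr.loc[tid, "x_nm"] == pytest.approx(grp["x_nm"].mean())
            assert tr.loc[tid, "sd_y_nm"] == pytest.approx(grp["y_nm"].std(ddof=1))

    def test_single_point_trace_excluded_with_warning(self):
        table = _record(2e5, 0.5, tid=1)
        with pytest.warns(UserWarning, match="fewer than 2"):
            tr = qc.aggregate_traces(table)
        assert len(tr) == 0


class TestResolution:
    def _traces(self, rng, sigma, n_traces=500, n_locs=10):
        recs = []
        for tid in range(n_traces):
            pts = rng.normal(0, sigma, (n_locs, 3))
            for p in pts:
                recs.append(("f", tid, *p))
        df = pd.DataFrame(recs, columns=["fov_id", "tid", "x_nm", "y_nm", "z_nm"])
        return qc.aggregate_traces(df)

    def test_recovers_generating_sigma_bias_corrected(self):
        rng = np.random.default_rng(31)
        sigma = np.array([5.39, 5.14, 3.01])
        est = qc.estimate_resolution(self._traces(rng, sigma), bias_correct=True)
        np.testing.assert_allclose(est.mean_nm, sigma, rtol=0.05)

    def test_naive_mode_shows_known_c4_bias(self):
        rng = np.random.default_rng(32)
        sigma = np.array([5.0, 5.0, 5.0])
        naive = qc.estimate_resolution(self._traces(rng, sigma), bias_correct=False)
        c4 = qc._c4(10)
        np.testing.assert_allclose(naive.mean_nm, sigma * c4, rtol=0.03)

    def test_hand_computed_mean_on_three_traces(self):
        traces = pd.DataFrame({
            "fov_id": ["a", "a", "b"], "tid": [1, 2, 3], "channel": "",
            "n_locs": [4, 4, 4],
            "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0,
            "sd_x_nm": [1.0, 2.0, 6.0], "sd_y_nm": [1.0, 1.0, 1.0],
            "sd_z_nm": [0.0, 0.0, 0.0],
        })
        est = qc.estimate_resolution(traces)
        assert est.mean_nm[0] == pytest.approx(3.0)
        # per-FOV mode averages FOV means: ((1+2)/2 + 6)/2 = 3.75
        est_fov = qc.estimate_resolution(traces, group_by_fov=True)
        assert est_fov.mean_nm[0] == pytest.approx(3.75)

    def test_all_zero_spreads(self):
        traces = pd.DataFrame({
            "fov_id": "a", "tid": [1, 2], "channel": "", "n_locs": 4,
            "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0,
            "sd_x_nm": 0.0, "sd_y_nm": 0.0, "sd_z_nm": 0.0,
        })
        assert qc.estimate_resolution(traces).mean_nm == (0, 0, 0)
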