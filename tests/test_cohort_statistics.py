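"""Activation rates, the threshold sweep, and threshold selection."""

import warnings

import numpy as np
import pytest

from mechanoindent import (
    CohortReport,
    SweepCurve,
    activation_rate,
    activation_rate_at_depth,
    build_report,
    classify_cohort,
    default_sweep_grid,
    select_threshold,
    threshold_sweep,
)
from mechanoindent.cohort_statistics import UNASSIGNED
from mechanoindent.synthetic_data import CohortSpec, TraceGenConfig, gen_cohort
from mechanoindent.trace_classification import CellClassification


def fake_cls(n_resp, n_total, delta=5.2, group="WT"):
    out = []
    for i in range(n_total):
        responsive = i < n_resp
        out.append(
            CellClassification(
                cell_id=f"c{i}", group=group, responsive=responsive,
                step_index=3 if responsive else None,
                delta_um=delta if responsive else None,
            )
        )
    return out


class TestActivationRate:
    @pytest.mark.parametrize("n_resp, n, expected", [(0, 7, 0.0), (5, 10, 50.0), (3, 3, 100.0)])
    def test_counting(self, n_resp, n, expected):
        assert activation_rate(fake_cls(n_resp, n)) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            activation_rate([])

    def test_synthetic_cohort_recovers_parameter_within_one_cell(
        self, default_train, default_depths
    ):
        spec = CohortSpec(group_name="Piezo1", n_cells=28, responsive_fraction=0.32, seed=8)
        traces = gen_cohort(spec, TraceGenConfig(), default_train)
        cls = classify_cohort(traces, default_train, default_depths, 2.5)
        assert activation_rate(cls) == pytest.approx(32.0, abs=100.0 / 28)


class TestActivationRateAtDepth:
    def test_single_bin_holds_entire_ar(self, default_depths):
        cls = fake_cls(4, 10, delta=default_depths[3])
        hist = activation_rate_at_depth(cls, default_depths)
        assert hist[f"{default_depths[3]:.2f}"] == pytest.approx(40.0)
        assert sum(hist.values()) == pytest.approx(activation_rate(cls))

    def test_no_responsive_cells_all_bins_zero(self, default_depths):
        hist = activation_rate_at_depth(fake_cls(0, 5), default_depths)
        assert all(v == 0.0 for v in hist.values())

    def test_negative_depth_bins_are_excluded(self, default_depths):
        hist = activation_rate_at_depth(fake_cls(1, 4), default_depths)
        keys = [k for k in hist if k != UNASSIGNED]
        assert all(float(k) > 0 for k in keys)
        # the default train reaches a 9.2 um cell only from the third step on
        assert len(keys) == 4

    def test_unassigned_cells_counted_with_warning(self, default_depths):
        cls = [CellClassification(cell_id="x", group="WT", responsive=True, delta_um=None)]
        with pytest.warns(UserWarning, match="unassigned"):
            hist = activation_rate_at_depth(cls, default_depths)
        assert hist[UNASSIGNED] == pytest.approx(100.0)

    def test_ground_truth_indices_occupy_matching_bins(self, default_train, default_depths):
        spec = CohortSpec(group_name="Piezo1", n_cells=30, responsive_fraction=0.5,
                          responsive_depth_index=2, seed=5)
        traces = gen_cohort(spec, TraceGenConfig(), default_train)
        cls = classify_cohort(traces, default_train, default_depths, 2.5)
        hist = activation_rate_at_depth(cls, default_depths)
        occupied = {k for k, v in hist.items() if v > 0}
        assert occupied == {f"{default_depths[2]:.2f}"}


@pytest.fixture(scope="module")
def sweep_setup(default_train, default_depths):
    cfg = TraceGenConfig()
    traces = []
    for group, n, frac in [("WT", 20, 0.18), ("Piezo1", 20, 0.32), ("CaFree", 12, 0.0)]:
        spec = CohortSpec(group_name=group, n_cells=n, responsive_fraction=frac, seed=13)
        traces += gen_cohort(spec, cfg, default_train, peak_amplitude=3.5)
    sweep = threshold_sweep(traces, default_train, default_depths)
    return traces, sweep


class TestThresholdSweep:
    def test_ar_curves_monotone_non_increasing(self, sweep_setup):
        _, sweep = sweep_setup
        for group, curve in sweep.ar_percent.items():
            assert np.all(np.diff(curve) <= 0), group

    def test_cafree_null_above_noise_regime(self, sweep_setup):
        _, sweep = sweep_setup
        control = sweep.ar_percent["CaFree"]
        assert np.all(control[sweep.grid >= 1.5] == 0.0)

    def test_no_response_above_max_amplitude(self, sweep_setup):
        _, sweep = sweep_setup
        for curve in sweep.ar_percent.values():
            assert np.all(curve[sweep.grid >= 3.6] == 0.0)

    def test_sweep_consistent_with_single_threshold_classification(
        self, sweep_setup, default_train, default_depths
    ):
        traces, sweep = sweep_setup
        i = int(np.argmin(np.abs(sweep.grid - 2.5)))
        wt = [t for t in traces if t.group == "WT"]
        cls = classify_cohort(wt, default_train, default_depths, 2.5)
        assert sweep.ar_percent["WT"][i] == pytest.approx(activation_rate(cls))

    def test_end_to_end_selection_near_study_value(self, sweep_setup):
        _, sweep = sweep_setup
        assert select_threshold(sweep) == pytest.approx(2.5, abs=0.25)

    def test_conservation_across_thresholds(self, sweep_setup, default_train, default_depths):
        traces, _ = sweep_setup
        for rt in (1.0, 2.0, 2.5, 3.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cls = classify_cohort(traces, default_train, default_depths, rt)
            by_group = {}
            for c in cls:
                by_group.setdefault(c.group, []).append(c)
            for g, gc in by_group.items():
                hist = activation_rate_at_depth(gc, default_depths)
                assert sum(hist.values()) == pytest.approx(activation_rate(gc)), (g, rt)


class TestSelectThreshold:
    @staticmethod
    def synthetic_sweep(lower, upper):
        grid = default_sweep_grid()
        control = np.where(grid < lower, 50.0, 0.0)
        # groups still respond AT the upper bound, not above it
        treated = np.where(grid <= upper + 1e-9, 40.0, 0.0)
        return SweepCurve(grid=grid, ar_percent={"CaFree": control, "Piezo1": treated})

    def test_reference_bounds_give_midpoint(self):
        sweep = self.synthetic_sweep(1.5, 3.5)
        assert select_threshold(sweep) == pytest.approx(2.5)

    def test_degenerate_interval_returns_bound(self):
        grid = default_sweep_grid()
        zero = np.zeros(len(grid))
        sweep = SweepCurve(grid=grid, ar_percent={"CaFree": zero, "Piezo1": zero})
        assert select_threshold(sweep) == pytest.approx(grid[0])

    def test_missing_control_rejected(self):
        sweep = self.synthetic_sweep(1.5, 3.5)
        with pytest.raises(ValueError, match="control group"):
            select_threshold(sweep, control_group="Locke")

    def test_never_settling_control_rejected(self):
        grid = default_sweep_grid()
        sweep = SweepCurve(
            grid=grid, ar_percent={"CaFree": np.full(len(grid), 10.0)}
        )
        with pytest.raises(ValueError, match="never settles"):
            select_threshold(sweep)


class TestReport:
    def test_single_responsive_cell_report(self, default_depths):
        sweep = TestSelectThreshold.synthetic_sweep(1.5, 3.5)
        cls = fake_cls(1, 1, delta=default_depths[3], group="Piezo1")
        report = build_report(cls, sweep, 2.5, default_depths)
        assert report.ar_percent["Piezo1"] == pytest.approx(100.0)
        hist = report.ar_delta["Piezo1"]
        assert hist[f"{default_depths[3]:.2f}"] == pytest.approx(100.0)

    def test_report_round_trips_through_json(self, tmp_path, default_depths):
        sweep = TestSelectThreshold.synthetic_sweep(1.5, 3.5)
        cls = fake_cls(2, 5, delta=default_depths[4], group="WT")
        report = build_report(cls, sweep, 2.5, default_depths, provenance={"seed": 1})
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = CohortReport.from_json(path)
        assert loaded.to_dict() == report.to_dict()

    def test_ar_recovery_over_replicates(self, default_train, default_depths):
        """Mean recovered AR lies within 2 binomial SEs of 100 p for the
        study's responsive fractions, over 20 seeded replicates."""
        cfg = TraceGenConfig()
        for p, n in [(0.18, 33), (0.32, 28)]:
            ars = []
            for rep in range(20):
                spec = CohortSpec(group_name="Piezo1", n_cells=n,
                                  responsive_fraction=p, seed=1000 + rep)
                traces = gen_cohort(spec, cfg, default_train)
                cls = classify_cohort(traces, default_train, default_depths, 2.5)
                ars.append(activation_rate(cls))
            se = 100.0 * np.sqrt(p * (1 - p) / n) / np.sqrt(20)
            # the generator fixes round(n p) responsive cells per replicate,
            # so the binomial SE bounds the residual rounding + detection error
            assert abs(np.mean(ars) - 100.0 * p) <= 2 * max(se, 100.0 * 0.5 / n)
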