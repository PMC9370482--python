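"""Positioning metrology: deviations, E, backlash estimation and correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mechanoindent import (
    apply_overshoot,
    bidirectional_systematic_error,
    deviations,
    estimate_backlash,
    plan_overshoot,
    positioning_accuracy,
    random_error,
    total_uncertainty,
)
from mechanoindent.synthetic_data import StageSimConfig, gen_stage_trajectory, make_sawtooth


def traj_from_deviations(dev_by_pos_dir, n_repeats=1):
    """Build a trajectory table with prescribed deviations.

    ``dev_by_pos_dir``: {(position_index, direction): deviation or list of
    per-repeat deviations}.
    """
    rows = []
    for (pos, d), dev in dev_by_pos_dir.items():
        devs = np.atleast_1d(dev)
        for rep, v in enumerate(devs, start=1):
            rows.append((rep, pos, d, float(pos), float(pos) + float(v)))
    return pd.DataFrame(
        rows, columns=["repeat", "position_index", "direction", "target_um", "measured_um"]
    )


class TestDeviations:
    def test_perfect_stage_is_all_zero(self):
        traj = traj_from_deviations({(1, "+"): [0, 0], (1, "-"): [0, 0]})
        table = deviations(traj)
        assert np.allclose(table["mean_dev_um"], 0)
        assert np.allclose(table["std_dev_um"], 0)

    def test_hand_arithmetic_mean_and_sd(self):
        traj = traj_from_deviations({(1, "+"): [0.1, 0.2, 0.3], (1, "-"): [0, 0, 0]})
        row = deviations(traj).loc[(1, "+")]
        assert row["mean_dev_um"] == pytest.approx(0.2)
        assert row["std_dev_um"] == pytest.approx(0.1)

    def test_single_repeat_sd_is_zero(self):
        traj = traj_from_deviations({(1, "+"): 0.4, (1, "-"): 0.1})
        assert np.allclose(deviations(traj)["std_dev_um"], 0.0)


class TestSystematicError:
    def test_constant_offset_cancels(self):
        traj = traj_from_deviations({(i, d): 0.7 for i in (1, 2, 3) for d in "+-"})
        assert bidirectional_systematic_error(traj) == pytest.approx(0.0)

    def test_max_minus_min_arithmetic(self):
        traj = traj_from_deviations({(1, "+"): -1.5, (2, "+"): 0.0, (1, "-"): 1.7, (2, "-"): 0.0})
        assert bidirectional_systematic_error(traj) == pytest.approx(3.2)

    def test_single_direction_rejected(self):
        traj = traj_from_deviations({(1, "+"): 0.0, (2, "+"): 0.1})
        with pytest.raises(ValueError, match="both approach directions"):
            bidirectional_systematic_error(traj)

    def test_constant_backlash_gives_e_equal_b(self):
        cfg = StageSimConfig(
            true_backlash_pos_neg_um=2.0, true_backlash_neg_pos_um=2.0, seed=0
        )
        traj = gen_stage_trajectory(cfg, make_sawtooth(20, 1.0, 1))
        assert bidirectional_systematic_error(traj) == pytest.approx(2.0)

    @given(offset=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_constant_measured_offset(self, offset):
        cfg = StageSimConfig(seed=3, step_noise_sd_nm=50.0)
        traj = gen_stage_trajectory(cfg, make_sawtooth(10, 1.0, 2))
        shifted = traj.assign(measured_um=traj["measured_um"] + offset)
        assert bidirectional_systematic_error(shifted) == pytest.approx(
            bidirectional_systematic_error(traj)
        )
        assert estimate_backlash(shifted) == pytest.approx(estimate_backlash(traj))


class TestBacklashEstimation:
    def test_ideal_stage_zero_backlash(self):
        cfg = StageSimConfig(true_backlash_pos_neg_um=0.0, true_backlash_neg_pos_um=0.0)
        traj = gen_stage_trajectory(cfg, make_sawtooth(20, 1.0, 3))
        assert np.allclose(traj["measured_um"], traj["target_um"])
        b_pn, b_np = estimate_backlash(traj)
        assert b_pn == pytest.approx(0.0) and b_np == pytest.approx(0.0)

    def test_noiseless_recovery_is_exact(self):
        cfg = StageSimConfig()  # 3.7 / 3.1 um defaults
        traj = gen_stage_trajectory(cfg, make_sawtooth(20, 1.0, 3))
        b_pn, b_np = estimate_backlash(traj)
        assert b_pn == pytest.approx(3.7, abs=1e-12)
        assert b_np == pytest.approx(3.1, abs=1e-12)

    @pytest.mark.parametrize("backlash", [1.0, 3.1, 3.7])
    def test_noisy_recovery_within_tolerance(self, backlash):
        cfg = StageSimConfig(
            true_backlash_pos_neg_um=backlash,
            true_backlash_neg_pos_um=backlash,
            step_noise_sd_nm=50.0,
            seed=12,
        )
        traj = gen_stage_trajectory(cfg, make_sawtooth(100, 1.0, 3))
        b_pn, b_np = estimate_backlash(traj)
        assert b_pn == pytest.approx(backlash, abs=0.1)
        assert b_np == pytest.approx(backlash, abs=0.1)

    def test_no_common_positions_rejected(self):
        traj = traj_from_deviations({(1, "+"): 0.0, (2, "-"): 0.0})
        with pytest.raises(ValueError):
            estimate_backlash(traj)


class TestOvershoot:
    @pytest.mark.parametrize(
        "b, step_nm, expected",
        [(0.0, 21.1, 0), (3.7, 21.1, 175), (3.1, 18.9, 164)],
    )
    def test_plan_rounding(self, b, step_nm, expected):
        plan = plan_overshoot(b, b, step_pos_to_neg_nm=step_nm, step_neg_to_pos_nm=step_nm)
        assert plan.steps_pos_to_neg == expected

    def test_plan_rejects_nonpositive_step(self):
        with pytest.raises(ValueError):
            plan_overshoot(3.7, 3.1, step_pos_to_neg_nm=0.0)

    def test_monotone_commands_unchanged(self):
        plan = plan_overshoot(3.7, 3.1)
        targets = np.arange(1.0, 11.0)
        assert np.allclose(apply_overshoot(targets, plan), targets)

    def test_zero_overshoot_is_identity(self):
        plan = plan_overshoot(0.0, 0.0)
        cmd = make_sawtooth(10, 1.0, 2)
        corrected = apply_overshoot(cmd["target_um"].to_numpy(), plan)
        assert np.allclose(corrected, cmd["target_um"])

    def test_correction_reduces_e_to_one_step_noiseless(self):
        cfg = StageSimConfig()
        cmd = make_sawtooth(20, 1.0, 3)
        uncorrected = gen_stage_trajectory(cfg, cmd)
        b_pn, b_np = estimate_backlash(uncorrected)
        plan = plan_overshoot(b_pn, b_np, cfg.nominal_step_pos_nm, cfg.nominal_step_neg_nm)
        corrected_cmd = cmd.assign(
            commanded_um=apply_overshoot(cmd["target_um"].to_numpy(), plan)
        )
        corrected = gen_stage_trajectory(cfg, corrected_cmd)
        e_before = bidirectional_systematic_error(uncorrected)
        e_after = bidirectional_systematic_error(corrected)
        assert e_before >= 0.5 * cfg.true_backlash_pos_neg_um
        assert e_after <= cfg.nominal_step_pos_nm * 1e-3


class TestAccuracyAndUncertainty:
    def test_perfect_stage_zero_accuracy(self):
        traj = traj_from_deviations({(i, d): [0, 0] for i in (1, 2) for d in "+-"})
        assert positioning_accuracy(traj) == pytest.approx(0.0)

    def test_zero_sigma_degenerates_to_e(self):
        traj = traj_from_deviations({(1, "+"): 0.3, (2, "+"): -0.2, (1, "-"): 0.5, (2, "-"): 0.1})
        assert positioning_accuracy(traj) == pytest.approx(
            bidirectional_systematic_error(traj)
        )

    def test_hand_arithmetic_with_k2(self):
        traj = traj_from_deviations(
            {
                (1, "+"): [-0.25, 0.0, 0.25],  # mean 0, sd 0.25
                (2, "-"): [0.75, 1.0, 1.25],  # mean 1, sd 0.25
            }
        )
        assert positioning_accuracy(traj, k=2.0) == pytest.approx(2.0)

    def test_a_never_below_e(self):
        cfg = StageSimConfig(step_noise_sd_nm=80.0, seed=5)
        traj = gen_stage_trajectory(cfg, make_sawtooth(20, 1.0, 3))
        assert positioning_accuracy(traj) >= bidirectional_systematic_error(traj)

    @pytest.mark.parametrize(
        "e, e_r, expected", [(0.5, 0.4, 0.9), (0.0, 0.0, 0.0), (1.0, 0.0, 1.0)]
    )
    def test_total_uncertainty_is_the_sum(self, e, e_r, expected):
        assert total_uncertainty(e, e_r) == pytest.approx(expected)

    def test_total_uncertainty_rejects_negative(self):
        with pytest.raises(ValueError):
            total_uncertainty(-0.1, 0.2)

    def test_random_error_of_perfect_stage_is_zero(self):
        traj = traj_from_deviations({(1, "+"): [0, 0], (1, "-"): [0, 0]})
        assert random_error(traj) == pytest.approx(0.0)
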