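"""Push-pull rule: update directions, fixed point, closed-loop behaviour."""

import numpy as np
import pytest

from nmjhomeo.plasticity import (
    BurstSchedule,
    PlasticityRule,
    Synapse,
    calibrate_rule,
    default_cell,
    default_synapse,
    drive_curve,
    find_drive_zero,
    run_closed_loop,
    update_release,
)


class TestUpdateRelease:
    def test_zero_drives_leave_release_unchanged(self, rule):
        syn = Synapse(release_scale=1.0)
        assert update_release(syn, rule, 0.0, 0.0).release_scale == 1.0

    def test_nicotinic_drive_potentiates(self, rule):
        syn = Synapse(release_scale=1.0)
        assert update_release(syn, rule, 1.0, 0.0).release_scale > 1.0

    def test_dicr_drive_depresses(self, rule):
        syn = Synapse(release_scale=1.0)
        assert update_release(syn, rule, 0.0, 1.0).release_scale < 1.0

    def test_release_respects_bounds(self):
        rule = PlasticityRule(k_pot=10.0, k_dep=10.0, r_min=0.5, r_max=2.0, max_step=50.0)
        syn = Synapse(release_scale=1.0)
        assert update_release(syn, rule, 100.0, 0.0).release_scale == 2.0
        assert update_release(syn, rule, 0.0, 100.0).release_scale == 0.5

    def test_negative_integrals_rejected(self, rule):
        with pytest.raises(ValueError):
            update_release(Synapse(), rule, -1.0, 0.0)


class TestFixedPoint:
    def test_drive_sign_pattern_around_set_point(self, cell, rule):
        # the central stability property: positive below, ~zero at, negative
        # above the set point, with a negative slope at the crossing
        ratios = np.array([1.0, 1.8, 2.36, 3.0, 4.0])
        drives = drive_curve(ratios, cell=cell, rule=rule)
        assert drives[0] > 0 and drives[1] > 0
        assert abs(drives[2]) < 0.05 * drives[0]
        assert drives[3] < 0 and drives[4] < 0
        assert drives[3] - drives[1] < 0

    def test_bisection_zero_lands_on_set_point(self, cell, rule):
        assert find_drive_zero(rule, cell=cell) == pytest.approx(2.36, abs=0.01)

    def test_calibration_is_deterministic(self, cell):
        a = calibrate_rule(cell=cell)
        b = calibrate_rule(cell=cell)
        assert a.k_pot == b.k_pot and a.k_dep == b.k_dep


class TestClosedLoop:
    def test_stable_at_set_point_under_chronic_bursts(self, cell, rule):
        syn = default_synapse(cell)  # at the set point
        sched = BurstSchedule(n_bursts=10, pulses_per_burst=10)
        rec = run_closed_loop(cell, syn, rule, sched, seed=1)
        R = rec.release_trajectory[0]
        assert abs(R[-1] / R[0] - 1) < 0.05
        assert np.all(rec.gain_per_burst == 1.0)

    def test_subthreshold_curare_events_potentiate_from_below(self, cell, rule, short_burst):
        syn = default_synapse(cell, ratio=1.2)
        syn = Synapse(**{**syn.__dict__, "curare_factor": 0.05})
        rec = run_closed_loop(cell, syn, rule, short_burst, seed=1)
        assert rec.ratio_after[0] > rec.ratio_before[0]
        assert np.all(rec.spikes_per_burst == 0)

    def test_ryanodine_potentiates_past_set_point_without_converging(self, cell, rule):
        from dataclasses import replace

        blocked = replace(cell, ryanodine_blocked=True)
        syn = default_synapse(cell)
        sched = BurstSchedule(n_bursts=6, pulses_per_burst=5)
        rec = run_closed_loop(blocked, syn, rule, sched, seed=1)
        R = rec.release_trajectory[0]
        assert np.all(np.diff(R) > 0)  # monotone growth, no settling
        assert rec.ratio_after[0] > 2.36

    def test_ltd_then_nerve_bursts_partially_recover(self, cell, rule):
        syn = default_synapse(cell)
        ltd = BurstSchedule(n_bursts=3, pulses_per_burst=5, drive="muscle")
        rec1 = run_closed_loop(cell, syn, rule, ltd, seed=1)
        depressed = rec1.final_synapses[0]
        assert depressed.release_scale < syn.release_scale
        recovery = BurstSchedule(n_bursts=5, pulses_per_burst=40, drive="nerve")
        rec2 = run_closed_loop(cell, depressed, rule, recovery, seed=2)
        recovered = rec2.final_synapses[0]
        assert recovered.release_scale > depressed.release_scale

    def test_presynaptic_locus_spsc_amplitude_invariant(self, cell, rule, short_burst):
        # plasticity moves the release scale only: quantal amplitude fixed,
        # spontaneous rate proportional to R
        syn = default_synapse(cell, ratio=1.0)
        sub = Synapse(**{**syn.__dict__, "curare_factor": 0.05})
        rec = run_closed_loop(cell, sub, rule, short_burst, seed=1)
        after = rec.final_synapses[0]
        assert after.release_scale > sub.release_scale * 1.3
        assert after.spsc_amplitude == pytest.approx(sub.spsc_amplitude, rel=1e-12)
        assert after.spsc_rate / sub.spsc_rate == pytest.approx(
            after.release_scale / sub.release_scale, rel=1e-12
        )

    def test_record_is_deterministic_given_seed(self, cell, rule, short_burst):
        syn = default_synapse(cell)
        a = run_closed_loop(cell, syn, rule, short_burst, seed=9)
        b = run_closed_loop(cell, syn, rule, short_burst, seed=9)
        assert np.array_equal(a.ratio_before, b.ratio_before)
        assert np.array_equal(a.release_trajectory, b.release_trajectory)
        assert np.array_equal(a.ratio_after, b.ratio_after)


def test_calibrated_rule_meets_fast_ltp_contract(cell, rule, short_burst):
    # three 5-pulse subthreshold bursts potentiate release >= 1.5x
    syn = default_synapse(cell)
    sub = Synapse(**{**syn.__dict__, "curare_factor": 0.05})
    rec = run_closed_loop(cell, sub, rule, short_burst, seed=0)
    R = rec.release_trajectory[0]
    assert R[-1] / R[0] >= 1.5
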