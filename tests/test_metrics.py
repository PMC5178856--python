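"""Metrics layer against analytic synthetic traces."""

import math

import numpy as np
import pytest

from ordcamk.cli_io import fixture_apd90, make_fixture_trace
from ordcamk.metrics import (apd90, classify_ead_pattern, detect_eads,
                             inal_deactivation_time, measure_beat,
                             peak_amplitude)


class TestApd90:
    def test_trapezoid_has_analytic_apd90(self):
        tr = make_fixture_trace("clean")
        a, failed = apd90(tr)
        assert not failed
        assert a == pytest.approx(fixture_apd90(), abs=0.2)

    def test_invariant_under_grid_refinement(self):
        params = {"plateau_end": 180.0, "repol_end": 340.0}
        coarse = make_fixture_trace("clean", {**params, "sample_dt": 0.5})
        fine = make_fixture_trace("clean", {**params, "sample_dt": 0.05})
        a_c, _ = apd90(coarse)
        a_f, _ = apd90(fine)
        assert abs(a_c - a_f) < 0.1

    def test_repolarization_failure_flagged(self):
        tr = make_fixture_trace("clean", {"repol_end": 5000.0,
                                          "cycle_length": 1000.0})
        a, failed = apd90(tr)
        assert failed
        assert a == pytest.approx(tr.t[-1], abs=2.0)


class TestDetectEads:
    def test_clean_beat_has_no_events(self):
        count, _ = detect_eads(make_fixture_trace("clean"))
        assert count == 0

    def test_single_injected_hump_counts_once(self):
        count, times = detect_eads(make_fixture_trace("one_ead"))
        assert count == 1
        assert len(times) == 1
        # the event onset lies near the carved dip before the hump
        assert 80.0 < times[0] < 160.0

    def test_noise_below_half_prominence_is_ignored(self):
        """Bounded noise of amplitude < delta_v/2 never changes the count
        (hysteresis robustness)."""
        for kind, expected in (("clean", 0), ("one_ead", 1)):
            for seed in range(5):
                tr = make_fixture_trace(kind, {"noise_sd": 0.4}, seed=seed)
                count, _ = detect_eads(tr)
                assert count == expected

    def test_events_below_voltage_threshold_not_counted(self):
        # place the hump after V has fallen below -40 mV
        tr = make_fixture_trace("one_ead", {"hump_t": 400.0,
                                            "repol_end": 320.0})
        count, _ = detect_eads(tr)
        assert count == 0


class TestClassifyEadPattern:
    @pytest.mark.parametrize("counts,expected", [
        ([0, 0, 0, 0], "none"),
        ([1, 0, 1, 0], "alternating"),
        ([0, 1, 0, 1], "alternating"),
        ([1, 1, 1, 1], "stable"),
        ([2, 1, 2, 1], "stable"),
        ([1, 1, 0, 0], "indeterminate"),
    ])
    def test_patterns(self, counts, expected):
        assert classify_ead_pattern(counts) == expected

    @pytest.mark.parametrize("counts", [
        [0, 0, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1]])
    def test_reversal_invariance(self, counts):
        assert (classify_ead_pattern(counts[::-1])
                == classify_ead_pattern(counts))

    def test_too_few_beats(self):
        with pytest.raises(ValueError):
            classify_ead_pattern([1, 0])


class TestPeaksAndDeactivation:
    def test_constant_zero_current_has_zero_peak(self):
        tr = make_fixture_trace("clean")
        assert peak_amplitude(tr, "ICaL") == 0.0

    def test_inward_peak_magnitude(self):
        tr = make_fixture_trace("exp_decay")
        assert peak_amplitude(tr, "INaL") == pytest.approx(0.25, rel=1e-6)

    def test_exponential_decay_closed_form(self):
        lam = 0.004
        tr = make_fixture_trace("exp_decay", {"decay_rate": lam,
                                              "cycle_length": 2000.0})
        d, flagged = inal_deactivation_time(tr, 0.05)
        assert not flagged
        assert d == pytest.approx(math.log(20.0) / lam, abs=0.2)

    def test_no_crossing_flagged(self):
        tr = make_fixture_trace("exp_decay", {"decay_rate": 1e-5})
        d, flagged = inal_deactivation_time(tr, 0.05)
        assert flagged

    def test_unknown_current_rejected(self):
        tr = make_fixture_trace("clean")
        with pytest.raises(KeyError):
            peak_amplitude(tr, "IKachR")


def test_measure_beat_bundles_everything():
    tr = make_fixture_trace("one_ead")
    m = measure_beat(tr)
    assert m.ead_count == 1
    assert m.apd90 < 1000.0
    assert m.peak_amplitudes["INaL"] > 0.0
    assert m.camk_active_max == 0.0  # fixture carries no CaMKII signal


def test_model_alternans_metrics(sim):
    """CaMKII overexpression on I_NaL at CL 2000 ms with 85 % I_Kr block:
    EADs appear on alternate beats only, and the late-Na current of EAD
    beats deactivates far more slowly than on the intervening beats."""
    res = sim.run(cycle_length=2000.0, ikr_block=0.85, overexpressed="INaL")
    beats = [measure_beat(tr) for tr in res.traces]
    counts = [b.ead_count for b in beats]
    assert classify_ead_pattern(counts) == "alternating"
    ead = [b for b in beats if b.ead_count > 0]
    normal = [b for b in beats if b.ead_count == 0]
    ratio = (np.mean([b.inal_deactivation_time for b in ead])
             / np.mean([b.inal_deactivation_time for b in normal]))
    assert 1.4 < ratio < 2.0
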