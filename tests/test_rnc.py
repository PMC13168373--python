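from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectqc.rnc import (LU177_HALF_LIFE_DAYS, RNCReading, RNCSession,
                         UncertaintyBudget, UncertaintyComponent,
                         combine_uncertainty, corrected_dial, decay_correct,
                         dial_response_ratio, geometry_correction_factor,
                         read_session_csv, summarize_session,
                         write_session_csv)
from spectqc.simulate import RNCModel, simulate_rnc_session

T0 = datetime(2024, 1, 1, 8, 0, 0)


class TestDecayCorrection:
    def test_identity_at_reference_time(self):
        assert decay_correct(100.0, T0, T0) == 100.0

    def test_one_half_life_doubles(self):
        t = T0 + timedelta(days=LU177_HALF_LIFE_DAYS)
        assert decay_correct(100.0, t, T0) == pytest.approx(200.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-30, max_value=30),
           st.floats(min_value=0.1, max_value=100))
    def test_round_trip_is_identity(self, dt_days, half_life):
        t = T0 + timedelta(days=dt_days)
        there = decay_correct(100.0, t, T0, half_life)
        back = decay_correct(there, T0, t, half_life)
        assert back == pytest.approx(100.0, rel=1e-12)


class TestSummarizeSession:
    def test_pure_bias_recovered_exactly(self):
        session = simulate_rnc_session(
            RNCModel(true_activity_at_ref=291.0, bias=0.05, jitter_sd=0.0))
        s = summarize_session(session, 291.0)
        assert s.deviation_pct == pytest.approx(5.00, abs=1e-9)
        assert s.n == 9

    def test_jitter_regime_sd(self):
        sds = []
        for seed in range(20):
            session = simulate_rnc_session(
                RNCModel(true_activity_at_ref=291.0, jitter_sd=0.004,
                         seed=seed))
            sds.append(summarize_session(session, 291.0).sd_pct)
        assert np.mean(sds) == pytest.approx(0.4, rel=0.35)

    def test_background_equal_to_raw_gives_minus_100(self):
        readings = [RNCReading(T0, 5.0, background=5.0)]
        session = RNCSession(readings=readings, ref_time=T0)
        s = summarize_session(session, 10.0)
        assert s.deviation_pct == -100.0
        assert s.sd_pct is None  # single reading: SD undefined

    def test_invariant_to_reading_order_and_time_shift(self):
        session = simulate_rnc_session(
            RNCModel(true_activity_at_ref=158.0, bias=-0.02, jitter_sd=0.003,
                     seed=4))
        base = summarize_session(session, 158.0)
        rev = RNCSession(readings=list(reversed(session.readings)),
                         ref_time=session.ref_time)
        assert summarize_session(rev, 158.0).deviation_pct \
            == pytest.approx(base.deviation_pct)
        shift = timedelta(days=3)
        moved = RNCSession(
            readings=[RNCReading(r.timestamp + shift, r.raw_reading,
                                 r.background) for r in session.readings],
            ref_time=session.ref_time + shift)
        assert summarize_session(moved, 158.0).deviation_pct \
            == pytest.approx(base.deviation_pct, abs=1e-9)

    def test_csv_round_trip(self, tmp_path):
        session = simulate_rnc_session(
            RNCModel(true_activity_at_ref=291.0, bias=0.01, seed=2),
            protocol="clinical", chamber_model="vik202", dial_setting=751,
            vial_geometry="ref_vial")
        path = tmp_path / "session.csv"
        write_session_csv(session, path)
        back = read_session_csv(path)
        assert back.dial_setting == 751
        assert back.chamber_model == "vik202"
        assert summarize_session(back, 291.0).deviation_pct == pytest.approx(
            summarize_session(session, 291.0).deviation_pct)


class TestCorrectedDial:
    def test_proportional_chamber_examples(self):
        assert corrected_dial(751, +0.0093, "vik202") == 744
        assert corrected_dial(751, -0.0093, "vik202") == 758

    def test_zero_deviation_leaves_dial(self):
        for model in ("vik202", "crc55tr"):
            assert corrected_dial(456, 0.0, model) == 456

    def test_inverse_chamber_moves_opposite_way(self):
        assert corrected_dial(456, -0.01, "crc55tr") < 456
        assert corrected_dial(456, +0.01, "crc55tr") > 456

    def test_generic_requires_sensitivity(self):
        with pytest.raises(ValueError, match="sensitivity"):
            corrected_dial(500, 0.01, "generic")

    @pytest.mark.parametrize("chamber, dial", [("vik202", 751),
                                               ("crc55tr", 456)])
    @pytest.mark.parametrize("bias", [-0.10, -0.05, -0.01, 0.02, 0.05, 0.10])
    def test_one_step_closure(self, chamber, dial, bias):
        """A single dial correction nulls any +/-10% bias to within the
        integer-dial granularity (< 0.1%)."""
        session = simulate_rnc_session(
            RNCModel(true_activity_at_ref=291.0, bias=bias, jitter_sd=0.0),
            chamber_model=chamber, dial_setting=dial)
        dev = summarize_session(session, 291.0).deviation_pct / 100.0
        new_dial = corrected_dial(dial, dev, chamber)
        residual = (1 + bias) * dial_response_ratio(chamber, dial, new_dial) - 1
        assert abs(residual) < 0.001

    def test_bias_recovery_within_sampling_error(self):
        """Injected bias recovered within 3 jitter/sqrt(n) on average."""
        bias, jitter, n = 0.03, 0.004, 9
        devs = [summarize_session(
            simulate_rnc_session(RNCModel(true_activity_at_ref=100.0,
                                          bias=bias, jitter_sd=jitter,
                                          n_readings=n, seed=s)),
            100.0).deviation_pct / 100.0 for s in range(100)]
        assert abs(np.mean(devs) - bias) < 3 * jitter / np.sqrt(n)


class TestGeometryCorrection:
    def _sessions(self, rel_response, seed=0):
        ref = simulate_rnc_session(
            RNCModel(true_activity_at_ref=291.0, bias=0.01, jitter_sd=0.0),
            chamber_model="vik202", dial_setting=751, vial_geometry="ref")
        clin = simulate_rnc_session(
            RNCModel(true_activity_at_ref=158.0,
                     bias=(1.01) * (1 + rel_response) - 1, jitter_sd=0.0),
            chamber_model="vik202", dial_setting=751, vial_geometry="clin")
        return ref, clin

    def test_identical_geometry_gives_unity(self):
        ref, clin = self._sessions(0.0)
        assert geometry_correction_factor(ref, clin, 291.0, 158.0) \
            == pytest.approx(1.000, abs=1e-9)

    def test_lower_clinical_response(self):
        ref, clin = self._sessions(-0.006)
        assert geometry_correction_factor(ref, clin, 291.0, 158.0) \
            == pytest.approx(0.994, abs=1e-6)

    def test_invariant_to_activity_level(self):
        ref, clin = self._sessions(-0.006)
        f1 = geometry_correction_factor(ref, clin, 291.0, 158.0)
        ref2 = simulate_rnc_session(
            RNCModel(true_activity_at_ref=66.0, bias=0.01, jitter_sd=0.0),
            chamber_model="vik202", dial_setting=751)
        clin2 = simulate_rnc_session(
            RNCModel(true_activity_at_ref=35.0,
                     bias=1.01 * 0.994 - 1, jitter_sd=0.0),
            chamber_model="vik202", dial_setting=751)
        assert geometry_correction_factor(ref2, clin2, 66.0, 35.0) \
            == pytest.approx(f1, abs=1e-9)

    def test_mismatched_chamber_rejected(self):
        ref, clin = self._sessions(0.0)
        clin.chamber_model = "crc55tr"
        with pytest.raises(ValueError, match="share"):
            geometry_correction_factor(ref, clin, 291.0, 158.0)


class TestUncertaintyBudget:
    def test_single_k2_component_round_trips(self):
        budget = UncertaintyBudget(
            (UncertaintyComponent("reference activity", 2.8, "normal_k2"),),
            k=2.0)
        assert combine_uncertainty(budget) == pytest.approx(2.8)

    def test_three_four_five_quadrature(self):
        budget = UncertaintyBudget(
            (UncertaintyComponent("a", 3.0), UncertaintyComponent("b", 4.0)),
            k=1.0)
        assert combine_uncertainty(budget) == pytest.approx(5.0)

    def test_mixed_distribution_budget(self):
        """Vial-activity term at k=2 plus a rectangular dilution term."""
        budget = UncertaintyBudget(
            (UncertaintyComponent("vial activity", 3.3, "normal_k2"),
             UncertaintyComponent("sphere dilution", 2.0,
                                  "rectangular_halfwidth")), k=2.0)
        assert combine_uncertainty(budget) == pytest.approx(4.03, abs=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(
        st.floats(min_value=0, max_value=10),
        st.sampled_from(["normal_k1", "normal_k2", "rectangular_halfwidth"])),
        min_size=1, max_size=6),
        st.integers(min_value=0, max_value=5),
        st.floats(min_value=0.01, max_value=5))
    def test_monotone_and_permutation_invariant(self, comps, idx, bump):
        components = tuple(UncertaintyComponent(f"c{i}", m, d)
                           for i, (m, d) in enumerate(comps))
        budget = UncertaintyBudget(components, k=2.0)
        base = combine_uncertainty(budget)
        perm = UncertaintyBudget(components[::-1], k=2.0)
        assert combine_uncertainty(perm) == pytest.approx(base)
        i = idx % len(components)
        bumped = list(components)
        bumped[i] = UncertaintyComponent("x", components[i].magnitude + bump,
                                         components[i].distribution)
        assert combine_uncertainty(UncertaintyBudget(tuple(bumped), k=2.0)) \
            >= base
        assert base >= 2.0 * max(c.standard for c in components) - 1e-12
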