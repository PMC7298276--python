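"""Scenario engine: built-in chronologies, quasi-static tracings, zone
summaries, path independence, reconstitution and LED brightness classes."""

from fractions import Fraction

import numpy as np
import pytest

from splanchsim import (FlowTrace, ModelState, PiecewiseLinearSignal,
                        Scenario, SplanchnicParameters, Zone,
                        builtin_scenario, classify_brightness,
                        combined_scenario, detect_reconstitution,
                        run_scenario, scenario_equivalence, steady_flows,
                        summarize)
from test_model import exact_divider


@pytest.fixture(scope="module")
def traces():
    params = SplanchnicParameters()
    out = {}
    for which in (1, 2):
        sc = builtin_scenario(which)
        out[which] = (sc, run_scenario(sc, params))
    return out


class TestSignals:
    def test_interpolation_and_holds(self):
        sig = PiecewiseLinearSignal([(1.0, 0.0), (2.0, 50000.0)])
        assert sig.value(1.5) == 25000.0
        assert sig.value(0.0) == 0.0       # held before first breakpoint
        assert sig.value(10.0) == 50000.0  # held after last breakpoint

    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            PiecewiseLinearSignal([(0.0, 0.0), (0.0, 1.0)])

    def test_zone_tiling_enforced(self):
        sig = PiecewiseLinearSignal([(0.0, 0.0)])
        with pytest.raises(ValueError, match="tile"):
            Scenario("bad", 2.0, sig, sig,
                     zones=(Zone(0, 1, "normal"), Zone(1.5, 2, "postop")))

    def test_unknown_zone_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            Zone(0, 1, "miracle")


class TestBuiltinScenarios:
    def test_both_start_at_normal_state(self):
        for which in (1, 2):
            st = builtin_scenario(which).state_at(0.5)
            assert (st.r_stenosis, st.r_aneurysm) == (0.0, 50000.0)

    def test_scenario1_preop_zone_state(self):
        st = builtin_scenario(1).state_at(4.5)
        assert (st.r_stenosis, st.r_aneurysm) == (50000.0, 0.0)

    def test_scenario2_aneurysm_only_zone_state(self):
        st = builtin_scenario(2).state_at(2.5)
        assert (st.r_stenosis, st.r_aneurysm) == (0.0, 0.0)

    def test_combined_timeline_offsets_scenario2(self):
        sc = combined_scenario()
        assert sc.duration == 14.0
        st = sc.state_at(9.5)  # scenario 2's aneurysm-only zone
        assert (st.r_stenosis, st.r_aneurysm) == (0.0, 0.0)
        assert sc.zone_at(9.5).label == "aneurysm_only"
        assert sc.zone_at(13.5).label == "postop"

    def test_invalid_selector(self):
        with pytest.raises(ValueError):
            builtin_scenario(3)

    def test_json_round_trip(self):
        sc = builtin_scenario(1)
        again = Scenario.from_dict(sc.to_dict())
        assert again == sc


class TestRunScenario:
    def test_normal_zone_flow(self, traces):
        _, trace = traces[1]
        assert round(trace.at(0.5).i_ca, 3) == 0.427

    def test_postop_reconstituted_flow(self, traces):
        _, trace = traces[1]
        fp = trace.at(6.5)
        assert round(fp.i_ca, 3) == 0.044  # 44 mL/min, not 0: reconstitution
        assert round(fp.i_pda, 3) == 0.760

    def test_ramp_midpoint_matches_exact_divider(self, traces):
        # t = 1.5 s in scenario 1: r_s = 25 kΩ (mid-ramp), r_a = 50 kΩ
        _, trace = traces[1]
        e_ca, _ = exact_divider(25000, 50000)
        fp = trace.at(1.5)
        assert fp.i_ca == pytest.approx(float(e_ca), abs=1e-12)
        assert round(fp.i_ca, 4) == 0.0800

    def test_trace_matches_scalar_oracle_on_subsample(self, traces):
        params = SplanchnicParameters()
        _, trace = traces[2]
        for k in range(0, len(trace.times), 500):
            st = ModelState(float(trace.r_stenosis[k]),
                            float(trace.r_aneurysm[k]))
            fp = steady_flows(params, st)
            assert trace.i_ca[k] == pytest.approx(fp.i_ca, abs=1e-9)
            assert trace.i_pda[k] == pytest.approx(fp.i_pda, abs=1e-9)
            total = trace.i_ca[k] + trace.i_pda[k]
            assert total == pytest.approx(fp.i_total, abs=1e-9)

    def test_zone_steadiness_in_hold_zones(self, traces):
        for which in (1, 2):
            sc, trace = traces[which]
            for z in sc.zones:
                if z.label == "transition":
                    continue
                mask = (trace.times >= z.start) & (trace.times < z.end)
                ref = trace.at(z.midpoint)
                assert np.max(np.abs(trace.i_ca[mask] - ref.i_ca)) < 1e-9
                assert np.max(np.abs(trace.i_pda[mask] - ref.i_pda)) < 1e-9

    def test_mirror_image_slopes(self, traces):
        """CA and PDA tracings move in opposite directions everywhere: the
        finite-difference slopes never share a sign (current divider)."""
        for which in (1, 2):
            _, trace = traces[which]
            d_ca = np.diff(trace.i_ca)
            d_pda = np.diff(trace.i_pda)
            assert np.all(d_ca * d_pda <= 1e-24)

    def test_dt_refinement_leaves_hold_zones_unchanged(self):
        sc = builtin_scenario(1)
        params = SplanchnicParameters()
        coarse = summarize(run_scenario(sc, params, dt=0.002), sc)
        fine = summarize(run_scenario(sc, params, dt=0.001), sc)
        for a, b in zip(coarse.zones, fine.zones):
            if a.label != "transition":
                assert a.i_ca_ma == pytest.approx(b.i_ca_ma, abs=1e-12)
                assert a.i_pda_ma == pytest.approx(b.i_pda_ma, abs=1e-12)

    def test_unit_converted_columns(self, traces):
        _, trace = traces[1]
        assert np.allclose(trace.q_ca, trace.i_ca * 1000.0)
        assert round(float(trace.q_ca[-1])) == 44  # postop, mL/min

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            run_scenario(builtin_scenario(1), dt=0.0)
        with pytest.raises(ValueError):
            run_scenario(builtin_scenario(1), dt=0.5)


class TestSummaries:
    def test_scenario1_zone_narrative(self, traces):
        sc, trace = traces[1]
        s = summarize(trace, sc)
        assert (round(s.zone("normal").i_ca_ma, 3),
                round(s.zone("normal").i_pda_ma, 3)) == (0.427, 0.455)
        assert (round(s.zone("preop").i_ca_ma, 3),
                round(s.zone("preop").i_pda_ma, 3)) == (0.000, 1.000)
        assert (round(s.zone("postop").i_ca_ma, 3),
                round(s.zone("postop").i_pda_ma, 3)) == (0.044, 0.760)
        assert s.steal_flag and s.reconstitution_flag

    def test_scenario2_steal_without_stenosis(self, traces):
        sc, trace = traces[2]
        s = summarize(trace, sc)
        z = s.zone("aneurysm_only")
        assert (round(z.i_ca_ma, 3), round(z.i_pda_ma, 3)) == (0.000, 1.000)
        assert (round(s.zone("postop").i_ca_ma, 3),
                round(s.zone("postop").i_pda_ma, 3)) == (0.044, 0.760)

    def test_builtin_scenarios_are_equivalent(self, traces):
        s1 = summarize(traces[1][1], traces[1][0])
        s2 = summarize(traces[2][1], traces[2][0])
        assert scenario_equivalence(s1, s2)
        assert scenario_equivalence(s1, s1)  # reflexivity

    def test_different_potentiometer_cap_breaks_equivalence(self, traces):
        s1 = summarize(traces[1][1], traces[1][0])
        small = SplanchnicParameters(pot_max=25000.0)
        sc = builtin_scenario(1, small)
        s_alt = summarize(run_scenario(sc, small), sc)
        assert not scenario_equivalence(s1, s_alt)

    def test_equivalence_requires_shared_labels(self, traces):
        s1 = summarize(traces[1][1], traces[1][0])
        sig = PiecewiseLinearSignal([(0.0, 0.0)])
        aneu = PiecewiseLinearSignal([(0.0, 50000.0)])
        sc = Scenario("flat", 1.0, sig, aneu, zones=(Zone(0, 1, "normal"),))
        bare = summarize(run_scenario(sc), sc)
        with pytest.raises(ValueError, match="preop"):
            scenario_equivalence(s1, bare)

    def test_all_normal_scenario_has_no_flags(self):
        sig = PiecewiseLinearSignal([(0.0, 0.0)])
        aneu = PiecewiseLinearSignal([(0.0, 50000.0)])
        sc = Scenario("flat", 2.0, sig, aneu,
                      zones=(Zone(0, 1, "normal"), Zone(1, 2, "normal")))
        s = summarize(run_scenario(sc), sc)
        assert not s.steal_flag and not s.reconstitution_flag
        for z in s.zones:
            assert round(z.i_ca_ma, 3) == 0.427

    def test_reconstitution_requires_residual_stenosis(self):
        # if the stenosis is ALSO corrected postop, flows return to normal
        # (postop == normal), which is restoration rather than the partial
        # reconstitution seen with the stenosis left in situ
        hi = 50000.0
        sten = PiecewiseLinearSignal([(0, 0), (1, 0), (2, hi), (4, hi),
                                      (5, 0), (7, 0)])
        aneu = PiecewiseLinearSignal([(0, hi), (2, hi), (3, 0), (4, 0),
                                      (5, hi), (7, hi)])
        zones = (Zone(0, 1, "normal"), Zone(1, 3, "transition"),
                 Zone(3, 4, "preop"), Zone(4, 5, "transition"),
                 Zone(5, 7, "postop"))
        sc = Scenario("corrected", 7.0, sten, aneu, zones=zones)
        s = summarize(run_scenario(sc), sc)
        assert s.zone("postop").i_ca_ma == pytest.approx(
            s.zone("normal").i_ca_ma, abs=1e-9)
        assert not detect_reconstitution(s)

    def test_summary_trace_mismatch_rejected(self, traces):
        sc14 = combined_scenario()
        _, trace7 = traces[1]
        with pytest.raises(ValueError, match="cover"):
            summarize(trace7, sc14)

    def test_summary_json_reporting_precision(self, traces):
        s = summarize(traces[1][1], traces[1][0])
        d = s.to_dict()
        postop = [z for z in d["zones"] if z["label"] == "postop"][0]
        assert postop["i_ca_mA"] == 0.044
        assert postop["q_ca_mL_min"] == 44


class TestCombinedTimeline:
    def test_matching_zones_across_scenarios(self):
        params = SplanchnicParameters()
        sc = combined_scenario(params)
        trace = run_scenario(sc, params)
        s = summarize(trace, sc)
        labels = [z.label for z in s.zones]
        assert labels.count("normal") == 2
        for label in ("normal", "preop", "postop"):
            pair = [z for z in s.zones if z.label == label]
            assert pair[0].i_ca_ma == pytest.approx(pair[1].i_ca_ma,
                                                    abs=1e-9)
            assert pair[0].i_pda_ma == pytest.approx(pair[1].i_pda_ma,
                                                     abs=1e-9)


class TestTraceCSV:
    def test_round_trip_at_stored_precision(self, tmp_path, traces):
        _, trace = traces[1]
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        again = FlowTrace.from_csv(path)
        assert len(again.times) == len(trace.times)
        assert again.zone == trace.zone
        # stored precision: 6 significant digits for currents
        assert np.allclose(again.i_ca, trace.i_ca, rtol=1e-5, atol=1e-9)
        # writing the reread trace reproduces the file byte-for-byte
        path2 = tmp_path / "trace2.csv"
        again.to_csv(path2)
        assert path.read_text() == path2.read_text()

    def test_header_contract(self, tmp_path, traces):
        _, trace = traces[1]
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == ("time_s,r_stenosis_ohm,r_aneurysm_ohm,"
                          "i_ca_mA,i_pda_mA,q_ca_mL_min,q_pda_mL_min,zone")


class TestBrightness:
    @pytest.mark.parametrize("i, i_norm, expected", [
        (0.000, 0.427, "off"),      # CA at total steal
        (0.044, 0.427, "dim"),      # CA reconstituted postop
        (0.427, 0.427, "normal"),
        (0.760, 0.455, "bright"),   # PDA with stenosis upstream
        (1.000, 0.455, "bright"),
    ])
    def test_classes(self, i, i_norm, expected):
        assert classify_brightness(i, i_norm) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_brightness(-0.1, 0.5)
        with pytest.raises(ValueError):
            classify_brightness(0.1, 0.0)
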