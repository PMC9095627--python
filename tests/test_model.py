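import numpy as np
import pytest

from persist import motifs
from persist.model import (CircuitSpec, ModelParams, OnMotif, Transcript,
                           cleavage_rate, deg_ladder, dose_response,
                           endpoint_many, find_fixed_points, simulate,
                           steady_state, transcript_output)


class TestCleavageRate:
    def test_zero_enzyme_gives_zero(self, registry, params):
        e = registry.enzyme("Csy4")
        assert cleavage_rate(0.0, e, "Csy4-site", registry.matrix, params) == 0.0

    def test_half_saturation(self, registry, params):
        e = registry.enzyme("Csy4")
        r = cleavage_rate(e.K, e, "Csy4-site", registry.matrix, params)
        assert r == pytest.approx(e.vmax_rel * params.vmax / 2)

    def test_partial_activity_at_ten_k(self, registry):
        # activity 0.5, vmax 2/h, E = 10K: 0.5 * 2 * 10/11 = 0.909/h
        from persist.registry import (CrossReactivityMatrix, EndoRNase, Family,
                                      RecognitionSite, Registry)
        p = ModelParams(vmax=2.0)
        e1 = EndoRNase("E1", Family.CAS6, 1.0, 100.0)
        e2 = EndoRNase("E2", Family.CAS6, 1.0, 100.0)
        reg = Registry([e1, e2],
                       [RecognitionSite("s1", "E1"), RecognitionSite("s2", "E2")],
                       CrossReactivityMatrix({("E1", "s1"): 1.0, ("E1", "s2"): 0.5,
                                              ("E2", "s1"): 0.0, ("E2", "s2"): 1.0}))
        r = cleavage_rate(1000.0, e1, "s2", reg.matrix, p)
        assert r == pytest.approx(0.909, abs=1e-3)

    def test_negative_level_rejected(self, registry, params):
        with pytest.raises(ValueError):
            cleavage_rate(-1.0, registry.enzyme("Csy4"), "Csy4-site",
                          registry.matrix, params)

    def test_monotone_and_saturating(self, registry, params):
        e = registry.enzyme("Csy4")
        levels = np.geomspace(1, 1e7, 30)
        rates = [cleavage_rate(E, e, "Csy4-site", registry.matrix, params)
                 for E in levels]
        assert np.all(np.diff(rates) > 0)
        assert rates[-1] < e.vmax_rel * params.vmax


class TestTranscriptOutput:
    def test_plain_reporter_closed_form(self, registry, params):
        t = Transcript(name="r", payload="EYFP", alpha=2.0)
        flux = transcript_output(t, {}, params, copies=50.0, registry=registry)
        assert flux == pytest.approx(params.kp * 2.0 * 50.0 / params.d0)

    def test_off_reporter_saturating_fold(self, registry, params):
        t = Transcript(name="r", payload="EYFP", five_prime_sites=("Csy4-site",))
        e = registry.enzyme("Csy4")
        lo = transcript_output(t, {"Csy4": 0.0}, params, 10.0, registry)
        hi = transcript_output(t, {"Csy4": 1e9}, params, 10.0, registry)
        expected = (params.d0 + e.vmax_rel * params.vmax * 1e9 / (e.K + 1e9)) / params.d0
        assert lo / hi == pytest.approx(expected, rel=1e-9)

    def test_on_reporter_fold_matches_closed_form(self, registry, params):
        t = Transcript(name="r", payload="EYFP",
                       on_motif=OnMotif(sites=("Csy4-site",), deg_repeats=30))
        e = registry.enzyme("Csy4")
        E = 1e8
        k = e.vmax_rel * params.vmax * E / (e.K + E)
        D = params.d0 + params.d_fast(30)
        lo = transcript_output(t, {"Csy4": 0.0}, params, 10.0, registry)
        hi = transcript_output(t, {"Csy4": E}, params, 10.0, registry)
        expected = (D / (D + k)) * (1.0 + k / params.d_slow)
        assert hi / lo == pytest.approx(expected, rel=1e-9)


class TestSimulateAgainstClosedForm:
    """ODE endpoints must match analytic steady states on acyclic circuits."""

    @pytest.mark.parametrize("builder,kwargs", [
        (motifs.plain_reporter, {}),
        (motifs.off_reporter, {"enzyme": "Csy4", "enzyme_copies": 30.0}),
        (motifs.on_reporter, {"enzyme": "CasE", "enzyme_copies": 100.0}),
        (motifs.repression_cascade, {"upstream_copies": 50.0}),
        (motifs.activation_cascade, {"upstream_copies": 50.0}),
        (motifs.cffl, {"input_copies": 20.0}),
    ])
    def test_endpoint_matches_steady_state(self, registry, params, builder, kwargs):
        circuit = builder(registry, **kwargs)
        ss = steady_state(circuit, params)
        _, states = simulate(circuit, params, t_end=3000.0)
        for payload, level in ss.proteins.items():
            if level > 0:
                assert states[-1].proteins[payload] == pytest.approx(level, rel=1e-6)

    def test_vectorized_endpoint_matches_steady_state(self, registry, params):
        circuit = motifs.repression_cascade(registry)
        copies = {"reporter": np.array([100.0, 50.0]),
                  "intermediate": np.array([25.0, 10.0]),
                  "input": np.array([0.0, 80.0])}
        levels = endpoint_many(circuit, copies, params)
        for i in range(2):
            ss = steady_state(
                circuit.with_copies(reporter=copies["reporter"][i],
                                    intermediate=copies["intermediate"][i],
                                    input=copies["input"][i]), params)
            assert levels["EYFP"][i] == pytest.approx(ss.proteins["EYFP"], rel=1e-6)


class TestCircuitBehaviors:
    def test_repression_cascade_restores_reporter(self, registry, params):
        # more upstream enzyme -> less intermediate -> more reporter
        circuit = motifs.repression_cascade(registry)
        curve = dose_response(circuit, "input", np.geomspace(0.1, 300, 12),
                              params, output_payload="EYFP")
        assert np.all(np.diff(curve["output"]) > 0)

    def test_auto_positive_feedback_beats_no_site_control(self, registry, params):
        for c in (5.0, 20.0, 100.0):
            with_site = motifs.auto_positive_feedback(registry, copies=c)
            no_site = motifs.auto_positive_feedback(registry, copies=c,
                                                    with_site=False)
            _, s1 = simulate(with_site, params)
            _, s0 = simulate(no_site, params)
            assert s1[-1].proteins["CasE"] >= s0[-1].proteins["CasE"]

    def test_off_dose_response_nonincreasing(self, registry, params):
        circuit = motifs.off_reporter(registry, "Csy4")
        curve = dose_response(circuit, "enzyme", np.geomspace(0.01, 1000, 15),
                              params, output_payload="EYFP")
        assert np.all(np.diff(curve["output"]) < 0)

    def test_flat_curve_without_active_enzyme(self, registry, params):
        # sweeping an enzyme with zero activity on the reporter's site
        circuit = motifs.off_reporter(registry, "Csy4")
        t = [t for t in circuit.transcripts if t.name == "enzyme"]
        other = Transcript(name="other", payload="RfxCas13d")
        circuit = CircuitSpec(circuit.transcripts + [other],
                              {**circuit.copies, "other": 0.0}, registry)
        curve = dose_response(circuit, "other", [0.0, 10.0, 1000.0], params,
                              output_payload="EYFP")
        assert np.ptp(curve["output"]) == pytest.approx(0.0, abs=1e-9)

    def test_cffl_fold_exceeds_on_switch_alone(self, cfg):
        from persist.experiments import cffl_sweep

        sweep = cffl_sweep(cfg, intermediate_copies=(0.0, 20.0))
        alone = sweep.loc[sweep.intermediate_copies == 0, "dynamic_range"].iloc[0]
        with_ffl = sweep.loc[sweep.intermediate_copies == 20, "dynamic_range"].iloc[0]
        assert with_ffl > alone

    def test_fold_invariant_to_joint_alpha_kp_rescale(self, registry, params):
        # reporter-output folds are a unit-free statistic: rescaling the
        # transcription and translation of the reporter (its absolute
        # brightness) at fixed enzyme levels cannot change them
        import dataclasses

        t = Transcript(name="r", payload="EYFP",
                       five_prime_sites=("Csy4-site",), alpha=1.0)
        t2 = dataclasses.replace(t, alpha=11.0)
        p2 = dataclasses.replace(params, kp=params.kp * 7.0)
        levels_lo, levels_hi = {"Csy4": 50.0}, {"Csy4": 5000.0}
        def fold(tr, p):
            lo = transcript_output(tr, levels_lo, p, 10.0, registry)
            hi = transcript_output(tr, levels_hi, p, 10.0, registry)
            return lo / hi
        assert fold(t, params) == pytest.approx(fold(t2, p2), rel=1e-12)


class TestDegLadder:
    def test_no_repeats_fold_one(self, params):
        assert deg_ladder([0], params)[0] == 1.0

    def test_thirty_repeats_over_three_hundred(self, params):
        assert deg_ladder([30], params)[30] >= 300.0

    def test_monotone_in_repeats(self, params):
        folds = deg_ladder([0, 5, 10, 20, 30], params)
        vals = [folds[n] for n in (0, 5, 10, 20, 30)]
        assert vals == sorted(vals)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            deg_ladder([31], params)
        with pytest.raises(ValueError):
            deg_ladder([-1], params)


class TestTriplexRescue:
    def test_rescue_fold_at_default_calibration(self, cfg):
        from persist.experiments import triplex_rescue_fold

        assert triplex_rescue_fold(cfg) == pytest.approx(166.0, rel=0.01)

    def test_rescue_abolished_without_stabilizer_semantics(self, registry, params):
        import dataclasses

        # if the cleaved species decays as fast as the tagged one, the
        # constitutive cleavage site cannot rescue expression
        p2 = dataclasses.replace(params,
                                 d_slow=params.d0 + params.d_fast(30))
        without = steady_state(motifs.degraded_reporter(registry, 30), p2)
        withsite = steady_state(
            motifs.degraded_reporter(registry, 30, rnasep_site=True), p2)
        assert withsite.proteins["EYFP"] / without.proteins["EYFP"] < 1.05


class TestFixedPoints:
    def test_single_reporter_has_one_stable_point(self, registry, params):
        fps = find_fixed_points(motifs.plain_reporter(registry), params,
                                n_starts=8, seed=0)
        assert fps.n_stable == 1 and len(fps.points) == 1

    def test_broken_toggle_is_monostable(self, registry, params):
        circuit = motifs.toggle(registry).with_copies(nodeB=0.0, reporterB=0.0)
        fps = find_fixed_points(circuit, params, n_starts=16, seed=0)
        assert fps.n_stable == 1

    def test_min_starts_enforced(self, registry, params):
        with pytest.raises(ValueError):
            find_fixed_points(motifs.plain_reporter(registry), params, n_starts=4)

    def test_stability_labels_consistent_with_dynamics(self, registry, params):
        # perturbing a stable point and re-integrating returns to it
        circuit = motifs.auto_positive_feedback(registry, copies=50.0)
        fps = find_fixed_points(circuit, params, n_starts=16, seed=3)
        stable = [p for p in fps.points if p.stable]
        assert stable
        st = stable[-1].state
        bumped = type(st)(dict(st.uncut), dict(st.stabilized),
                          {k: v * 1.05 for k, v in st.proteins.items()})
        _, states = simulate(circuit, params, t_end=2000.0, x0=bumped)
        for k, v in st.proteins.items():
            if v > 1e-9:
                assert states[-1].proteins[k] == pytest.approx(v, rel=1e-4)


class TestValidation:
    def test_unknown_site_rejected(self, registry):
        t = Transcript(name="r", payload="EYFP", five_prime_sites=("nope",))
        with pytest.raises(KeyError):
            CircuitSpec([t], {"r": 1.0}, registry)

    def test_deg_repeats_bounds(self):
        with pytest.raises(ValueError):
            OnMotif(sites=(), deg_repeats=31)

    def test_dslow_direction_unconstrained_but_dp_pest_checked(self):
        with pytest.raises(ValueError, match="dp_pest"):
            ModelParams(dp=0.5, dp_pest=0.5)
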