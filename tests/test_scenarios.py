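"""Scenario composition, presets, labeled-pool designs and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turnoverkit import (
    LN2,
    ParameterError,
    Perturbation,
    Scenario,
    StateVector,
    TimeCourse,
    TurnoverParams,
    integrate_reference,
    predict_fold_change,
    preset,
    pulse_chase,
    rate_constants,
    silac_switch,
    simulate,
    steady_state,
)

from conftest import random_params, sampling_span


class TestScenarioValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError, match="kind"):
            Perturbation(0.0, "magic", 1.0)

    def test_two_label_switches_rejected(self):
        with pytest.raises(ParameterError, match="label_switch"):
            Scenario(
                perturbations=(
                    Perturbation(0.0, "label_switch"),
                    Perturbation(1.0, "label_switch"),
                )
            )

    def test_label_switch_with_explicit_initial_condition_rejected(self, nondividing_params):
        scen = Scenario(
            perturbations=(Perturbation(0.0, "label_switch"),),
            sampling_times=(0.0, 1.0),
            initial_condition=StateVector(mrna=5.0, protein=10.0),
        )
        with pytest.raises(ParameterError, match="label_switch"):
            simulate(scen, nondividing_params)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError, match="preset"):
            preset("mystery_chase", (0.0, 1.0))

    def test_unknown_preset_option_rejected(self):
        with pytest.raises(ParameterError, match="options"):
            preset("chx_chase", (0.0, 1.0), strength=2.0)


class TestSimulate:
    def test_no_perturbations_stays_at_steady_state(self, dividing_params):
        tc = simulate(Scenario(sampling_times=tuple(np.linspace(0, 20, 9))), dividing_params)
        p0 = steady_state(dividing_params)
        assert np.max(np.abs(tc.protein_total / p0 - 1)) < 1e-12

    def test_synthesis_block_halves_at_half_life(self, nondividing_params):
        tc = simulate(preset("chx_chase", (0.0, 2.0)), nondividing_params)
        assert tc.protein_total[-1] / tc.protein_total[0] == pytest.approx(0.5, rel=1e-9)

    def test_transcription_shutoff_matches_closed_form(self):
        p = TurnoverParams(10, 2, 1.0, 1.0)
        tc = simulate(preset("tet_off", (0.0, 1.0)), p)
        assert tc.protein_total[-1] / tc.protein_total[0] == pytest.approx(0.8466, abs=1e-4)

    def test_sirna_relaxes_to_residual_fraction(self):
        # fast mRNA turnover, slow protein: new steady state is f * P0
        p = TurnoverParams(10, 2, 0.2, 5.0)
        scen = preset("sirna_knockdown", (0.0, 200.0), residual_fraction=0.2)
        tc = simulate(scen, p)
        assert tc.protein_total[-1] / tc.protein_total[0] == pytest.approx(0.2, rel=1e-6)

    def test_full_degradation_block_gives_linear_rise(self):
        p = TurnoverParams(10, 2, 0.5, 40.0)
        t = np.array([0.0, 2.0, 4.0, 8.0])
        tc = simulate(preset("degradation_inhibitor", tuple(t)), p)
        expected = 1 + t * LN2 / 40.0  # dP/dt = D * P0 when degradation is fully blocked
        assert np.allclose(tc.protein_total / tc.protein_total[0], expected, rtol=1e-9)

    def test_chx_plus_full_inhibitor_freezes_protein(self):
        p = TurnoverParams(10, 2, 0.5, 2.0)
        tc = simulate(preset("chx_plus_inhibitor", (0.0, 5.0, 10.0)), p)
        assert np.max(np.abs(tc.protein_total / tc.protein_total[0] - 1)) < 1e-12

    def test_composition_equals_sequential_propagation(self):
        # simulating [A then B] == simulating B from the state reached under A
        p = TurnoverParams(8, 3, 1.5, 4.0, 30.0)
        t_switch = 2.0
        combined = simulate(
            Scenario(
                perturbations=(
                    Perturbation(0.0, "synthesis_multiplier", 0.3),
                    Perturbation(t_switch, "degradation_multiplier", 0.1),
                ),
                sampling_times=(t_switch, 5.0, 9.0),
            ),
            p,
        )
        first = simulate(
            Scenario(
                perturbations=(Perturbation(0.0, "synthesis_multiplier", 0.3),),
                sampling_times=(t_switch,),
            ),
            p,
        )
        second = simulate(
            Scenario(
                perturbations=(
                    Perturbation(0.0, "synthesis_multiplier", 0.3),
                    Perturbation(0.0, "degradation_multiplier", 0.1),
                ),
                sampling_times=(5.0 - t_switch, 9.0 - t_switch),
                initial_condition=StateVector(mrna=first.mrna[0], protein=first.protein_total[0]),
            ),
            p,
        )
        assert np.allclose(combined.protein_total[1:], second.protein_total, rtol=1e-8)

    @pytest.mark.parametrize("name", ["chx_chase", "tet_off", "sirna_knockdown",
                                      "degradation_inhibitor", "chx_plus_inhibitor"])
    def test_presets_agree_with_reference_integrator(self, name):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(5):
            p = random_params(rng)
            t = sampling_span(p)
            scen = preset(name, tuple(t))
            tc = simulate(scen, p)
            ref = integrate_reference(p, scen.perturbations, t)
            scale = steady_state(p)
            worst = max(worst, np.max(np.abs(tc.protein_total - ref.protein) / scale))
            worst = max(worst, np.max(np.abs(tc.mrna - ref.mrna) / p.mrna_copies))
        assert worst < 1e-6


class TestLabeledDesigns:
    def test_silac_heavy_half_filled_at_effective_half_life(self, dividing_params):
        rc = rate_constants(dividing_params)
        t_eff = LN2 / rc.k_p
        tc = silac_switch(dividing_params, [0.0, t_eff])
        frac = tc.protein_labeled / tc.protein_total
        assert frac[0] == 0.0
        assert frac[1] == pytest.approx(0.5, rel=1e-9)

    def test_silac_long_lived_protein_slow_labeling(self):
        # heavy fraction after 8 h for t_p = 40 h in cells doubling every 24 h
        p = TurnoverParams(10, 2, 0.5, 40.0, 24.0)
        tc = silac_switch(p, [0.0, 8.0])
        assert tc.protein_labeled[-1] / tc.protein_total[-1] == pytest.approx(0.3090, abs=1e-4)

    def test_silac_total_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_params(rng)
            t = sampling_span(p)
            tc = silac_switch(p, t)
            assert np.max(np.abs(tc.protein_total / steady_state(p) - 1)) < 1e-8

    def test_silac_pools_match_reference(self):
        p = TurnoverParams(10, 2, 0.5, 40.0, 24.0)
        t = np.linspace(0, 48, 9)
        tc = silac_switch(p, t)
        ref = integrate_reference(p, [], t, label_active=True)
        assert np.allclose(tc.protein_labeled, ref.labeled, rtol=1e-6, atol=1e-9)
        assert np.allclose(tc.protein_unlabeled, ref.unlabeled, rtol=1e-6, atol=1e-9)

    def test_pulse_chase_labeled_halves_at_half_life(self, nondividing_params):
        tc = pulse_chase(nondividing_params, 1.0, preset("chx_chase"), times=[0.0, 2.0])
        assert tc.protein_labeled[-1] / tc.protein_labeled[0] == pytest.approx(0.5, rel=1e-9)

    def test_pulse_chase_blocked_degradation_freezes_label(self, nondividing_params):
        chase = preset("degradation_inhibitor")
        tc = pulse_chase(nondividing_params, 1.0, chase, times=[0.0, 3.0, 6.0])
        assert np.max(np.abs(tc.protein_labeled / tc.protein_labeled[0] - 1)) < 1e-12

    def test_short_pulse_accumulation(self):
        # labeled pool after a 0.5 h pulse for t_p = 2 h, non-dividing
        p = TurnoverParams(10, 2, 0.5, 2.0)
        tc = pulse_chase(p, 0.5, preset("chx_chase"), times=[0.0])
        assert tc.protein_labeled[0] / steady_state(p) == pytest.approx(0.1591, abs=1e-4)

    def test_pulse_chase_rejects_label_switch_in_chase(self, nondividing_params):
        chase = Scenario(perturbations=(Perturbation(0.0, "label_switch"),), sampling_times=(1.0,))
        with pytest.raises(ParameterError, match="label"):
            pulse_chase(nondividing_params, 1.0, chase)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        s_syn=st.floats(0, 3),
        s_deg=st.floats(0, 3),
        pulse=st.floats(0.1, 5),
        seed=st.integers(0, 100),
    )
    def test_label_conservation_under_arbitrary_chase(self, s_syn, s_deg, pulse, seed):
        """labeled + unlabeled always equals the independently simulated total."""
        p = random_params(np.random.default_rng(seed))
        chase = Scenario(
            perturbations=(
                Perturbation(0.0, "synthesis_multiplier", s_syn),
                Perturbation(0.0, "degradation_multiplier", s_deg),
            ),
            sampling_times=tuple(sampling_span(p, 5)),
        )
        tc = pulse_chase(p, pulse, chase)
        assert np.all(tc.protein_labeled >= -1e-12)
        assert np.all(tc.protein_unlabeled >= -1e-12)
        ref = integrate_reference(p, chase.perturbations, tc.times,
                                  initial=(tc.mrna[0], tc.protein_labeled[0], tc.protein_unlabeled[0]))
        denom = np.maximum(ref.protein, 1e-12)
        assert np.max(np.abs(tc.protein_total - ref.protein) / denom) < 1e-6


class TestFoldChangeDecomposition:
    def test_pure_degradation_block_is_bounded(self):
        p = TurnoverParams(10, 2, 0.5, 40.0)
        fc = predict_fold_change(p, degradation_multiplier=0.0, transcription_multiplier=1.0, t=8.0)
        assert fc.total == pytest.approx(1 + 8 * LN2 / 40, rel=1e-9)  # ~1.139
        assert fc.synthesis_attributed == pytest.approx(1.0, rel=1e-12)

    def test_null_perturbation_is_flat(self, dividing_params):
        fc = predict_fold_change(dividing_params, 1.0, 1.0, 12.0)
        assert fc.total == pytest.approx(1.0, rel=1e-10)

    def test_transcription_doubling_doubles_steady_state(self):
        p = TurnoverParams(10, 2, 0.1, 5.0)  # t_m << t_p
        fc = predict_fold_change(p, 1.0, 2.0, 200.0)
        assert fc.total == pytest.approx(2.0, rel=1e-6)
        assert fc.degradation_only == pytest.approx(1.0, rel=1e-9)

    def test_threefold_rise_requires_synthesis(self):
        # a 3x rise of a 40 h half-life protein in 8 h cannot come from
        # blocked degradation alone; the decomposition must say so
        p = TurnoverParams(10, 2, 0.5, 40.0)
        fc = predict_fold_change(p, 0.0, 15.8, 8.0)
        assert fc.total == pytest.approx(3.0, abs=0.1)
        assert fc.degradation_only < 1.15
        assert fc.synthesis_attributed > 2.0
        assert fc.total == pytest.approx(fc.degradation_only * fc.synthesis_attributed, rel=1e-12)


class TestTimeCourseIO:
    def test_round_trip_through_frame(self, nondividing_params):
        tc = silac_switch(nondividing_params, np.linspace(0, 6, 5))
        back = TimeCourse.from_frame(tc.to_frame())
        assert np.allclose(back.protein_labeled, tc.protein_labeled)
        assert np.allclose(back.protein_total, tc.protein_total)
        assert back.labeled_present
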