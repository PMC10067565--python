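"""Thorax simulator: pressures, recruitment hysteresis, rendering."""

import copy
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eitpose import io as eio
from eitpose import sim
from eitpose.errors import DegenerateLungError, EventError
from eitpose.sim import (
    LATERAL_LEFT,
    LATERAL_RIGHT,
    SUPINE,
    Posture,
    Segment,
    SimConfig,
    VentSettings,
    build_lung_model,
    gravitational_depth,
    initialize_state,
    oxygenation_surrogate,
    pleural_pressure,
    render_frames,
    step_state,
    transpulmonary_pressure,
)


def ards_config(seed=0, **kw):
    kw.setdefault("injury_severity", 1.0)
    return SimConfig(seed=seed, **kw)


class TestConfigValidation:
    def test_rl_span_must_exceed_ap(self):
        with pytest.raises(ValueError, match="span"):
            SimConfig(thorax_ap_cm=30.0, thorax_rl_cm=22.0)

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(thorax_ap_cm=-1.0)

    def test_supine_posture_requires_zero_tilt(self):
        with pytest.raises(ValueError):
            Posture("supine", 30.0)

    def test_vent_guards(self):
        with pytest.raises(ValueError):
            VentSettings(tidal_volume=0.0)
        with pytest.raises(ValueError):
            VentSettings(fio2=0.0)


class TestBuildModel:
    def test_unit_count_equals_lung_mask(self, roi):
        model = build_lung_model(ards_config(), roi)
        assert model.n_units == roi.lung_pixels.size

    def test_same_seed_identical_field_by_field(self, roi):
        a = build_lung_model(ards_config(seed=42), roi)
        b = build_lung_model(ards_config(seed=42), roi)
        for name in ("pixel_index", "compliance", "opening", "closing",
                     "perfusion_base", "collapse_delay"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_healthy_lung_opening_nonpositive_and_never_collapses(self, roi):
        cfg = SimConfig(seed=1, injury_severity=0.0)
        model = build_lung_model(cfg, roi)
        assert np.all(model.opening <= 0.0)
        vent = VentSettings(peep=0.0)
        step_state(model, vent, SUPINE, cfg, n_breaths=100)
        assert model.is_open.all()

    def test_hysteresis_never_negative(self, roi):
        for inj in (0.0, 0.5, 1.0):
            model = build_lung_model(ards_config(seed=3, injury_severity=inj), roi)
            assert np.all(model.opening >= model.closing)

    def test_thresholds_increase_with_depth(self, roi):
        model = build_lung_model(ards_config(seed=4), roi)
        r = np.corrcoef(model.depth_anat, model.opening)[0, 1]
        assert r > 0.8

    def test_initial_state_matches_unit_by_unit_oracle(self, roi):
        """Collapsed set == brute-force end-inspiratory P_L < opening rule."""
        cfg = ards_config(seed=7)
        model = build_lung_model(cfg, roi)
        peep, peak = 10.0, 25.0
        initialize_state(model, VentSettings(peep=peep), SUPINE, cfg,
                         peak_pressure=peak)
        for i in range(model.n_units):
            unit = model.unit(i)
            pl_ei = transpulmonary_pressure(unit, peak, SUPINE, cfg)
            assert unit.is_open == (pl_ei > unit.opening_pressure)


class TestPressures:
    def test_zero_depth_gives_airway_pressure(self):
        cfg = SimConfig(pleural_offset=0.0)
        # uppermost point of the thorax ellipse in supine: d_ap = -a, rl = 0
        depth = gravitational_depth(-cfg.thorax_ap_cm / 2.0, 0.0, SUPINE, cfg)
        assert abs(depth) < 1e-12
        ppl = pleural_pressure(-cfg.thorax_ap_cm / 2.0, 0.0, SUPINE, cfg)
        assert abs((12.0 - ppl) - 12.0) < 1e-12

    def test_linear_gradient_10cm_apart(self):
        cfg = SimConfig(pleural_gradient=0.5)
        p1 = pleural_pressure(-5.0, 0.0, SUPINE, cfg)
        p2 = pleural_pressure(5.0, 0.0, SUPINE, cfg)
        assert abs((p2 - p1) - 5.0) < 1e-12

    @pytest.mark.parametrize("posture", [LATERAL_LEFT, LATERAL_RIGHT])
    def test_lateral_pl_spread_exceeds_supine(self, roi, posture):
        """Brute force over all units: the across-units P_L range is wider
        in 30-degree lateral than supine because the chest is wider than
        deep."""
        cfg = ards_config(seed=0)
        model = build_lung_model(cfg, roi)
        paw = 20.0
        pl_sup = transpulmonary_pressure(model, paw, SUPINE, cfg)
        pl_lat = transpulmonary_pressure(model, paw, posture, cfg)
        assert np.ptp(pl_lat) > np.ptp(pl_sup)


class TestStepState:
    def test_driving_pressure_is_vt_over_open_compliance(self, roi):
        cfg = SimConfig(seed=2, injury_severity=0.0, compliance_total=20.0)
        model = build_lung_model(cfg, roi)
        state = step_state(model, VentSettings(tidal_volume=350.0), SUPINE, cfg)
        assert state.driving_pressure == pytest.approx(17.5, rel=1e-9)

    def test_peep_above_closing_is_a_hysteresis_floor(self, roi):
        cfg = ards_config(seed=5, collapse_delay_breaths=0)
        model = build_lung_model(cfg, roi)
        ppl = pleural_pressure(model.d_ap, model.rl, SUPINE, cfg)
        peep = float((model.closing + ppl).max()) + 0.5
        vent = VentSettings(peep=peep)
        open_before = model.is_open.copy()
        step_state(model, vent, SUPINE, cfg, n_breaths=100)
        assert np.array_equal(model.is_open | ~open_before, np.ones_like(open_before))

    def test_all_collapsed_is_degenerate(self, roi):
        cfg = ards_config(seed=6)
        model = build_lung_model(cfg, roi)
        model.is_open[:] = False
        with pytest.raises(DegenerateLungError):
            step_state(model, VentSettings(), SUPINE, cfg)

    def test_single_unit_trajectory_matches_hand_rule(self):
        """A dorsal left-lung unit with an end-inspiratory P_L deficit in
        supine at PEEP 10 stays closed, opens during a lateral epoch that
        makes it non-dependent (P_L gain exceeds the deficit), and remains
        open back in supine at PEEP 14 - the breath-by-breath open/close
        rule evaluated independently for that single unit."""
        cfg = SimConfig(seed=0, collapse_delay_breaths=0,
                        pleural_gradient=0.7, pleural_offset=-3.0)
        # two units: a big healthy ventral reservoir fixing dP = 350/20 =
        # 17.5, plus the lateral-most dorsal unit under test (left lung ->
        # non-dependent during LateralRight)
        model = sim.LungModel(
            pixel_index=np.array([8 * 32 + 16, 24 * 32 + 29]),
            d_ap=np.array([-5.0, 6.0]),
            rl=np.array([1.0, 13.0]),
            compliance=np.array([20.0, 1.0]),
            opening=np.array([-50.0, 21.0]),
            closing=np.array([-60.0, 4.0]),
            perfusion_base=np.ones(2),
            side=np.array(["left_lung", "left_lung"]),
            is_open=np.array([True, False]),
            collapse_delay=np.ones(2, dtype=int),
        )

        def pl(paw, posture):
            return transpulmonary_pressure(model, paw, posture, cfg)[1]

        # oracle: the P_L sequence computed by hand drives the rule
        vent10 = VentSettings(peep=10.0)
        dp = 350.0 / 20.0
        step_state(model, vent10, SUPINE, cfg, n_breaths=5)
        assert pl(10.0 + dp, SUPINE) < 21.0  # P_L deficit: stays closed
        assert not model.is_open[1]

        step_state(model, vent10, LATERAL_RIGHT, cfg, n_breaths=5)
        assert pl(10.0 + dp, LATERAL_RIGHT) > 21.0  # gain > deficit: opens
        assert pl(10.0, LATERAL_RIGHT) > 4.0  # and stays above closing
        assert model.is_open[1]

        vent14 = VentSettings(peep=14.0)
        step_state(model, vent14, SUPINE, cfg, n_breaths=5)
        assert pl(14.0, SUPINE) > 4.0  # supported above closing
        assert model.is_open[1]

    def test_raising_peep_never_increases_steady_collapse(self, roi):
        """Hysteresis monotonicity: steady-state collapsed count is
        non-increasing in PEEP, all else fixed."""
        cfg = ards_config(seed=8, collapse_delay_breaths=0)
        counts = []
        for peep in (6.0, 10.0, 14.0, 18.0):
            model = build_lung_model(cfg, roi)
            vent = VentSettings(peep=peep)
            initialize_state(model, vent, SUPINE, cfg, peak_pressure=40.0)
            step_state(model, vent, SUPINE, cfg, n_breaths=120)
            counts.append(int((~model.is_open).sum()))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_more_open_units_lower_driving_pressure(self, roi):
        cfg = ards_config(seed=9)
        model = build_lung_model(cfg, roi)
        vent = VentSettings()
        model.is_open[:] = True
        dp_all = sim.driving_pressure(model, vent)
        model.is_open[model.depth_anat > np.median(model.depth_anat)] = False
        dp_fewer = sim.driving_pressure(model, vent)
        assert dp_fewer > dp_all


class TestPerfusion:
    def test_fractions_sum_to_one(self, roi):
        cfg = ards_config(seed=10)
        model = build_lung_model(cfg, roi)
        model.is_open[::3] = False
        for posture in (SUPINE, LATERAL_LEFT):
            q = sim.perfusion_fractions(model, VentSettings(), posture, cfg)
            assert abs(q.sum() - 1.0) < 1e-9
            assert np.all(q >= 0.0)

    def test_hpv_reduces_collapsed_share(self, roi):
        cfg = ards_config(seed=11)
        model = build_lung_model(cfg, roi)
        collapsed = np.zeros(model.n_units, dtype=bool)
        collapsed[:40] = True
        model.is_open = ~collapsed
        vent = VentSettings()
        q_hpv = sim.perfusion_fractions(model, vent, SUPINE, cfg)
        q_off = sim.perfusion_fractions(
            model, vent, SUPINE, replace(cfg, hpv_factor=1.0)
        )
        assert q_hpv[collapsed].sum() < q_off[collapsed].sum()


class TestOxygenationSurrogate:
    def test_limits_are_exact(self):
        assert oxygenation_surrogate(0.0) == pytest.approx(500.0)
        assert oxygenation_surrogate(1.0) == pytest.approx(40.0)

    def test_strictly_decreasing_100_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = np.sort(rng.uniform(0.0, 1.0, 2))
            if a == b:
                continue
            assert oxygenation_surrogate(a) > oxygenation_surrogate(b)

    @given(st.floats(min_value=-10, max_value=10).filter(lambda s: not 0 <= s <= 1))
    def test_out_of_range_rejected(self, s):
        with pytest.raises(ValueError):
            oxygenation_surrogate(s)


class TestRendering:
    def test_frame_count_60s_at_50hz(self, quiet_config, roi):
        model = build_lung_model(quiet_config, roi)
        seg = Segment(model, VentSettings(), SUPINE, 60.0)
        seq = render_frames([seg], quiet_config)
        assert seq.n_frames == 3000

    def test_bit_identical_for_same_seed(self, roi):
        cfg = ards_config(seed=12)
        out = []
        for _ in range(2):
            model = build_lung_model(cfg, roi)
            seg = Segment(model, VentSettings(), SUPINE, 5.0)
            out.append(render_frames([seg], cfg).frames)
        np.testing.assert_array_equal(out[0], out[1])

    def test_single_open_unit_global_signal_is_its_tidal_waveform(self, roi):
        cfg = SimConfig(seed=0, injury_severity=0.0, noise_sd=0.0,
                        cardiac_amplitude=0.0)
        model = build_lung_model(cfg, roi)
        model.is_open[:] = False
        model.is_open[10] = True
        vent = VentSettings()
        seg = Segment(model, vent, SUPINE, 10.0)
        seq = render_frames([seg], cfg)
        glob = seq.frames.sum(axis=1)
        amp = sim.tidal_amplitudes(model, vent, cfg)[10]
        phase = np.arange(seq.n_frames) / (cfg.frame_rate * vent.breath_period)
        expected = amp * sim.breath_waveform(phase, vent.ie_ratio)
        np.testing.assert_allclose(glob - glob.min(), expected, atol=1e-9)

    def test_apnea_has_no_tidal_component(self, quiet_config, roi):
        model = build_lung_model(quiet_config, roi)
        seg = Segment(model, VentSettings(), SUPINE, 10.0, kind="apnea")
        seq = render_frames([seg], quiet_config)
        assert np.ptp(seq.frames.sum(axis=1)) < 1e-9

    def test_bolus_deflection_confined_to_perfused_quadrant(self, roi):
        cfg = SimConfig(seed=1, injury_severity=0.0, noise_sd=0.0,
                        cardiac_amplitude=0.0)
        model, q = sim.model_with_perfusion_fractions(
            cfg,
            {"upper_right": 1.0, "upper_left": 0.0,
             "lower_right": 0.0, "lower_left": 0.0},
            roi,
        )
        seg = Segment(model, VentSettings(), SUPINE, 20.0, kind="apnea",
                      bolus_time=3.0, perfusion=q)
        seq = render_frames([seg], cfg)
        deflection = seq.frames[0] - seq.frames.min(axis=0)
        outside = np.setdiff1d(roi.lung_pixels, roi.pixels("quadrant", "upper_right"))
        assert deflection[roi.pixels("quadrant", "upper_right")].max() > 0.01
        assert np.abs(deflection[outside]).max() < 1e-9

    def test_bolus_outside_apnea_rejected(self, quiet_config, roi):
        model = build_lung_model(quiet_config, roi)
        with pytest.raises(EventError, match="bolus"):
            Segment(model, VentSettings(), SUPINE, 20.0, kind="breathing",
                    bolus_time=3.0)
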