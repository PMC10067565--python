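"""Breath detection and ventilation-distribution metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eitpose import breaths as bra
from eitpose import io as eio
from eitpose import sim
from eitpose.errors import AnalysisError, NoBreathsError
from eitpose.io import FrameSequence
from eitpose.sim import Segment, SimConfig, VentSettings

QUADS = list(eio.QUADRANT_LABELS)


def quadrant_model(fractions, roi, seed=0, noise=0.05, cardiac=30.0):
    cfg = SimConfig(seed=seed, injury_severity=0.0, noise_sd=noise,
                    cardiac_amplitude=cardiac)
    model = sim.model_with_ventilation_fractions(cfg, dict(zip(QUADS, fractions)), roi)
    return cfg, model


def rendered(fractions, roi, seed=0, noise=0.05, duration=30.0, cardiac=30.0):
    cfg, model = quadrant_model(fractions, roi, seed, noise, cardiac)
    seg = Segment(model, VentSettings(), sim.SUPINE, duration)
    return cfg, sim.render_frames([seg], cfg)


class TestDetectBreaths:
    def test_pure_sinusoid_counts_and_amplitude(self):
        """30 cycles/min sinusoid: one breath per cycle, dZ = 2 x amplitude."""
        fr, f = 50.0, 0.5
        t = np.arange(int(62 * fr)) / fr
        x = 100.0 - 3.0 * np.cos(2 * np.pi * f * (t - 1.0))
        table = bra.detect_breaths(x, fr, 30.0)
        assert len(table) == 30
        dz = x[table["peak"]] - x[table["start"]]
        np.testing.assert_allclose(dz, 6.0, rtol=1e-2)

    def test_constant_signal_raises(self):
        with pytest.raises(NoBreathsError):
            bra.detect_breaths(np.full(3000, 5.0), 50.0, 30.0)

    def test_too_short_signal_raises(self):
        with pytest.raises(NoBreathsError, match="three breath periods"):
            bra.detect_breaths(np.sin(np.arange(100) / 10.0), 50.0, 30.0)

    def test_boundaries_match_simulator_truth(self, roi):
        """Detected end-expiration indices within +/-2 samples of the known
        breath grid for at least 95 % of breaths at default noise."""
        cfg, seq = rendered([0.3, 0.3, 0.2, 0.2], roi, seed=3, duration=60.0)
        glob = seq.frames[:, roi.lung_pixels].sum(axis=1)
        table = bra.detect_breaths(glob, cfg.frame_rate, 30.0)
        period = 2.0 * cfg.frame_rate  # samples per breath
        truth = np.round(np.round(table["start"] / period) * period)
        hits = np.abs(table["start"] - truth) <= 2
        assert hits.mean() >= 0.95


class TestRegionalDeltaZ:
    def test_localization_single_quadrant(self, roi):
        cfg, seq = rendered([1.0, 0.0, 0.0, 0.0], roi, noise=0.0, cardiac=0.0)
        glob = seq.frames[:, roi.lung_pixels].sum(axis=1)
        table = bra.detect_breaths(glob, cfg.frame_rate, 30.0)
        dz = bra.regional_delta_z(seq, table, roi)
        assert (dz["upper_right"] > 1.0).all()
        for q in QUADS[1:]:
            np.testing.assert_allclose(dz[q], 0.0, atol=1e-9)

    def test_additivity_halves_quadrants_global(self, roi):
        cfg, seq = rendered([0.4, 0.3, 0.2, 0.1], roi, seed=5)
        glob = seq.frames[:, roi.lung_pixels].sum(axis=1)
        table = bra.detect_breaths(glob, cfg.frame_rate, 30.0)
        dz_q = bra.regional_delta_z(seq, table, roi, "quadrant")
        dz_h = bra.regional_delta_z(seq, table, roi, "half")
        np.testing.assert_allclose(
            dz_q[QUADS].sum(axis=1), dz_q["global"], rtol=1e-12
        )
        np.testing.assert_allclose(
            dz_h[["ventral", "dorsal"]].sum(axis=1), dz_q["global"], rtol=1e-12
        )

    def test_amplitude_ratios_recovered(self, roi):
        """Per-quadrant tidal amplitudes 4:3:2:1 recovered within 2 %."""
        target = np.array([0.4, 0.3, 0.2, 0.1])
        cfg, seq = rendered(target, roi, seed=6)
        glob = seq.frames[:, roi.lung_pixels].sum(axis=1)
        table = bra.detect_breaths(glob, cfg.frame_rate, 30.0)
        dz = bra.regional_delta_z(seq, table, roi).mean()
        shares = (dz[QUADS] / dz[QUADS].sum()).to_numpy()
        np.testing.assert_allclose(shares, target, rtol=0.02)

    def test_empty_roi_rejected(self, roi, quick_sequence):
        bad = eio.ROIMask(
            roi.lung_mask,
            np.where(roi.half == "dorsal", "ventral", roi.half),
            roi.side,
            roi.quadrant,
        )
        glob = quick_sequence.frames[:, roi.lung_pixels].sum(axis=1)
        table = bra.detect_breaths(glob, 50.0, 30.0)
        with pytest.raises(AnalysisError, match="empty ROI"):
            bra.regional_delta_z(quick_sequence, table, bad, "half")


class TestVentilationDistribution:
    def test_single_roi_takes_all(self):
        d = bra.ventilation_distribution({"a": 5.0, "b": 0.0, "c": 0.0})
        assert d["a"] == pytest.approx(100.0)
        assert d["b"] == d["c"] == 0.0

    def test_equal_quadrants_25_each(self):
        d = bra.ventilation_distribution(dict.fromkeys(QUADS, 3.3))
        np.testing.assert_allclose(d.to_numpy(), 25.0)

    def test_zero_total_rejected(self):
        with pytest.raises(AnalysisError):
            bra.ventilation_distribution({"a": 0.0, "b": 0.0})

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=8)
    )
    def test_shares_sum_to_100(self, values):
        d = bra.ventilation_distribution(
            {f"r{i}": v for i, v in enumerate(values)}
        )
        assert d.sum() == pytest.approx(100.0, abs=1e-9)
        assert (d >= 0).all()

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=6),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_invariant_to_global_rescaling(self, values, k):
        rois = {f"r{i}": v for i, v in enumerate(values)}
        scaled = {r: v * k for r, v in rois.items()}
        pd.testing.assert_series_equal(
            bra.ventilation_distribution(rois),
            bra.ventilation_distribution(scaled),
            rtol=1e-9,
        )

    def test_dorsal_fraction_recovered_from_simulator(self, roi):
        """A configured 40 % dorsal share is recovered within 2 percentage
        points averaged over at least 10 breaths."""
        cfg = SimConfig(seed=9, injury_severity=0.0)
        model = sim.model_with_ventilation_fractions(
            cfg, {"ventral": 0.6, "dorsal": 0.4}, roi
        )
        seg = Segment(model, VentSettings(), sim.SUPINE, 30.0)
        seq = sim.render_frames([seg], cfg)
        out = bra.epoch_ventilation_summary(seq, roi, 30.0)
        assert out["n_breaths"] >= 10
        assert out["distribution_half"]["dorsal"] == pytest.approx(40.0, abs=2.0)


class TestVolumeAndCompliance:
    def test_direct_formulas(self):
        vtr = bra.regional_tidal_volume({"r": 30.0}, 350.0)
        assert vtr["r"] == pytest.approx(105.0)
        assert bra.regional_tidal_volume({"r": 100.0}, 350.0)["r"] == 350.0
        assert bra.regional_compliance(105.0, 15.0) == pytest.approx(7.0)

    def test_nonpositive_driving_pressure_rejected(self):
        with pytest.raises(AnalysisError):
            bra.regional_compliance(100.0, 0.0)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0, allow_subnormal=False),
                 min_size=4, max_size=4),
        st.floats(min_value=50.0, max_value=600.0),
        st.floats(min_value=5.0, max_value=30.0),
    )
    def test_partition_identities(self, raw, vt, dp):
        """V_Tr sums to V_T and regional C_Z sums to V_T/dP over a
        partition; C_Z x dP recovers V_Tr at machine precision."""
        if sum(raw) <= 0:
            raw = [r + 1.0 for r in raw]
        dist = bra.ventilation_distribution(dict(zip(QUADS, raw)))
        vtr = bra.regional_tidal_volume(dist, vt)
        cz = bra.regional_compliance(vtr, dp)
        assert vtr.sum() == pytest.approx(vt, rel=1e-9)
        assert cz.sum() == pytest.approx(vt / dp, rel=1e-9)
        np.testing.assert_allclose(cz * dp, vtr, rtol=1e-12)


class TestEELI:
    @staticmethod
    def _table(seq, roi):
        glob = seq.frames[:, roi.lung_pixels].sum(axis=1)
        return bra.detect_breaths(glob, seq.frame_rate, 30.0)

    def test_identical_epochs_give_zero(self, roi, quick_sequence):
        table = self._table(quick_sequence, roi)
        series = bra.eeli_series(quick_sequence, table, roi)
        d = bra.delta_eeli(series, (0.0, 20.0), (0.0, 20.0))
        np.testing.assert_allclose(d.to_numpy(), 0.0, atol=1e-12)

    def test_constant_offset_on_one_quadrant(self, roi, quiet_config):
        """Adding +K to one quadrant's pixels in the second half of the
        record shifts that quadrant's EELI by K x pixel count, others 0."""
        model = sim.build_lung_model(quiet_config, roi)
        seg = Segment(model, VentSettings(), sim.SUPINE, 40.0)
        seq = sim.render_frames([seg], quiet_config)
        K, quad = 2.5, "lower_left"
        px = roi.pixels("quadrant", quad)
        frames = seq.frames.copy()
        frames[seq.n_frames // 2 :, px] += K
        seq2 = FrameSequence(seq.frame_rate, frames, seq.events, seq.metadata)
        table = self._table(seq2, roi)
        series = bra.eeli_series(seq2, table, roi)
        d = bra.delta_eeli(series, (0.0, 20.0), (20.0, 40.0))
        # the step discontinuity itself perturbs one breath's alignment by
        # a few samples, so the check is to ~0.5 % rather than exact
        assert d[quad] == pytest.approx(K * px.size, abs=1.0)
        for q in QUADS:
            if q != quad:
                assert abs(d[q]) < 1.0

    def test_noise_only_delta_within_3se(self, roi):
        cfg = SimConfig(seed=13, injury_severity=0.0, noise_sd=0.5)
        model = sim.build_lung_model(cfg, roi)
        seg = Segment(model, VentSettings(), sim.SUPINE, 60.0)
        seq = sim.render_frames([seg], cfg)
        table = self._table(seq, roi)
        series = bra.eeli_series(seq, table, roi)
        a, b = (0.0, 30.0), (30.0, 60.0)
        d = bra.delta_eeli(series, a, b)
        t = series["time"].to_numpy()
        for col in ("global", *QUADS):
            va = series[col][(t >= a[0]) & (t < a[1])]
            vb = series[col][(t >= b[0]) & (t < b[1])]
            se = np.sqrt(va.var(ddof=1) / len(va) + vb.var(ddof=1) / len(vb))
            assert abs(d[col]) < 3.0 * max(se, 1e-12)

    def test_empty_epoch_rejected(self, roi, quick_sequence):
        table = self._table(quick_sequence, roi)
        series = bra.eeli_series(quick_sequence, table, roi)
        with pytest.raises(AnalysisError):
            bra.delta_eeli(series, (100.0, 110.0), (0.0, 20.0))
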