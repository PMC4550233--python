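"""Puff amplitude ratios, site classification and depth estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import spearmanr

import spintirf as st
from spintirf.puff_analysis import (
    PuffEvent,
    detect_events,
    events_table,
    sites_table,
)


def _trace(values, dt=0.01):
    values = np.asarray(values, dtype=float)
    return st.Trace(np.arange(len(values)) * dt, values)


class TestMeasureAmplitude:
    def test_flat_trace_zero_amplitude(self):
        tr = _trace(np.full(100, 0.3))
        assert st.measure_amplitude(tr, (0.2, 0.5)) == 0.0

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.01, 200)
        base[50:60] += 0.5
        tr1 = _trace(base)
        tr2 = _trace(base + 3.7)
        w = (0.45, 0.65)
        assert st.measure_amplitude(tr1, w) == pytest.approx(
            st.measure_amplitude(tr2, w), abs=1e-12
        )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no trace samples"):
            st.measure_amplitude(_trace(np.zeros(10)), (5.0, 6.0))

    def test_recovers_injected_peak(self, optics, camera):
        """A simulated puff of peak dF/F0 ~0.5 in WF is recovered within
        +/-0.05 at default noise."""
        from spintirf.puff_analysis import analyze_interleaved
        from spintirf.sim_camera import puff_event_windows

        spec, sched = st.make_scenario(
            "puff_depths", seed=21, depths_nm=[0.0], n_events=4,
            amplitude=0.5, bulk_photons_per_frame_per_um=0.0,
        )
        stack = st.render_stack(spec, sched, optics, camera, seed=21)
        site = spec.puff_sites[0]
        px, (ny, nx) = camera.pixel_size_um, camera.frame_shape
        roi = st.ROI.centered(
            "s", int(round(site.x_um / px + (nx - 1) / 2)),
            int(round(site.y_um / px + (ny - 1) / 2)), 3,
        )
        res = analyze_interleaved(
            stack, [roi], {"s": puff_event_windows(site)}, (0, 100),
            depth_nm=200.0,
        )
        # ROI averaging over 3x3 pixels dilutes the Gaussian footprint by
        # a geometric factor; compare against the footprint-averaged peak
        xs = (np.arange(-1, 2) * px)
        foot = np.exp(-(xs[None, :]**2 + xs[:, None]**2)
                      / (2 * site.spatial_sigma_um**2)).mean()
        expected = 0.5 * foot
        for e in res["events"]:
            assert e.amplitude_wf == pytest.approx(expected, abs=0.05)


class TestEventRatios:
    def test_identical_traces_give_unit_ratios(self):
        v = np.zeros(300)
        v[100:110] = 1.0
        tr = _trace(v)
        events = st.event_ratios(tr, tr, [(0.95, 1.3)])
        assert len(events) == 1
        assert events[0].ratio == pytest.approx(1.0)

    def test_below_noise_floor_excluded(self):
        quiet = _trace(np.zeros(300))
        loud = _trace(np.concatenate([np.zeros(100), [1.0], np.zeros(199)]))
        events = st.event_ratios(loud, quiet, [(0.95, 1.3)],
                                 wf_noise_floor=0.02)
        assert events == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            st.event_ratios(_trace(np.zeros(10)), _trace(np.zeros(20)),
                            [(0.0, 0.05)])

    def test_membrane_site_ratio_above_one(self, puff_analysis_result):
        """Site simulated at z=0: TIRF amplitude exceeds WF amplitude for
        every event (TIRF has the smaller resting background)."""
        events = [e for e in puff_analysis_result["events"]
                  if e.site_id == "site0"]
        assert events and all(e.ratio > 1.0 for e in events)

    def test_deep_site_ratio_below_one(self, puff_analysis_result):
        """Site at z = 2.5 d: evanescent attenuation pushes ratios < 1."""
        events = [e for e in puff_analysis_result["events"]
                  if e.site_id == "site5"]
        assert events and all(e.ratio < 1.0 for e in events)


class TestSummarizeSites:
    def _events(self, sid, ratios):
        return [PuffEvent(sid, (0, 1), r, 1.0) for r in ratios]

    def test_superficial_classification(self):
        s, = st.summarize_sites(self._events("a", [1.3, 1.2, 1.4, 1.25]))
        assert s.site_class == "superficial"
        assert s.n_events == 4

    def test_deep_and_intermediate_classification(self):
        events = (self._events("deep", [0.5, 0.6, 0.55, 0.58])
                  + self._events("mid", [0.95, 1.0, 1.05, 1.02]))
        by_id = {s.site_id: s.site_class for s in st.summarize_sites(events)}
        assert by_id == {"deep": "deep", "mid": "intermediate"}

    def test_sites_below_min_events_excluded(self):
        assert st.summarize_sites(self._events("a", [1.0, 1.0, 1.0])) == []

    def test_two_depth_populations_segregate(self, optics, camera):
        """Sites at z=0 and z=400 nm: site-mean ratios separate with zero
        overlap, mirroring the bimodal classification picture."""
        from spintirf.puff_analysis import analyze_interleaved
        from spintirf.sim_camera import PUFF_SCAN_RADIUS, puff_event_windows

        spec, sched = st.make_scenario(
            "puff_depths", seed=31, depths_nm=[0, 0, 400, 400], n_events=5
        )
        stack = st.render_stack(spec, sched, optics, camera, seed=31)
        px, (ny, nx) = camera.pixel_size_um, camera.frame_shape
        rois, events = [], {}
        for i, site in enumerate(spec.puff_sites):
            roi = st.ROI.centered(
                f"site{i}", int(round(site.x_um / px + (nx - 1) / 2)),
                int(round(site.y_um / px + (ny - 1) / 2)), 3,
            )
            rois.append(roi)
            events[roi.label] = puff_event_windows(site)
        d = st.depth_for_scan_radius(PUFF_SCAN_RADIUS, optics)
        res = analyze_interleaved(stack, rois, events, (0, 100), d)
        shallow = [s.mean_ratio for s in res["sites"]
                   if s.site_id in ("site0", "site1")]
        deep = [s.mean_ratio for s in res["sites"]
                if s.site_id in ("site2", "site3")]
        assert min(shallow) > max(deep)
        classes = {s.site_id: s.site_class for s in res["sites"]}
        assert classes["site0"] == classes["site1"] == "superficial"
        assert classes["site2"] == classes["site3"] == "deep"

    def test_within_class_spread_narrower_than_pooled(
        self, puff_analysis_result
    ):
        """Within-class ratio SD is well below the pooled SD: the ratio
        variability is between sites, not between events at a site."""
        sites = puff_analysis_result["sites"]
        pooled = np.concatenate([s.ratios for s in sites])
        within = np.concatenate(
            [np.asarray(s.ratios) - s.mean_ratio for s in sites]
        )
        assert within.std() < 0.5 * pooled.std()


class TestRatioHistogram:
    def test_counts_sum_to_n_events(self):
        events = [PuffEvent(0, (0, 1), r, 1.0) for r in (0.5, 0.9, 1.4, 2.1)]
        counts, _ = st.ratio_histogram(events, np.arange(0, 3.1, 0.5))
        assert counts.sum() == 4

    def test_unit_ratios_fall_in_unit_bin(self):
        events = [PuffEvent(0, (0, 1), 1.0, 1.0)] * 5
        counts, frac = st.ratio_histogram(events, [0.0, 0.9, 1.1, 2.0])
        assert counts[1] == 5
        assert frac == 0.0  # ratios equal, not greater than, 1

    def test_depth_range_crossing_unity_splits_events(self, optics, camera):
        """Depths uniform over (0, 2 z1) with ratio crossing 1 at z1 give
        roughly half the events above ratio 1 and half below."""
        from spintirf.puff_analysis import analyze_interleaved
        from spintirf.sim_camera import PUFF_SCAN_RADIUS, puff_event_windows

        d = st.depth_for_scan_radius(PUFF_SCAN_RADIUS, optics)
        k = 1.285  # resting-baseline ratio of the scenario defaults
        z1 = d * np.log(k)
        rng = np.random.default_rng(41)
        depths = rng.uniform(0.0, 2 * z1, 8)
        spec, sched = st.make_scenario(
            "puff_depths", seed=41, depths_nm=list(depths), n_events=4
        )
        stack = st.render_stack(spec, sched, optics, camera, seed=41)
        px, (ny, nx) = camera.pixel_size_um, camera.frame_shape
        rois, events = [], {}
        for i, site in enumerate(spec.puff_sites):
            roi = st.ROI.centered(
                f"site{i}", int(round(site.x_um / px + (nx - 1) / 2)),
                int(round(site.y_um / px + (ny - 1) / 2)), 3,
            )
            rois.append(roi)
            events[roi.label] = puff_event_windows(site)
        res = analyze_interleaved(stack, rois, events, (0, 100), d)
        _, frac = st.ratio_histogram(res["events"], np.arange(0, 3.1, 0.2))
        assert 0.3 <= frac <= 0.7


class TestEstimateDepth:
    def test_calibration_point_maps_to_zero(self):
        assert st.estimate_depth(1.3, 200.0, k=1.3) == 0.0

    def test_exponential_identity(self):
        assert st.estimate_depth(1.3 / np.e, 200.0, k=1.3) == pytest.approx(
            200.0
        )

    def test_ratio_above_k_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert st.estimate_depth(2.0, 200.0, k=1.3) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(z=hst.floats(0.0, 2000.0), d=hst.floats(50.0, 500.0),
           k=hst.floats(0.5, 3.0))
    def test_inverts_forward_model_exactly(self, z, d, k):
        ratio = k * np.exp(-z / d)
        assert st.estimate_depth(ratio, d, k) == pytest.approx(z, abs=1e-6)

    def test_depth_recovery_rmse(self, puff_recording, puff_analysis_result):
        """Simulated depths 0-500 nm recovered with RMSE < 50 nm."""
        _, specimen, _, _, _ = puff_recording
        res = puff_analysis_result
        true = np.array([s.z_nm for s in specimen.puff_sites])
        est = np.array([res["depths_nm"][f"site{i}"] for i in range(len(true))])
        rmse = np.sqrt(np.mean((est - true) ** 2))
        assert rmse < 50.0

    def test_mean_ratio_monotone_in_depth(self, puff_recording,
                                          puff_analysis_result):
        """Site-mean ratio decreases strictly with depth (Spearman -1)."""
        _, specimen, _, _, _ = puff_recording
        sites = puff_analysis_result["sites"]
        depths = [s.z_nm for s in specimen.puff_sites]
        ratios = [
            next(s.mean_ratio for s in sites if s.site_id == f"site{i}")
            for i in range(len(depths))
        ]
        assert spearmanr(depths, ratios).statistic == pytest.approx(-1.0)

    def test_ratio_invariant_under_common_gain(self, optics):
        """A common gain applied to the recorded fluorescence of both modes
        cancels in dF/F0, leaving every event ratio exactly unchanged."""
        from dataclasses import replace as dc_replace

        from spintirf.puff_analysis import analyze_interleaved
        from spintirf.sim_camera import PUFF_SCAN_RADIUS, puff_event_windows

        camera = st.CameraModel(em_gain=5.0)  # headroom for the 3x counts
        spec, sched = st.make_scenario(
            "puff_depths", seed=51, depths_nm=[150.0], n_events=4
        )
        d = st.depth_for_scan_radius(PUFF_SCAN_RADIUS, optics)
        site = spec.puff_sites[0]
        px, (ny, nx) = camera.pixel_size_um, camera.frame_shape
        roi = st.ROI.centered(
            "s", int(round(site.x_um / px + (nx - 1) / 2)),
            int(round(site.y_um / px + (ny - 1) / 2)), 3,
        )
        stack = st.render_stack(spec, sched, optics, camera, seed=51)
        scaled = dc_replace(
            stack, frames=(stack.frames.astype(np.uint32) * 3).astype(np.uint16)
        )
        ratios = []
        for s, black in ((stack, 100.0), (scaled, 300.0)):
            res = analyze_interleaved(
                s, [roi], {"s": puff_event_windows(site)}, (0, 100), d,
                black_level=black,
            )
            ratios.append([e.ratio for e in res["events"]])
        assert np.allclose(ratios[0], ratios[1], rtol=1e-12)


class TestHelpers:
    def test_detect_events_finds_threshold_crossings(self):
        v = np.zeros(1000)
        v[200:220] = 0.5
        v[600:620] = 0.5
        windows = detect_events(_trace(v, dt=0.005), threshold=0.2)
        assert len(windows) == 2
        assert windows[0][0] == pytest.approx(1.0 - 0.05, abs=0.01)

    def test_tables_have_expected_columns(self, puff_analysis_result):
        ev = events_table(puff_analysis_result["events"])
        si = sites_table(puff_analysis_result["sites"],
                         puff_analysis_result["depths_nm"])
        assert {"site_id", "ratio", "amplitude_tirf"} <= set(ev.columns)
        assert {"mean_ratio", "class", "depth_nm"} <= set(si.columns)
        assert len(si) == 6
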