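"""Event-level analysis of interleaved TIRF/widefield recordings.

A Ca2+ puff recorded in alternating TIRF and widefield (WF) frames gives
two dF/F0 amplitudes per event.  Because the evanescent field decays as
exp(-z/d) while WF excitation reaches through the cell, the per-event
amplitude ratio TIRF/WF reports the axial position of the release site:
superficial sites give ratios above 1 (TIRF also enjoys a lower resting
background), deep sites ratios below 1.  Sites with at least four events
are classified by mean ratio (> 1.1 superficial, < 0.9 deep, otherwise
intermediate), and the forward model ratio(z) = k exp(-z/d) — with k the
calibration ratio for a site at the membrane — is inverted to estimate
the release depth.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .processing import ROI, RatioStack, Trace, df_f0, deinterleave, roi_trace, subtract_black
from .sim_camera import ImageStack

__all__ = [
    "PuffEvent",
    "SiteSummary",
    "measure_amplitude",
    "event_ratios",
    "summarize_sites",
    "ratio_histogram",
    "estimate_depth",
    "calibration_ratio",
    "detect_events",
    "analyze_interleaved",
    "events_table",
    "sites_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PuffEvent:
    """One puff measured in both modes through linked ROIs."""

    site_id: int | str
    window_s: tuple[float, float]
    amplitude_tirf: float
    amplitude_wf: float

    @property
    def ratio(self) -> float:
        if self.amplitude_wf <= 0:
            raise ValueError("ratio undefined: non-positive WF amplitude")
        return self.amplitude_tirf / self.amplitude_wf


@dataclass(frozen=True)
class SiteSummary:
    """Per-site aggregate over >= min_events puffs."""

    site_id: int | str
    n_events: int
    mean_ratio: float
    site_class: str  # superficial | intermediate | deep
    ratios: tuple[float, ...] = ()


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    return (times >= t0) & (times < t1)


def measure_amplitude(
    trace: Trace,
    window_s: tuple[float, float],
    event_windows_s: list[tuple[float, float]] | None = None,
) -> float:
    """Peak dF/F0 within a time window, baseline-offset corrected.

    The baseline offset is the median of the trace outside all event
    windows (``event_windows_s``, defaulting to just the measured
    window), which makes the amplitude invariant to any constant added
    to the trace.
    """
    inside = _window_mask(trace.times_s, window_s)
    if not np.any(inside):
        raise ValueError(f"window {window_s} contains no trace samples")
    if event_windows_s is None:
        event_windows_s = [window_s]
    outside = np.ones(len(trace.values), dtype=bool)
    for w in event_windows_s:
        outside &= ~_window_mask(trace.times_s, w)
    baseline = float(np.nanmedian(trace.values[outside])) if np.any(outside) else 0.0
    return float(np.nanmax(trace.values[inside]) - baseline)


def event_ratios(
    tirf_trace: Trace,
    wf_trace: Trace,
    events: list[tuple[float, float]],
    site_id: int | str = 0,
    wf_noise_floor: float = 0.02,
) -> list[PuffEvent]:
    """Per-event amplitudes in both modes and their TIRF/WF ratio.

    Both traces must come from linked ROIs on the de-interleaved stacks
    (equal frame counts to within one frame); amplitudes are measured on
    the same time windows in each mode.  Events whose WF amplitude falls
    below ``wf_noise_floor`` are excluded (their ratio would be noise-
    dominated) and logged.
    """
    if abs(len(tirf_trace.values) - len(wf_trace.values)) > 1:
        raise ValueError(
            "trace length mismatch beyond one frame: "
            f"{len(tirf_trace.values)} vs {len(wf_trace.values)}"
        )
    out = []
    for w in events:
        amp_t = measure_amplitude(tirf_trace, w, events)
        amp_w = measure_amplitude(wf_trace, w, events)
        if amp_w < wf_noise_floor:
            logger.info(
                "site %s: event at %.3f s excluded (WF amplitude %.4f "
                "below floor %.4f)", site_id, w[0], amp_w, wf_noise_floor,
            )
            continue
        out.append(PuffEvent(site_id, w, max(amp_t, 0.0), amp_w))
    return out


def summarize_sites(
    events: list[PuffEvent],
    min_events: int = 4,
    lo: float = 0.9,
    hi: float = 1.1,
) -> list[SiteSummary]:
    """Aggregate events by site and classify by mean TIRF/WF ratio.

    Sites with fewer than ``min_events`` events are excluded.  A mean
    ratio above ``hi`` marks a superficial site, below ``lo`` a deep one,
    in between intermediate.
    """
    by_site: dict = {}
    for e in events:
        by_site.setdefault(e.site_id, []).append(e)
    out = []
    for sid in sorted(by_site, key=str):
        evs = by_site[sid]
        if len(evs) < min_events:
            logger.info("site %s excluded: only %d events (< %d)",
                        sid, len(evs), min_events)
            continue
        ratios = tuple(e.ratio for e in evs)
        mean_ratio = float(np.mean(ratios))
        if mean_ratio > hi:
            cls = "superficial"
        elif mean_ratio < lo:
            cls = "deep"
        else:
            cls = "intermediate"
        out.append(SiteSummary(sid, len(evs), mean_ratio, cls, ratios))
    return out


def ratio_histogram(
    events: list[PuffEvent], bin_edges: np.ndarray | list[float]
) -> tuple[np.ndarray, float]:
    """Histogram of event amplitude ratios and the fraction above 1."""
    if not events:
        raise ValueError("no events to histogram")
    ratios = np.array([e.ratio for e in events])
    counts, _ = np.histogram(ratios, bins=np.asarray(bin_edges, dtype=float))
    return counts, float(np.mean(ratios > 1.0))


def estimate_depth(ratio: float, depth_nm: float, k: float = 1.0) -> float:
    """Invert ratio(z) = k exp(-z/d) for the release depth z (nm).

    ``depth_nm`` is the evanescent penetration depth d of the TIRF
    setting and ``k`` the calibration ratio expected for a site at z = 0
    (from config or a reference superficial site).  Ratios above k are
    clipped to z = 0 with a warning.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio > k:
        warnings.warn(
            f"ratio {ratio:.3f} exceeds calibration k={k:.3f}; clipping to z=0",
            stacklevel=2,
        )
        return 0.0
    return depth_nm * math.log(k / ratio)


def calibration_ratio(
    f0_tirf: np.ndarray, f0_wf: np.ndarray, roi: ROI | None = None
) -> float:
    """Estimate k = F0_wf / F0_tirf from measured resting-fluorescence maps.

    With per-mode dF/F0 normalization, a membrane-level release of equal
    physical size reports a TIRF/WF amplitude ratio equal to the ratio of
    resting baselines, because WF resting fluorescence includes the
    out-of-plane bulk that TIRF excludes.
    """
    if roi is not None:
        sy, sx = roi.slices()
        f0_tirf = f0_tirf[sy, sx]
        f0_wf = f0_wf[sy, sx]
    return float(np.nanmean(f0_wf) / np.nanmean(f0_tirf))


def detect_events(
    trace: Trace,
    threshold: float = 0.2,
    min_separation_s: float = 0.2,
    window_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Convenience threshold-crossing event finder (non-canonical).

    Returns candidate (start, stop) windows around upward threshold
    crossings of a dF/F0 trace.  This helper is a convenience only;
    quantitative analyses should use known event times (ground truth or
    curated intervals).
    """
    v = np.asarray(trace.values)
    above = v > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    windows: list[tuple[float, float]] = []
    last = -np.inf
    for i in crossings:
        t = float(trace.times_s[i])
        if t - last < min_separation_s:
            continue
        windows.append((t - 0.05, t + window_s))
        last = t
    return windows


def analyze_interleaved(
    stack: ImageStack,
    rois: list[ROI],
    events_by_roi: dict[str, list[tuple[float, float]]],
    baseline_range: tuple[int, int],
    depth_nm: float,
    black_level: float | None = None,
    tirf_first: bool | None = None,
    k: float | None = None,
    min_events: int = 4,
    wf_noise_floor: float = 0.02,
) -> dict:
    """End-to-end pipeline for a 2-mode interleaved recording.

    Subtracts the black level, de-interleaves into TIRF and WF substacks,
    forms dF/F0 stacks against ``baseline_range`` (frame indices within
    each substack), measures per-event amplitudes through linked ROIs,
    and returns events, site summaries, depth estimates and the
    calibration ratio k (estimated from the F0 maps unless given).
    """
    if black_level is None:
        black_level = stack.camera.black_level if stack.camera else 0.0
    work = subtract_black(stack, black_level)
    subs = deinterleave(work, 2)
    tags = [s.mode_tags[0] if s.mode_tags else None for s in subs]
    if tirf_first is None:
        tirf_idx = next(
            (i for i, t in enumerate(tags) if t in ("spinning_tirf", "stationary_tirf")),
            0,
        )
    else:
        tirf_idx = 0 if tirf_first else 1
    tirf_stack, wf_stack = subs[tirf_idx], subs[1 - tirf_idx]
    tirf_ratio = df_f0(tirf_stack, baseline_range)
    wf_ratio = df_f0(wf_stack, baseline_range)
    if k is None:
        k = calibration_ratio(tirf_ratio.f0, wf_ratio.f0)

    all_events: list[PuffEvent] = []
    for roi in rois:
        ev = events_by_roi.get(roi.label, [])
        if not ev:
            continue
        t_tr = roi_trace(tirf_ratio, roi)
        w_tr = roi_trace(wf_ratio, roi)
        all_events.extend(
            event_ratios(t_tr, w_tr, ev, site_id=roi.label,
                         wf_noise_floor=wf_noise_floor)
        )
    summaries = summarize_sites(all_events, min_events=min_events)
    depths = {
        s.site_id: estimate_depth(min(max(s.mean_ratio, 1e-9), k), depth_nm, k)
        for s in summaries
    }
    return {
        "events": all_events,
        "sites": summaries,
        "depths_nm": depths,
        "k": k,
        "tirf_ratio": tirf_ratio,
        "wf_ratio": wf_ratio,
    }


def events_table(events: list[PuffEvent]) -> pd.DataFrame:
    """Per-event table (site, window, amplitudes, ratio)."""
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in events],
            "t_start_s": [e.window_s[0] for e in events],
            "t_stop_s": [e.window_s[1] for e in events],
            "amplitude_tirf": [e.amplitude_tirf for e in events],
            "amplitude_wf": [e.amplitude_wf for e in events],
            "ratio": [e.ratio for e in events],
        }
    )


def sites_table(
    sites: list[SiteSummary], depths_nm: dict | None = None
) -> pd.DataFrame:
    """Per-site table (event count, mean ratio, class, optional depth)."""
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "n_events": [s.n_events for s in sites],
            "mean_ratio": [s.mean_ratio for s in sites],
            "class": [s.site_class for s in sites],
        }
    )
    if depths_nm is not None:
        df["depth_nm"] = [depths_nm.get(s.site_id, np.nan) for s in sites]
    return df
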