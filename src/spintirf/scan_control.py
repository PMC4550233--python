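"""Galvanometer scan-waveform synthesis and frame-interleave scheduling.

A pair of orthogonally mounted galvanometer mirrors, driven by 90
degree phase-shifted sine waves, spins the laser spot in a circle at the
objective back focal plane.  Drive amplitudes are expressed in normalized
units where 1.0 deflects the spot to the aperture edge; conversion to a
physical BFP radius lives in :mod:`spintirf.tirf_optics`.

Waveforms are generated as one-period lookup tables at a configurable
sample rate (1 MHz by default, matching typical DAC hardware).  Up to
three scan presets can be interleaved frame by frame, with a camera
trigger at the start of each frame, so that alternating frames are
acquired in different excitation modes (e.g. spinning-spot TIRF and
pseudo-widefield) for near-simultaneous multi-modal imaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tirf_optics import MODE_TAGS

__all__ = [
    "ScanPreset",
    "WaveformTable",
    "InterleaveSchedule",
    "UndersampledScanError",
    "ClippingError",
    "ScheduleError",
    "synthesize_waveforms",
    "build_schedule",
    "frame_triggers",
]

logger = logging.getLogger(__name__)

FULL_SCALE = 1.0  # normalized drive full scale (aperture radius at the BFP)


class UndersampledScanError(ValueError):
    """Sample rate too low to resolve the scan circle."""


class ClippingError(ValueError):
    """Drive waveform exceeds full scale after offsets."""


class ScheduleError(ValueError):
    """Invalid interleave schedule request."""


@dataclass(frozen=True)
class ScanPreset:
    """One galvo/laser setting, mirroring the driver's slider panel.

    ``radius`` is the common amplitude A of the sine (x) and cosine (y)
    drives; ``ellipticity`` scales the y amplitude relative to x and
    ``phase_offset_deg`` is added to the y channel beyond the nominal 90
    degrees, both compensating optical astigmatism and galvo mismatch.
    ``x_shift``/``y_shift`` recenter the circle.  For ``stationary_tirf``
    the spot is parked at a fixed azimuth (frequency is ignored).
    """

    label: str = "preset"
    frequency_hz: float = 200.0
    radius: float = 0.95
    ellipticity: float = 1.0
    phase_offset_deg: float = 0.0
    x_shift: float = 0.0
    y_shift: float = 0.0
    laser_id: int = 488
    laser_power: float = 1.0
    laser_on: bool = True
    mode_tag: str = "spinning_tirf"

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.ellipticity <= 0:
            raise ValueError("ellipticity must be positive")
        if not 0 <= self.laser_power <= 1:
            raise ValueError("laser_power must lie in [0, 1]")
        if self.mode_tag not in MODE_TAGS:
            raise ValueError(f"unknown mode_tag {self.mode_tag!r}")


@dataclass(frozen=True)
class WaveformTable:
    """Sampled one-period drive table with laser gating and triggers."""

    sample_rate: float
    x_samples: np.ndarray
    y_samples: np.ndarray
    laser_ttl: np.ndarray
    frame_trigger_indices: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x_samples)
        if not (len(self.y_samples) == n == len(self.laser_ttl)):
            raise ValueError("sample sequences must have equal length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.x_samples)) / self.sample_rate


def synthesize_waveforms(
    preset: ScanPreset, sample_rate: float = 1_000_000.0
) -> WaveformTable:
    """Build the one-period x/y drive lookup table for a preset.

    x(t) = x_shift + A sin(2 pi f t);
    y(t) = y_shift + e A cos(2 pi f t + phase_offset).

    The y channel leads x by 90 degrees plus the phase offset, giving a
    counterclockwise circular scan when viewed from the objective.  A
    stationary-spot preset parks the beam at (x_shift + A, y_shift); its
    table length still covers one nominal period so that interleaved
    frames remain commensurate.
    """
    ratio = sample_rate / preset.frequency_hz
    if ratio < 100:
        raise UndersampledScanError(
            f"sample_rate/frequency = {ratio:.1f} < 100; scan undersampled"
        )
    n = round(ratio)
    t = np.arange(n) / sample_rate
    if preset.mode_tag == "stationary_tirf":
        x = np.full(n, preset.x_shift + preset.radius)
        y = np.full(n, preset.y_shift)
    else:
        w = 2.0 * math.pi * preset.frequency_hz
        phase = math.radians(preset.phase_offset_deg)
        x = preset.x_shift + preset.radius * np.sin(w * t)
        y = preset.y_shift + preset.ellipticity * preset.radius * np.cos(
            w * t + phase
        )
    peak = max(np.abs(x).max(), np.abs(y).max())
    if peak > FULL_SCALE * (1 + 1e-12):
        raise ClippingError(
            f"drive peak {peak:.4f} exceeds full scale {FULL_SCALE}"
        )
    ttl = np.full(n, bool(preset.laser_on))
    return WaveformTable(
        sample_rate=sample_rate,
        x_samples=x,
        y_samples=y,
        laser_ttl=ttl,
        frame_trigger_indices=np.array([0]),
    )


@dataclass(frozen=True)
class InterleaveSchedule:
    """Frame-by-frame cycle of up to three scan presets.

    Frames cycle through ``presets`` in order (ABCABC...).  Spinning
    presets have their frequencies adjusted so an integer number of scan
    revolutions fits each exposure, guaranteeing complete 360 degree
    azimuthal averaging per frame.
    """

    presets: tuple[ScanPreset, ...]
    exposure_time_s: float
    n_frames: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.presets) <= 3:
            raise ScheduleError("schedule requires 1-3 presets")
        if self.exposure_time_s <= 0:
            raise ScheduleError("exposure_time must be positive")
        if self.n_frames < 1:
            raise ScheduleError("n_frames must be >= 1")

    @property
    def frame_mode_tags(self) -> list[str]:
        k = len(self.presets)
        return [self.presets[i % k].mode_tag for i in range(self.n_frames)]

    @property
    def frame_preset_labels(self) -> list[str]:
        k = len(self.presets)
        return [self.presets[i % k].label for i in range(self.n_frames)]

    def preset_for_frame(self, i: int) -> ScanPreset:
        return self.presets[i % len(self.presets)]


def build_schedule(
    presets: list[ScanPreset] | tuple[ScanPreset, ...],
    exposure_time_s: float,
    n_frames: int,
) -> InterleaveSchedule:
    """Build an interleave schedule, snapping frequencies to the exposure.

    For every scanning preset the number of revolutions per exposure is
    rounded to the nearest integer (at least 1) and the frequency adjusted
    accordingly, so each frame averages over complete 360 degree
    revolutions.  A requested frequency whose revolutions-per-exposure
    fall below 0.5 cannot be snapped and raises :class:`ScheduleError`.
    """
    if not presets:
        raise ScheduleError("empty preset list")
    adjusted: list[ScanPreset] = []
    for p in presets:
        if p.mode_tag == "stationary_tirf":
            adjusted.append(p)
            continue
        revs = exposure_time_s * p.frequency_hz
        if revs < 0.5:
            raise ScheduleError(
                f"exposure {exposure_time_s} s is shorter than half a "
                f"revolution at {p.frequency_hz} Hz ({p.label!r})"
            )
        n_revs = max(1, round(revs))
        f_new = n_revs / exposure_time_s
        if not math.isclose(f_new, p.frequency_hz, rel_tol=1e-12):
            logger.info(
                "preset %r: frequency adjusted %.6g -> %.6g Hz "
                "(%d revolutions per %.4g s exposure)",
                p.label, p.frequency_hz, f_new, n_revs, exposure_time_s,
            )
            p = replace(p, frequency_hz=f_new)
        adjusted.append(p)
    return InterleaveSchedule(tuple(adjusted), exposure_time_s, n_frames)


def frame_triggers(
    schedule: InterleaveSchedule,
) -> list[tuple[int, float, str]]:
    """Camera trigger list: (frame index, start time s, preset label).

    One TTL trigger is issued at the start of every frame so that each
    exposure spans the scheduled revolutions exactly.
    """
    return [
        (i, i * schedule.exposure_time_s, schedule.preset_for_frame(i).label)
        for i in range(schedule.n_frames)
    ]
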