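"""Synthetic specimens and EMCCD rendering of interleaved image stacks.

The specimens emulate the test preparations used to characterize a
spinning-spot TIRF illuminator: a thin fluorophore (rhodamine-like) film
adhering to the coverslip, sub-diffraction beads at known heights,
refractile occluders that cast directional shadows under stationary-spot
illumination, and Ca2+ puff sites releasing transient, localized signals
at known depths below the membrane.

Rendering combines a per-mode excitation field (lateral map x axial
weight) with the specimen's photon emission rates, draws Poisson photons,
applies stochastic electron-multiplying gain (gamma-distributed, excess
noise factor sqrt(2); a deterministic mean-gain mode exists for
exact-value tests), adds Gaussian read noise and a black level, and
quantizes to 16-bit counts.  Frames carry the interleave schedule's mode
tags so the downstream pipeline can de-interleave them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .scan_control import InterleaveSchedule, ScanPreset, build_schedule
from .tirf_optics import (
    ExcitationField,
    Occluder,
    OpticalConfig,
    SpeckleModel,
    mode_field,
)

__all__ = [
    "Bead",
    "PuffSite",
    "Specimen",
    "CameraModel",
    "ImageStack",
    "expected_signal",
    "render_stack",
    "make_scenario",
    "puff_event_windows",
    "SCENARIOS",
]


@dataclass(frozen=True)
class Bead:
    """Fluorescent microsphere at (x, y) um, height z nm, emitting
    ``brightness`` photons/s into its pixel under unit excitation."""

    x_um: float
    y_um: float
    z_nm: float = 0.0
    brightness: float = 1e5

    def __post_init__(self) -> None:
        if self.z_nm < 0:
            raise ValueError("bead z must be >= 0 (coverslip at z=0)")
        if self.brightness < 0:
            raise ValueError("bead brightness must be >= 0")


@dataclass(frozen=True)
class PuffSite:
    """A Ca2+ release site at depth ``z_nm`` producing transient puffs.

    ``amplitude`` is the peak fluorescence increase relative to the local
    resting near-membrane fluorescence (i.e. the peak dF/F0 a mode with
    full axial visibility would report).  Each event rises linearly over
    ``rise_time_ms`` and decays exponentially with ``decay_time_ms``
    (puffs last tens to a few hundred ms); the spatial footprint is a 2-D
    Gaussian of ``spatial_sigma_um``.
    """

    x_um: float
    y_um: float
    z_nm: float
    event_times_s: tuple[float, ...]
    amplitude: float = 1.0
    rise_time_ms: float = 10.0
    decay_time_ms: float = 100.0
    spatial_sigma_um: float = 0.5

    def __post_init__(self) -> None:
        if self.z_nm < 0:
            raise ValueError("site depth must be >= 0")
        if not self.rise_time_ms < self.decay_time_ms:
            raise ValueError("rise_time must be shorter than decay_time")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def time_course(self, t: float) -> float:
        """Dimensionless release time course (0..1) at time t (s)."""
        rise = self.rise_time_ms / 1000.0
        tau = self.decay_time_ms / 1000.0
        total = 0.0
        for t0 in self.event_times_s:
            dt = t - t0
            if dt <= 0:
                continue
            if dt < rise:
                total += dt / rise
            else:
                total += math.exp(-(dt - rise) / tau)
        return total


@dataclass(frozen=True)
class Specimen:
    """Everything in front of the objective.

    ``film_brightness`` is the photon emission rate (photons/s/pixel)
    of the coverslip-adherent fluorophore film at z = 0 under unit
    excitation; ``bulk_brightness_per_um`` is the rate contributed per
    micrometre of excited depth by indicator in the cytosolic bulk, which
    is what makes widefield resting fluorescence exceed TIRF resting
    fluorescence.
    """

    film_brightness: float = 0.0
    bulk_brightness_per_um: float = 0.0
    beads: tuple[Bead, ...] = ()
    occluders: tuple[Occluder, ...] = ()
    puff_sites: tuple[PuffSite, ...] = ()

    def __post_init__(self) -> None:
        if self.film_brightness < 0 or self.bulk_brightness_per_um < 0:
            raise ValueError("brightness rates must be >= 0")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera description (128x128 frame-transfer device by default)."""

    pixel_size_um: float = 0.4
    frame_shape: tuple[int, int] = (128, 128)
    em_gain: float = 30.0
    read_noise: float = 5.0     # counts RMS
    black_level: float = 100.0  # counts
    qe: float = 0.9
    gain_mode: str = "gamma"    # "gamma" (stochastic) or "mean" (exact)

    def __post_init__(self) -> None:
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")
        if self.black_level < 0:
            raise ValueError("black_level must be >= 0")
        if not 0 < self.qe <= 1:
            raise ValueError("qe must lie in (0, 1]")
        if self.gain_mode not in ("gamma", "mean"):
            raise ValueError("gain_mode must be 'gamma' or 'mean'")


@dataclass
class ImageStack:
    """Frames + per-frame metadata: the simulator/pipeline interchange."""

    frames: np.ndarray                 # (n, h, w) integer counts
    mode_tags: list[str] | None
    exposure_time_s: float
    timestamps_s: np.ndarray
    camera: CameraModel | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.frames)
        if self.mode_tags is not None and len(self.mode_tags) != n:
            raise ValueError("mode_tags length must match frame count")
        if len(self.timestamps_s) != n:
            raise ValueError("timestamps length must match frame count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def expected_signal(
    specimen: Specimen,
    fieldmap: ExcitationField,
    t: float = 0.0,
    cell_thickness_um: float = 5.0,
) -> np.ndarray:
    """Expected photon emission rate map (photons/s/pixel) at time t.

    Sums film, bulk, bead and puff contributions, each weighted by the
    lateral excitation map and the axial weight at the component's depth.
    A puff's signal is its amplitude times the local resting film rate,
    shaped by its Gaussian footprint and release time course.
    """
    lat = fieldmap.lateral
    shape = lat.shape
    rate = np.zeros(shape, dtype=float)

    if specimen.film_brightness > 0:
        rate += specimen.film_brightness * fieldmap.axial.weight(0.0) * lat
    if specimen.bulk_brightness_per_um > 0:
        rate += (
            specimen.bulk_brightness_per_um
            * fieldmap.axial.integral_um(cell_thickness_um)
            * lat
        )

    px = fieldmap.pixel_size_um
    ny, nx = shape
    for b in specimen.beads:
        ix = int(round(b.x_um / px + (nx - 1) / 2.0))
        iy = int(round(b.y_um / px + (ny - 1) / 2.0))
        if 0 <= iy < ny and 0 <= ix < nx:
            rate[iy, ix] += b.brightness * lat[iy, ix] * fieldmap.axial.weight(
                b.z_nm
            )

    _add_puff_rate(rate, specimen, fieldmap, t)
    return rate


def _add_puff_rate(
    rate: np.ndarray,
    specimen: Specimen,
    fieldmap: ExcitationField,
    t: float,
) -> None:
    """Add the puff contributions at time t to ``rate`` in place.

    Each footprint is evaluated on a local +/- 5 sigma patch only; beyond
    that the Gaussian is below 4e-6 of its peak.
    """
    px = fieldmap.pixel_size_um
    ny, nx = rate.shape
    lat = fieldmap.lateral
    for s in specimen.puff_sites:
        tc = s.time_course(t)
        if tc <= 0:
            continue
        half = max(1, int(math.ceil(5.0 * s.spatial_sigma_um / px)))
        cx = s.x_um / px + (nx - 1) / 2.0
        cy = s.y_um / px + (ny - 1) / 2.0
        x0 = max(0, int(math.floor(cx)) - half)
        x1 = min(nx, int(math.floor(cx)) + half + 1)
        y0 = max(0, int(math.floor(cy)) - half)
        y1 = min(ny, int(math.floor(cy)) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = (np.arange(x0, x1) - (nx - 1) / 2.0) * px
        ys = (np.arange(y0, y1) - (ny - 1) / 2.0) * px
        foot = np.exp(
            -((xs[None, :] - s.x_um) ** 2 + (ys[:, None] - s.y_um) ** 2)
            / (2.0 * s.spatial_sigma_um**2)
        )
        rate[y0:y1, x0:x1] += (
            s.amplitude
            * specimen.film_brightness
            * tc
            * foot
            * lat[y0:y1, x0:x1]
            * fieldmap.axial.weight(s.z_nm)
        )


def _apply_camera(
    photons: np.ndarray, camera: CameraModel, rng: np.random.Generator
) -> np.ndarray:
    """Electron multiplication + read noise + black level -> uint16 counts."""
    if camera.gain_mode == "mean":
        counts = photons * camera.em_gain
    else:
        counts = np.zeros_like(photons, dtype=float)
        pos = photons > 0
        if np.any(pos):
            counts[pos] = rng.standard_gamma(photons[pos]) * camera.em_gain
    if camera.read_noise > 0:
        counts = counts + rng.normal(0.0, camera.read_noise, counts.shape)
    counts = counts + camera.black_level
    counts = np.rint(counts)
    if np.any(counts > 65535):
        warnings.warn("expected counts exceed 16-bit range; clipping", stacklevel=3)
    return np.clip(counts, 0, 65535).astype(np.uint16)


def render_stack(
    specimen: Specimen,
    schedule: InterleaveSchedule,
    cfg: OpticalConfig = OpticalConfig(),
    camera: CameraModel = CameraModel(),
    seed: int = 0,
    speckle: SpeckleModel | None = None,
    n_azimuths: int = 360,
    stationary_azimuth_deg: float = 0.0,
) -> ImageStack:
    """Render an interleaved, mode-tagged image stack.

    One excitation field is synthesized per distinct preset; each frame
    draws Poisson photons at qe x rate x exposure x laser power, passes
    them through the EM register and read-out chain, and is tagged with
    the schedule's mode label.  Randomness comes from a single seed,
    forked per frame by frame index, so results are independent of
    rendering order.
    """
    if speckle is None:
        speckle = SpeckleModel(seed=seed)
    fields: dict[str, ExcitationField] = {}
    static_rates: dict[str, np.ndarray] = {}
    static_specimen = replace(specimen, puff_sites=())
    for p in schedule.presets:
        if p.label in fields:
            continue
        fld = mode_field(
            p.mode_tag, p.radius, speckle, specimen.occluders, cfg,
            camera.frame_shape, camera.pixel_size_um,
            n_azimuths=n_azimuths,
            stationary_azimuth_deg=stationary_azimuth_deg,
            wavelength_nm=float(p.laser_id),
        )
        fields[p.label] = fld
        static_rates[p.label] = expected_signal(
            static_specimen, fld, 0.0, cfg.cell_thickness_um
        )

    n = schedule.n_frames
    h, w = camera.frame_shape
    frames = np.empty((n, h, w), dtype=np.uint16)
    timestamps = np.arange(n) * schedule.exposure_time_s
    dynamic = len(specimen.puff_sites) > 0
    root = np.random.SeedSequence(seed)
    for i in range(n):
        p = schedule.preset_for_frame(i)
        fld = fields[p.label]
        if dynamic:
            rate = static_rates[p.label].copy()
            _add_puff_rate(rate, specimen, fld, float(timestamps[i]))
        else:
            rate = static_rates[p.label]
        scale = p.laser_power if p.laser_on else 0.0
        mean_photons = camera.qe * rate * schedule.exposure_time_s * scale
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(i,)
        ))
        photons = rng.poisson(mean_photons).astype(float)
        frames[i] = _apply_camera(photons, camera, rng)

    return ImageStack(
        frames=frames,
        mode_tags=[schedule.presets[i % len(schedule.presets)].mode_tag
                   for i in range(n)],
        exposure_time_s=schedule.exposure_time_s,
        timestamps_s=timestamps,
        camera=camera,
        meta={
            "seed": seed,
            "preset_labels": [p.label for p in schedule.presets],
            "n_azimuths": n_azimuths,
        },
    )


# --------------------------------------------------------------------------
# Packaged scenarios


def _spin_preset(label="spin_tirf", radius=0.97, laser_id=488, **kw) -> ScanPreset:
    return ScanPreset(label=label, mode_tag="spinning_tirf", radius=radius,
                      laser_id=laser_id, **kw)


def puff_event_windows(
    site: PuffSite, pre_s: float = 0.02, post_decays: float = 4.0
) -> list[tuple[float, float]]:
    """Ground-truth measurement windows around each event of a site."""
    rise = site.rise_time_ms / 1000.0
    tau = site.decay_time_ms / 1000.0
    return [
        (t0 - pre_s, t0 + rise + post_decays * tau)
        for t0 in site.event_times_s
    ]


def _film_beads(seed: int, o: dict):
    """Fluorophore film + beads on the coverslip; stationary vs spinning."""
    rng = np.random.default_rng(seed)
    exposure = o.pop("exposure_time_s", 0.005)
    n_frames = o.pop("n_frames", 600)
    n_beads = o.pop("n_beads", 12)
    film = o.pop("film_photons_per_frame", 100.0)
    radius = o.pop("scan_radius", 0.97)
    modes = o.pop("modes", ["spinning_tirf"])
    qe = CameraModel().qe
    beads = tuple(
        Bead(x_um=float(rng.uniform(-20, 20)), y_um=float(rng.uniform(-20, 20)),
             z_nm=0.0, brightness=10.0 * film / (qe * exposure))
        for _ in range(n_beads)
    )
    specimen = Specimen(
        film_brightness=film / (qe * exposure),
        beads=beads,
    )
    presets = [
        ScanPreset(label=f"{m}_{j}", mode_tag=m, radius=radius)
        for j, m in enumerate(modes)
    ]
    schedule = build_schedule(presets, exposure, n_frames)
    return specimen, schedule


def _shadow_cells(seed: int, o: dict):
    """Film with refractile occluders; interleaved stationary/spinning."""
    rng = np.random.default_rng(seed)
    exposure = o.pop("exposure_time_s", 0.005)
    n_frames = o.pop("n_frames", 20)
    film = o.pop("film_photons_per_frame", 100.0)
    radius = o.pop("scan_radius", 0.97)
    n_occluders = o.pop("n_occluders", 3)
    attenuation = o.pop("attenuation", 0.6)
    qe = CameraModel().qe
    occluders = tuple(
        Occluder(
            x_um=float(rng.uniform(-12, 12)), y_um=float(rng.uniform(-12, 12)),
            radius_um=float(rng.uniform(1.5, 3.0)), attenuation=attenuation,
        )
        for _ in range(n_occluders)
    )
    specimen = Specimen(
        film_brightness=film / (qe * exposure), occluders=occluders
    )
    presets = [
        ScanPreset(label="stat", mode_tag="stationary_tirf", radius=radius),
        ScanPreset(label="spin", mode_tag="spinning_tirf", radius=radius),
    ]
    schedule = build_schedule(presets, exposure, n_frames)
    return specimen, schedule


# Scan radius giving a ~200 nm evanescent depth at 488 nm with the default
# objective (r_norm = n1 sin(theta)/NA with n1 sin(theta) = 1.3441).
PUFF_SCAN_RADIUS = 0.9270


def _puff_depths(seed: int, o: dict):
    """Puff sites at varying depth, imaged in alternating TIRF/WF frames.

    Sites release >= 4 events each so downstream site classification can
    apply its inclusion rule; depths default to uniform over 0-600 nm.
    """
    rng = np.random.default_rng(seed)
    exposure = o.pop("exposure_time_s", 0.005)
    n_sites = o.pop("n_sites", 6)
    n_events = o.pop("n_events", 6)
    amplitude = o.pop("amplitude", 1.0)
    film = o.pop("film_photons_per_frame", 500.0)
    bulk_per_um = o.pop("bulk_photons_per_frame_per_um", None)
    radius = o.pop("scan_radius", PUFF_SCAN_RADIUS)
    depths = o.pop("depths_nm", None)
    baseline_s = o.pop("baseline_s", 1.0)
    spacing_s = o.pop("event_spacing_s", 0.6)
    if n_events < 4:
        raise ValueError("puff sites need >= 4 events for site classification")
    if depths is None:
        depths = rng.uniform(0.0, 600.0, n_sites)
    else:
        depths = np.asarray(depths, dtype=float)
        n_sites = len(depths)
    qe = CameraModel().qe
    if bulk_per_um is None:
        bulk_per_um = 0.06 * film  # WF resting F ~1.3x TIRF resting F

    # Lay sites on a coarse grid so 3x3 um ROIs never overlap.
    n_side = math.ceil(math.sqrt(n_sites))
    pitch = 40.0 / (n_side + 1)  # camera field is ~51 um; keep margins
    positions = []
    for j in range(n_sites):
        gx, gy = j % n_side, j // n_side
        positions.append((
            -20.0 + (gx + 1) * pitch + float(rng.uniform(-0.5, 0.5)),
            -20.0 + (gy + 1) * pitch + float(rng.uniform(-0.5, 0.5)),
        ))

    sites = []
    t_end = baseline_s
    for (x, y), z in zip(positions, depths):
        times = tuple(
            baseline_s + 0.1 + k * spacing_s + float(rng.uniform(0.0, 0.1))
            for k in range(n_events)
        )
        t_end = max(t_end, times[-1] + 0.5)
        sites.append(PuffSite(
            x_um=x, y_um=y, z_nm=float(z), event_times_s=times,
            amplitude=amplitude,
        ))

    n_frames = o.pop("n_frames", None)
    if n_frames is None:
        n_frames = 2 * math.ceil(t_end / (2 * exposure))
    specimen = Specimen(
        film_brightness=film / (qe * exposure),
        bulk_brightness_per_um=bulk_per_um / (qe * exposure),
        puff_sites=tuple(sites),
    )
    presets = [
        ScanPreset(label="tirf", mode_tag="spinning_tirf", radius=radius),
        ScanPreset(label="wf", mode_tag="widefield", radius=0.3),
    ]
    schedule = build_schedule(presets, exposure, n_frames)
    return specimen, schedule


def _triple_interleave(seed: int, o: dict):
    """Two-laser, three-preset interleave: TIRF 488 / TIRF 532 / skimming 532."""
    rng = np.random.default_rng(seed)
    exposure = o.pop("exposure_time_s", 0.005)
    n_frames = o.pop("n_frames", 30)
    film = o.pop("film_photons_per_frame", 100.0)
    radius = o.pop("scan_radius", 0.97)
    qe = CameraModel().qe
    beads = tuple(
        Bead(x_um=float(rng.uniform(-15, 15)), y_um=float(rng.uniform(-15, 15)),
             z_nm=float(z), brightness=10.0 * film / (qe * exposure))
        for z in (0.0, 300.0, 1500.0)
    )
    specimen = Specimen(film_brightness=film / (qe * exposure), beads=beads)
    presets = [
        ScanPreset(label="tirf488", mode_tag="spinning_tirf",
                   radius=radius, laser_id=488),
        ScanPreset(label="tirf532", mode_tag="spinning_tirf",
                   radius=radius, laser_id=532),
        ScanPreset(label="skim532", mode_tag="skimming",
                   radius=0.90, laser_id=532),
    ]
    schedule = build_schedule(presets, exposure, n_frames)
    return specimen, schedule


SCENARIOS = {
    "film_beads": _film_beads,
    "shadow_cells": _shadow_cells,
    "puff_depths": _puff_depths,
    "triple_interleave": _triple_interleave,
}


def make_scenario(
    name: str, seed: int = 0, **overrides
) -> tuple[Specimen, InterleaveSchedule]:
    """Construct one of the packaged synthetic scenarios.

    Deterministic given ``seed``.  ``overrides`` replace scenario defaults
    (e.g. ``n_frames``, ``n_beads=0``, ``depths_nm=[0, 200, 400]``);
    unknown keys raise ``ValueError``.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    o = dict(overrides)
    specimen, schedule = SCENARIOS[name](seed, o)
    if o:
        raise ValueError(f"unknown overrides for scenario {name!r}: {sorted(o)}")
    return specimen, schedule
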