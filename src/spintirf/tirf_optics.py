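"""Physical model of through-the-objective TIRF excitation.

Through-the-objective TIRF focuses the excitation laser to a spot at the
back focal plane (BFP) of a high-NA objective.  The radial position ``r`` of
that spot sets the polar angle of the collimated beam emerging into the
specimen (Abbe sine condition, ``r = f n1 sin(theta)``), while the azimuthal
position sets the illumination direction.  Beyond the critical angle
``theta_c = arcsin(n2/n1)`` the beam totally internally reflects at the
glass-water interface and only an evanescent field, decaying exponentially
with distance ``z`` from the coverslip with characteristic depth

    d = lambda / (4 pi sqrt(n1^2 sin^2(theta) - n2^2)),

excites fluorophores.  A stationary spot yields a field marred by coherent
interference fringes and by shadows cast by refractile structures; spinning
the spot around the BFP annulus averages these azimuth-dependent
irregularities over a camera exposure.

This module provides the BFP-radius/angle mapping, critical angle and
penetration depth, and a phenomenological lateral-field model (Gaussian beam
envelope x cosine-fringe interference x directional occluder shadows) from
which stationary-spot, spinning-spot, pseudo-widefield and skimming-plane
excitation fields are synthesized on the camera pixel grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticalConfig",
    "SpeckleModel",
    "Occluder",
    "AxialModel",
    "ExcitationField",
    "NoTIRError",
    "OutsideApertureError",
    "SubcriticalAngleError",
    "critical_angle",
    "bfp_radius_to_angle",
    "angle_to_bfp_radius",
    "penetration_depth",
    "depth_for_scan_radius",
    "single_azimuth_field",
    "spinning_field",
    "mode_field",
]


class NoTIRError(ValueError):
    """Total internal reflection is impossible (n_water >= n_glass)."""


class OutsideApertureError(ValueError):
    """Requested BFP radius lies outside the objective aperture."""


class SubcriticalAngleError(ValueError):
    """Incidence angle (or scan radius) below the critical angle for TIR."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the illuminator and objective.

    Defaults describe a 60x NA 1.45 oil-immersion TIRF objective (glass
    n1 = 1.515, aqueous specimen n2 = 1.33) with a 180 mm tube lens, i.e.
    an objective focal length of 3 mm, and a usable illumination field of
    roughly 50 um on a side.
    """

    wavelength_nm: float = 488.0
    n_glass: float = 1.515
    n_water: float = 1.33
    numerical_aperture: float = 1.45
    objective_focal_length_mm: float = 3.0
    field_size_um: float = 51.2
    cell_thickness_um: float = 5.0       # widefield axial extent
    skimming_depth_nm: float = 1000.0    # effective skimming-plane depth
    beam_sigma_um: float | None = 100.0  # Gaussian envelope; None = flat
    shadow_recovery_um: float = 5.0      # shadow attenuation recovery length

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if not self.n_water < self.n_glass:
            raise NoTIRError(
                f"n_water ({self.n_water}) must be below n_glass ({self.n_glass})"
            )
        if self.numerical_aperture > self.n_glass:
            raise ValueError("numerical_aperture cannot exceed n_glass")

    @property
    def critical_angle_deg(self) -> float:
        return critical_angle(self.n_glass, self.n_water)

    @property
    def max_angle_deg(self) -> float:
        """Polar angle at the aperture edge, arcsin(NA/n1)."""
        return math.degrees(math.asin(self.numerical_aperture / self.n_glass))

    @property
    def aperture_radius_mm(self) -> float:
        """BFP radius of the aperture edge, f*NA."""
        return self.objective_focal_length_mm * self.numerical_aperture

    @property
    def tir_radius_mm(self) -> float:
        """BFP radius at which TIR sets in, f*n2."""
        return self.objective_focal_length_mm * self.n_water


def critical_angle(n_glass: float, n_water: float) -> float:
    """Critical angle for total internal reflection, in degrees.

    ``theta_c = arcsin(n_water / n_glass)`` at a glass-water interface.
    """
    if n_water <= 0 or n_glass <= 0:
        raise ValueError("refractive indices must be positive")
    if n_water > n_glass:
        raise NoTIRError(
            "no total internal reflection: n_water > n_glass "
            f"({n_water} > {n_glass})"
        )
    return math.degrees(math.asin(n_water / n_glass))


def bfp_radius_to_angle(r_mm: float, cfg: OpticalConfig) -> float:
    """Polar beam angle (degrees) for a BFP spot at radius ``r_mm``.

    Abbe sine condition: ``r = f n1 sin(theta)``.
    """
    if r_mm < 0:
        raise OutsideApertureError("BFP radius must be non-negative")
    if r_mm > cfg.aperture_radius_mm * (1 + 1e-12):
        raise OutsideApertureError(
            f"BFP radius {r_mm:.4g} mm outside aperture "
            f"(f*NA = {cfg.aperture_radius_mm:.4g} mm)"
        )
    s = min(r_mm / (cfg.objective_focal_length_mm * cfg.n_glass), 1.0)
    return math.degrees(math.asin(s))


def angle_to_bfp_radius(theta_deg: float, cfg: OpticalConfig) -> float:
    """Inverse of :func:`bfp_radius_to_angle`."""
    if not 0 <= theta_deg <= 90:
        raise ValueError("theta must lie in [0, 90] degrees")
    r = cfg.objective_focal_length_mm * cfg.n_glass * math.sin(
        math.radians(theta_deg)
    )
    if r > cfg.aperture_radius_mm * (1 + 1e-12):
        raise OutsideApertureError(
            f"angle {theta_deg:.3f} deg maps outside the aperture"
        )
    return r


def penetration_depth(
    wavelength_nm: float, theta_deg: float, cfg: OpticalConfig
) -> float:
    """Evanescent-field 1/e penetration depth in nm.

    ``d = lambda / (4 pi sqrt(n1^2 sin^2(theta) - n2^2))``; defined only
    above the critical angle, where it decreases monotonically with theta
    and diverges as theta approaches theta_c from above.
    """
    theta_c = critical_angle(cfg.n_glass, cfg.n_water)
    if theta_deg <= theta_c:
        raise SubcriticalAngleError(
            f"theta = {theta_deg:.4f} deg is below the critical angle "
            f"({theta_c:.4f} deg); no evanescent field"
        )
    arg = (cfg.n_glass * math.sin(math.radians(theta_deg))) ** 2 - cfg.n_water**2
    return wavelength_nm / (4.0 * math.pi * math.sqrt(arg))


def depth_for_scan_radius(
    scan_radius: float, cfg: OpticalConfig, wavelength_nm: float | None = None
) -> float:
    """Penetration depth (nm) for a normalized scan radius.

    ``scan_radius`` is the drive amplitude in units of the full aperture
    radius (1.0 = f*NA at the BFP edge).
    """
    wl = cfg.wavelength_nm if wavelength_nm is None else wavelength_nm
    r_mm = scan_radius * cfg.aperture_radius_mm
    theta = bfp_radius_to_angle(r_mm, cfg)
    return penetration_depth(wl, theta, cfg)


# --------------------------------------------------------------------------
# Lateral field model


@dataclass(frozen=True)
class SpeckleModel:
    """Phenomenological interference-fringe model.

    The coherent laser light picks up spurious reflections at surfaces in
    the optical path; the resulting fringes are modelled as a sum of
    ``n_components`` cosine gratings whose orientations track the
    illumination azimuth (plus a fixed random jitter per component) and
    whose phases and periods are drawn once from ``seed``.  ``contrast``
    is the peak modulation depth of the summed pattern.
    """

    n_components: int = 4
    contrast: float = 0.3
    fringe_period_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must lie in [0, 1]")

    def component_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-component (orientation jitter deg, phase rad, period um)."""
        rng = np.random.default_rng(self.seed)
        jitter = rng.uniform(-25.0, 25.0, self.n_components)
        phases = rng.uniform(0.0, 2.0 * math.pi, self.n_components)
        periods = self.fringe_period_um * rng.uniform(
            0.6, 1.6, self.n_components
        )
        return jitter, phases, periods


@dataclass(frozen=True)
class Occluder:
    """A refractile obstacle (organelle, dirt speck) casting a shadow.

    The shadow is a wedge of multiplicative attenuation directed along the
    beam propagation azimuth, recovering exponentially with distance.
    """

    x_um: float
    y_um: float
    radius_um: float
    attenuation: float = 0.6

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("occluder radius must be positive")
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation must lie in [0, 1]")


def pixel_grid(
    shape: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (um) with the origin at the field center.

    Returns ``(xx, yy)`` arrays of the given ``shape`` (rows = y, cols = x).
    """
    ny, nx = shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_um
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size_um
    return np.meshgrid(xs, ys)


def single_azimuth_field(
    azimuth_deg: float,
    speckle: SpeckleModel,
    occluders: list[Occluder] | tuple[Occluder, ...] = (),
    cfg: OpticalConfig = OpticalConfig(),
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.4,
) -> np.ndarray:
    """Lateral excitation map for one illumination azimuth, mean 1.

    The map is the product of a Gaussian beam envelope, an interference
    pattern of azimuth-locked cosine fringes, and a directional shadow mask
    behind each occluder, normalized to unit mean.  Azimuth 0 degrees
    propagates along +x; a shadow therefore falls on the +x side of its
    occluder.
    """
    xx, yy = pixel_grid(shape, pixel_size_um)

    if cfg.beam_sigma_um is None:
        fieldmap = np.ones(shape, dtype=float)
    else:
        s2 = 2.0 * cfg.beam_sigma_um**2
        fieldmap = np.exp(-(xx**2 + yy**2) / s2)

    if speckle.contrast > 0:
        jitter, phases, periods = speckle.component_params()
        acc = np.zeros(shape, dtype=float)
        for j, ph, per in zip(jitter, phases, periods):
            ang = math.radians(azimuth_deg + j)
            k = 2.0 * math.pi / per
            proj = xx * math.cos(ang) + yy * math.sin(ang)
            acc += np.cos(k * proj + ph)
        fieldmap = fieldmap * (1.0 + speckle.contrast * acc / speckle.n_components)

    if occluders:
        a = math.radians(azimuth_deg)
        ux, uy = math.cos(a), math.sin(a)
        for occ in occluders:
            rx, ry = xx - occ.x_um, yy - occ.y_um
            s = rx * ux + ry * uy            # downstream distance
            p = -rx * uy + ry * ux           # perpendicular offset
            in_wedge = (s > 0) & (np.abs(p) <= occ.radius_um)
            factor = np.ones(shape, dtype=float)
            factor[in_wedge] = 1.0 - occ.attenuation * np.exp(
                -s[in_wedge] / cfg.shadow_recovery_um
            )
            fieldmap = fieldmap * factor

    return fieldmap / fieldmap.mean()


@dataclass(frozen=True)
class AxialModel:
    """Axial excitation weight profile w(z), with z in nm above the glass.

    kinds: ``evanescent`` and ``skimming`` are exponentials with 1/e depth
    ``depth_nm``; ``uniform`` has unit weight for 0 <= z <= depth_nm and
    zero beyond (a slab the thickness of the cell).
    """

    kind: str
    depth_nm: float

    _KINDS = ("evanescent", "uniform", "skimming")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown axial model kind {self.kind!r}")
        if self.depth_nm <= 0:
            raise ValueError("depth_nm must be positive")

    def weight(self, z_nm):
        """Excitation weight at depth z (nm); vectorized."""
        z = np.asarray(z_nm, dtype=float)
        if self.kind == "uniform":
            w = ((z >= 0) & (z <= self.depth_nm)).astype(float)
        else:
            w = np.exp(-np.maximum(z, 0.0) / self.depth_nm)
        return w if w.ndim else float(w)

    def integral_um(self, z_max_um: float) -> float:
        """Integral of w(z) dz over [0, z_max_um], in um."""
        zmax_nm = z_max_um * 1000.0
        if self.kind == "uniform":
            return min(zmax_nm, self.depth_nm) / 1000.0
        d = self.depth_nm
        return d * (1.0 - math.exp(-zmax_nm / d)) / 1000.0


@dataclass(frozen=True)
class ExcitationField:
    """A complete excitation-field description for one imaging mode."""

    lateral: np.ndarray          # 2-D map, mean 1
    axial: AxialModel
    mode_tag: str
    azimuths_deg: tuple[float, ...]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if np.any(self.lateral < 0):
            raise ValueError("lateral map must be non-negative")
        if abs(float(self.lateral.mean()) - 1.0) > 1e-6:
            raise ValueError("lateral map must be mean-normalized to 1")


def spinning_field(
    n_azimuths: int,
    speckle: SpeckleModel,
    occluders: list[Occluder] | tuple[Occluder, ...] = (),
    cfg: OpticalConfig = OpticalConfig(),
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.4,
    depth_nm: float | None = None,
    mode_tag: str = "spinning_tirf",
    axial: AxialModel | None = None,
) -> ExcitationField:
    """Azimuthally averaged excitation field over equally spaced angles.

    With one azimuth this reduces to the stationary-spot field; as
    ``n_azimuths`` grows the azimuth-dependent fringes and shadows average
    out and the lateral map converges to the smooth beam envelope.
    """
    if n_azimuths < 1:
        raise ValueError("n_azimuths must be >= 1")
    azimuths = tuple(360.0 * i / n_azimuths for i in range(n_azimuths))
    acc = np.zeros(shape, dtype=float)
    for az in azimuths:
        acc += single_azimuth_field(az, speckle, occluders, cfg, shape, pixel_size_um)
    lateral = acc / n_azimuths
    lateral = lateral / lateral.mean()
    if axial is None:
        if depth_nm is None:
            raise ValueError("either depth_nm or axial must be given")
        axial = AxialModel("evanescent", depth_nm)
    return ExcitationField(lateral, axial, mode_tag, azimuths, pixel_size_um)


MODE_TAGS = ("spinning_tirf", "stationary_tirf", "widefield", "skimming")


def mode_field(
    mode_tag: str,
    scan_radius: float,
    speckle: SpeckleModel,
    occluders: list[Occluder] | tuple[Occluder, ...] = (),
    cfg: OpticalConfig = OpticalConfig(),
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.4,
    n_azimuths: int = 360,
    stationary_azimuth_deg: float = 0.0,
    wavelength_nm: float | None = None,
) -> ExcitationField:
    """Excitation field for one of the four illumination modes.

    ``scan_radius`` is normalized (1.0 = aperture edge).  TIRF modes
    require the scan radius to exceed the TIR threshold n2/NA and use an
    evanescent axial model with the depth set by the radius; pseudo-
    widefield uses a uniform slab the thickness of the cell; skimming-plane
    an exponential with an effective depth of order 1 um.
    """
    if mode_tag not in MODE_TAGS:
        raise ValueError(f"unknown mode_tag {mode_tag!r}")
    wl = cfg.wavelength_nm if wavelength_nm is None else wavelength_nm

    if mode_tag in ("spinning_tirf", "stationary_tirf"):
        d = depth_for_scan_radius(scan_radius, cfg, wl)  # raises if subcritical
        axial = AxialModel("evanescent", d)
    elif mode_tag == "widefield":
        axial = AxialModel("uniform", cfg.cell_thickness_um * 1000.0)
    else:  # skimming
        axial = AxialModel("skimming", cfg.skimming_depth_nm)

    if mode_tag == "stationary_tirf":
        lateral = single_azimuth_field(
            stationary_azimuth_deg, speckle, occluders, cfg, shape, pixel_size_um
        )
        return ExcitationField(
            lateral, axial, mode_tag, (stationary_azimuth_deg,), pixel_size_um
        )
    return spinning_field(
        n_azimuths, speckle, occluders, cfg, shape, pixel_size_um,
        mode_tag=mode_tag, axial=axial,
    )
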