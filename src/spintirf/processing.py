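"""Image-stack processing: black-level subtraction, de-interleaving,
dF/F0 normalization, projections, ROI traces, linescans and uniformity
metrics.

Interleaved recordings alternate excitation presets frame by frame; the
pipeline splits them into per-mode stacks, normalizes each pixel to its
mean over a range of resting baseline frames (the pseudo-ratio
dF/F0 = (F - F0)/F0, which cancels static excitation non-uniformity and
any common gain), and extracts traces from regions of interest that are
linked across the de-interleaved stacks so both modes are measured at
identical pixel coordinates.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import profile_line

from .sim_camera import ImageStack

__all__ = [
    "RatioStack",
    "ROI",
    "Trace",
    "TagMismatchError",
    "EmptyBaselineError",
    "subtract_black",
    "deinterleave",
    "interleave",
    "df_f0",
    "max_projection",
    "roi_trace",
    "linescan",
    "uniformity_metrics",
    "frame_mean_stability",
    "export_traces_ascii",
    "UniformityMetrics",
]


class TagMismatchError(ValueError):
    """Frame mode tags are inconsistent with the de-interleave stride."""


class EmptyBaselineError(ValueError):
    """Baseline range contains no usable frames."""


@dataclass
class RatioStack:
    """Pseudo-ratio dF/F0 stack.

    ``frames[t] = (F[t] - F0) / F0`` per pixel, with F0 the per-pixel mean
    over the baseline frame range; pixels whose F0 falls below the floor
    are NaN-masked to keep the ratio bounded.
    """

    frames: np.ndarray              # (n, h, w) float, NaN where masked
    f0: np.ndarray                  # (h, w) baseline map
    baseline_range: tuple[int, int]
    timestamps_s: np.ndarray
    mode_tags: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based half-open pixel intervals.

    ``x`` indexes columns and ``y`` rows; the region covers
    ``[y0, y1) x [x0, x1)``.  ROIs sharing a ``group`` are linked across
    de-interleaved stacks (identical pixel coordinates in both modes).
    """

    label: str
    x0: int
    y0: int
    x1: int
    y1: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"ROI {self.label!r} is empty")

    @classmethod
    def centered(cls, label: str, cx: int, cy: int, size: int = 3,
                 group: str | None = None) -> "ROI":
        """A size x size ROI centered on integer pixel (cx, cy)."""
        h = size // 2
        return cls(label, cx - h, cy - h, cx - h + size, cy - h + size, group)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        ny, nx = shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > nx or self.y1 > ny:
            raise ValueError(
                f"ROI {self.label!r} [{self.y0}:{self.y1}, {self.x0}:{self.x1}] "
                f"outside frame bounds {shape}"
            )


@dataclass
class Trace:
    """Mean pixel value within an ROI, per frame."""

    times_s: np.ndarray
    values: np.ndarray
    label: str = ""
    mode_tag: str | None = None

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.values):
            raise ValueError("times and values must have equal length")


def subtract_black(stack: ImageStack, level: float) -> ImageStack:
    """Subtract the camera black level, flooring at zero counts."""
    if level < 0:
        raise ValueError("black level must be >= 0")
    frames = np.clip(
        stack.frames.astype(np.int32) - int(round(level)), 0, None
    ).astype(stack.frames.dtype)
    meta = dict(stack.meta)
    meta["black_level_subtracted"] = level
    return ImageStack(
        frames=frames,
        mode_tags=list(stack.mode_tags) if stack.mode_tags else None,
        exposure_time_s=stack.exposure_time_s,
        timestamps_s=stack.timestamps_s.copy(),
        camera=stack.camera,
        meta=meta,
    )


def deinterleave(stack: ImageStack, k: int) -> list[ImageStack]:
    """Split an interleaved stack into k stride-k substacks.

    Substack j takes frames j, j+k, j+2k, ...  Mode tags and timestamps
    are carried along; tags inconsistent with a stride-k pattern raise
    :class:`TagMismatchError`.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if stack.n_frames < k:
        raise ValueError("stack shorter than the interleave stride")
    if k == 1:
        return [stack]
    if stack.mode_tags is not None:
        for i, tag in enumerate(stack.mode_tags):
            if tag != stack.mode_tags[i % k]:
                raise TagMismatchError(
                    f"frame {i} tagged {tag!r}, expected "
                    f"{stack.mode_tags[i % k]!r} for stride {k}"
                )
    out = []
    for j in range(k):
        tags = stack.mode_tags[j::k] if stack.mode_tags else None
        out.append(ImageStack(
            frames=stack.frames[j::k].copy(),
            mode_tags=list(tags) if tags else None,
            exposure_time_s=stack.exposure_time_s,
            timestamps_s=stack.timestamps_s[j::k].copy(),
            camera=stack.camera,
            meta={**stack.meta, "deinterleave": (j, k)},
        ))
    return out


def interleave(substacks: list[ImageStack]) -> ImageStack:
    """Re-interleave de-interleaved substacks (inverse of deinterleave)."""
    k = len(substacks)
    n_total = sum(s.n_frames for s in substacks)
    h, w = substacks[0].frames.shape[1:]
    frames = np.empty((n_total, h, w), dtype=substacks[0].frames.dtype)
    tags: list[str | None] = [None] * n_total
    times = np.empty(n_total)
    for j, s in enumerate(substacks):
        frames[j::k] = s.frames
        times[j::k] = s.timestamps_s
        if s.mode_tags is not None:
            tags[j::k] = s.mode_tags
    has_tags = all(t is not None for t in tags)
    return ImageStack(
        frames=frames,
        mode_tags=list(tags) if has_tags else None,
        exposure_time_s=substacks[0].exposure_time_s,
        timestamps_s=times,
        camera=substacks[0].camera,
        meta=dict(substacks[0].meta),
    )


def df_f0(
    stack: ImageStack,
    baseline_range: tuple[int, int],
    f0_floor: float = 1.0,
) -> RatioStack:
    """Pseudo-ratio normalization against resting baseline frames.

    F0 is the per-pixel mean over frames [start, stop); pixels with
    F0 < ``f0_floor`` counts are masked (NaN) rather than producing
    unbounded ratios.
    """
    start, stop = baseline_range
    if not (0 <= start < stop <= stack.n_frames):
        raise EmptyBaselineError(
            f"baseline range {baseline_range} invalid for "
            f"{stack.n_frames}-frame stack"
        )
    f = stack.frames.astype(float)
    f0 = f[start:stop].mean(axis=0)
    if not np.any(f0 >= f0_floor):
        raise EmptyBaselineError("all baseline pixels below the F0 floor")
    valid = f0 >= f0_floor
    ratio = np.full_like(f, np.nan)
    ratio[:, valid] = (f[:, valid] - f0[valid]) / f0[valid]
    return RatioStack(
        frames=ratio,
        f0=f0,
        baseline_range=(start, stop),
        timestamps_s=stack.timestamps_s.copy(),
        mode_tags=list(stack.mode_tags) if stack.mode_tags else None,
        meta={**stack.meta, "f0_floor": f0_floor,
              "masked_pixels": int((~valid).sum())},
    )


def _frames_of(obj) -> np.ndarray:
    if isinstance(obj, (ImageStack, RatioStack)):
        return obj.frames
    return np.asarray(obj)


def max_projection(obj, frame_range: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel maximum-intensity projection over a frame range."""
    frames = _frames_of(obj).astype(float)
    if frame_range is not None:
        start, stop = frame_range
        frames = frames[start:stop]
    if len(frames) == 0:
        raise ValueError("empty frame range")
    return np.nanmax(frames, axis=0)


def roi_trace(obj, roi: ROI) -> Trace:
    """Mean pixel value within the ROI for every frame."""
    frames = _frames_of(obj)
    roi.validate_bounds(frames.shape[1:])
    sy, sx = roi.slices()
    values = np.nanmean(frames[:, sy, sx].astype(float), axis=(1, 2))
    if isinstance(obj, (ImageStack, RatioStack)):
        times = obj.timestamps_s
        tags = obj.mode_tags
        mode = tags[0] if tags and len(set(tags)) == 1 else None
    else:
        times = np.arange(len(frames), dtype=float)
        mode = None
    return Trace(times_s=np.asarray(times, dtype=float), values=values,
                 label=roi.label, mode_tag=mode)


def linescan(
    image: np.ndarray,
    row: int | None = None,
    segment: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> np.ndarray:
    """Intensity profile along a horizontal row or an arbitrary segment.

    ``row=None`` with no segment takes the central row.  ``segment`` is
    ((row0, col0), (row1, col1)) and is sampled with linear interpolation.
    """
    image = np.asarray(image, dtype=float)
    if segment is not None:
        src, dst = segment
        return profile_line(image, src, dst, mode="reflect", order=1)
    if row is None:
        row = image.shape[0] // 2
    if not 0 <= row < image.shape[0]:
        raise ValueError(f"row {row} outside image of height {image.shape[0]}")
    return image[row].copy()


UniformityMetrics = namedtuple("UniformityMetrics", ["cv", "adjacent_variation"])


def uniformity_metrics(
    image: np.ndarray, tile: int = 16, mask: np.ndarray | None = None
) -> UniformityMetrics:
    """Field-uniformity metrics, both in percent.

    ``cv``: 100 x sd/mean over (optionally masked) pixels.
    ``adjacent_variation``: the image is tiled into tile x tile blocks
    (remainder rows/cols discarded) and the maximum symmetric percent
    difference 100 x |m_i - m_j| / (m_i + m_j) over 4-neighbouring block
    pairs is returned — the "variation between adjacent regions" measure.
    """
    image = np.asarray(image, dtype=float)
    pixels = image[mask] if mask is not None else image.ravel()
    mean = pixels.mean()
    if mean == 0:
        raise ValueError("zero-mean image; uniformity undefined")
    cv = 100.0 * pixels.std() / mean

    ny = image.shape[0] // tile
    nx = image.shape[1] // tile
    if ny < 1 or nx < 1:
        raise ValueError("tile larger than image")
    blocks = image[: ny * tile, : nx * tile].reshape(ny, tile, nx, tile)
    means = blocks.mean(axis=(1, 3))
    diffs = []
    if ny > 1:
        a, b = means[:-1, :], means[1:, :]
        diffs.append(np.abs(a - b) / (a + b))
    if nx > 1:
        a, b = means[:, :-1], means[:, 1:]
        diffs.append(np.abs(a - b) / (a + b))
    adjacent = 100.0 * max(float(d.max()) for d in diffs) if diffs else 0.0
    return UniformityMetrics(cv=float(cv), adjacent_variation=adjacent)


def frame_mean_stability(
    obj, region: tuple[slice, slice] | int | None = 100
) -> float:
    """Maximum percent deviation of the frame-mean trace from its mean.

    ``region`` selects a centered square of the given side (default 100
    pixels, averaging out shot noise), explicit slices, or the whole
    frame (None).  Returns 100 x max|frame mean - grand mean|/grand mean,
    the excitation-stability figure of merit.
    """
    frames = _frames_of(obj).astype(float)
    if isinstance(region, int):
        ny, nx = frames.shape[1:]
        if region > min(ny, nx):
            raise ValueError("region larger than frame")
        y0 = (ny - region) // 2
        x0 = (nx - region) // 2
        region = (slice(y0, y0 + region), slice(x0, x0 + region))
    if region is not None:
        frames = frames[:, region[0], region[1]]
    means = frames.mean(axis=(1, 2))
    grand = means.mean()
    if grand == 0:
        raise ValueError("zero grand mean")
    return float(100.0 * np.abs(means - grand).max() / grand)


def noise_corrected_cv(obj, mask: np.ndarray | None = None) -> float:
    """Spatial CV (%) of the time-averaged image, shot-noise corrected.

    The per-pixel temporal variance (dominated by photon shot noise and
    EM excess noise) inflates the spatial variance of an N-frame average
    by its mean over pixels divided by N; subtracting that leaves the
    variance of the static excitation pattern itself.
    """
    frames = _frames_of(obj).astype(float)
    n = len(frames)
    mean_img = frames.mean(axis=0)
    temporal_var = frames.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean_img)
    if mask is not None:
        mean_img = mean_img[mask]
        temporal_var = temporal_var[mask]
    spatial_var = mean_img.var()
    corrected = max(spatial_var - temporal_var.mean() / max(n, 1), 0.0)
    mu = mean_img.mean()
    if mu == 0:
        raise ValueError("zero-mean image")
    return float(100.0 * np.sqrt(corrected) / mu)


def export_traces_ascii(traces: list[Trace], path) -> None:
    """Write traces as a tab-separated ASCII table (time + one column each).

    Traces of unequal length (e.g. de-interleaved substacks differing by
    one frame) are padded with empty cells; each trace keeps its own
    timestamps in a paired column.
    """
    n = max(len(t.values) for t in traces)
    header = []
    for t in traces:
        header += [f"time_{t.label}", t.label]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(n):
            row = []
            for t in traces:
                if i < len(t.values):
                    row += [f"{t.times_s[i]:.6f}", f"{t.values[i]:.6g}"]
                else:
                    row += ["", ""]
            fh.write("\t".join(row) + "\n")
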