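"""Task geometry and stimulus rendering.

The cue-conflict saccade task presents two binary raster images per trial:

* an *encoding* image containing a crossing-lines landmark (one horizontal
  and one vertical line, each 1 px wide, spanning the full canvas) plus a
  6x6 px square marking the saccade target, and
* a *decoding* image containing only the landmark, optionally displaced by
  a shift vector (the cue conflict).

Both images are rendered in screen coordinates and then translated into a
retinal (eye-centred) frame by subtracting the initial gaze position.

Coordinate convention
---------------------
Screen coordinates are in degrees with (0, 0) at the canvas centre,
x rightward-positive and y upward-positive.  The canvas covers the square
field [-F, +F) degrees on each axis at a configurable pixel count, so the
degrees-per-pixel resolution is ``2 F / n_pixels``.  Column index grows
with x, row index grows with decreasing y, and pixel
(n_pixels//2, n_pixels//2) is the origin.  Sub-pixel positions are rounded
to the nearest pixel before rasterisation; the 6x6 target block is anchored
with its lower-left pixel at floor(target) (an even block has no centre
pixel).  Retinal translation uses integer-pixel shifts with canvas cropping
(no wraparound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Canvas",
    "TrialSpec",
    "StimulusImage",
    "ProtocolConfig",
    "render_encoding_image",
    "render_decoding_image",
    "retinal_transform",
    "sample_protocol_trial",
    "render_trial_images",
]

TARGET_BLOCK = 6  # side length of the target square, pixels
LINE_WIDTH = 1  # landmark line width, pixels


@dataclass(frozen=True)
class Canvas:
    """Raster geometry: ``n_pixels`` x ``n_pixels`` covering [-F, +F) deg."""

    n_pixels: int = 200
    field_halfwidth: float = 100.0

    @property
    def resolution(self) -> float:
        """Degrees per pixel."""
        return 2.0 * self.field_halfwidth / self.n_pixels

    def col(self, x: float | np.ndarray) -> np.ndarray:
        return (np.rint(np.asarray(x) / self.resolution).astype(int)
                + self.n_pixels // 2)

    def row(self, y: float | np.ndarray) -> np.ndarray:
        return (self.n_pixels // 2
                - np.rint(np.asarray(y) / self.resolution).astype(int))

    def floor_col(self, x: float | np.ndarray) -> np.ndarray:
        return (np.floor(np.asarray(x) / self.resolution).astype(int)
                + self.n_pixels // 2)

    def floor_row(self, y: float | np.ndarray) -> np.ndarray:
        return (self.n_pixels // 2
                - np.floor(np.asarray(y) / self.resolution).astype(int))

    def contains(self, xy: np.ndarray, margin_px: int = 0) -> bool:
        xy = np.asarray(xy, dtype=float)
        c = self.col(xy[..., 0])
        r = self.row(xy[..., 1])
        lo, hi = margin_px, self.n_pixels - margin_px
        return bool(np.all((c >= lo) & (c < hi) & (r >= lo) & (r < hi)))


@dataclass
class TrialSpec:
    """Geometry of one trial, all 2-vectors in degrees (screen frame)."""

    target: np.ndarray
    landmark: np.ndarray
    shift: np.ndarray
    initial_gaze: np.ndarray
    final_gaze: np.ndarray

    def __post_init__(self) -> None:
        for name in ("target", "landmark", "shift", "initial_gaze",
                     "final_gaze"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 2-vector")
            setattr(self, name, v)

    @property
    def shifted_landmark(self) -> np.ndarray:
        return self.landmark + self.shift

    @property
    def virtual_target(self) -> np.ndarray:
        """T' = target displaced by the landmark shift."""
        return self.target + self.shift


@dataclass
class StimulusImage:
    """A nonnegative intensity raster with its coordinate frame."""

    grid: np.ndarray
    resolution: float
    frame: str = "screen"  # {"screen", "retinal"}

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.frame not in ("screen", "retinal"):
            raise ValueError(f"unknown frame {self.frame!r}")


class GeometryError(ValueError):
    """Raised when a target or landmark cannot be rasterised in-canvas."""


def _draw_lines(grid: np.ndarray, canvas: Canvas, landmark: np.ndarray) -> None:
    r = int(canvas.row(landmark[1]))
    c = int(canvas.col(landmark[0]))
    n = canvas.n_pixels
    if not (0 <= r < n and 0 <= c < n):
        raise GeometryError(f"landmark {landmark} rasterises off-canvas")
    grid[r, :] = 1.0
    grid[:, c] = 1.0


def _draw_target_block(grid: np.ndarray, canvas: Canvas,
                       target: np.ndarray) -> None:
    # lower-left pixel of the block sits at floor(target)
    c0 = int(canvas.floor_col(target[0]))
    r1 = int(canvas.floor_row(target[1]))  # bottom row (largest row index)
    r0 = r1 - (TARGET_BLOCK - 1)
    n = canvas.n_pixels
    if not (0 <= r0 and r1 < n and 0 <= c0 and c0 + TARGET_BLOCK <= n):
        raise GeometryError(f"target {target} block extends off-canvas")
    grid[r0:r1 + 1, c0:c0 + TARGET_BLOCK] = 1.0


def render_encoding_image(spec: TrialSpec, canvas: Canvas) -> StimulusImage:
    """Landmark lines plus the 6x6 target block, screen frame."""
    grid = np.zeros((canvas.n_pixels, canvas.n_pixels))
    _draw_lines(grid, canvas, spec.landmark)
    _draw_target_block(grid, canvas, spec.target)
    return StimulusImage(grid, canvas.resolution, "screen")


def render_decoding_image(spec: TrialSpec, canvas: Canvas) -> StimulusImage:
    """Only the (possibly shifted) landmark lines, screen frame."""
    grid = np.zeros((canvas.n_pixels, canvas.n_pixels))
    _draw_lines(grid, canvas, spec.shifted_landmark)
    return StimulusImage(grid, canvas.resolution, "screen")


def retinal_transform(img: StimulusImage, gaze: np.ndarray,
                      canvas: Canvas | None = None) -> StimulusImage:
    """Translate a screen-frame image by -gaze (integer pixels, cropped).

    Emulates the retinal projection: the eye position is subtracted from
    the screen image, so content at screen position p appears at retinal
    position p - gaze.  Pixels shifted off-canvas are dropped and vacated
    pixels are zero.
    """
    if img.frame != "screen":
        raise ValueError("retinal_transform expects a screen-frame image")
    res = img.resolution if canvas is None else canvas.resolution
    gaze = np.asarray(gaze, dtype=float)
    dc = int(np.rint(gaze[0] / res))
    dr = int(np.rint(-gaze[1] / res))  # y up means row down
    out = np.zeros_like(img.grid)
    _shift_into(out, img.grid, -dr, -dc)
    return StimulusImage(out, res, "retinal")


def _shift_into(out: np.ndarray, src: np.ndarray, dr: int, dc: int) -> None:
    """out <- src translated by (dr, dc) in index space, zero-padded."""
    h, w = src.shape
    r0, r1 = max(0, dr), min(h, h + dr)
    c0, c1 = max(0, dc), min(w, w + dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = src[r0 - dr:r1 - dr, c0 - dc:c1 - dc]


@dataclass
class ProtocolConfig:
    """Sampling rules of the monkey protocol.

    The landmark sits at one of 4 oblique positions 11 deg from the target;
    the shift is one of 8 directions on an 8-deg circle (or zero in the
    no-shift condition); the initial gaze is jittered in a 7-12 deg annulus
    around the screen centre.
    """

    landmark_distance: float = 11.0
    shift_radius: float = 8.0
    n_shift_directions: int = 8
    gaze_annulus: tuple[float, float] = (7.0, 12.0)
    target_range: float = 50.0
    allocentric_weight: float = 0.0
    zero_shift: bool = False

    landmark_offsets: np.ndarray = field(init=False, repr=False)
    shift_offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        d = self.landmark_distance / np.sqrt(2.0)
        self.landmark_offsets = np.array(
            [[d, d], [-d, d], [-d, -d], [d, -d]])
        ang = 2.0 * np.pi * np.arange(self.n_shift_directions) \
            / self.n_shift_directions
        self.shift_offsets = self.shift_radius * np.column_stack(
            [np.cos(ang), np.sin(ang)])


def sample_protocol_trial(rng: np.random.Generator,
                          cfg: ProtocolConfig,
                          target: np.ndarray | None = None) -> TrialSpec:
    """Draw one trial under the monkey protocol geometry."""
    if target is None:
        target = rng.uniform(-cfg.target_range, cfg.target_range, size=2)
    target = np.asarray(target, dtype=float)
    landmark = target + cfg.landmark_offsets[rng.integers(4)]
    if cfg.zero_shift:
        shift = np.zeros(2)
    else:
        shift = cfg.shift_offsets[rng.integers(cfg.n_shift_directions)]
    r = rng.uniform(*cfg.gaze_annulus)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    gaze0 = r * np.array([np.cos(phi), np.sin(phi)])
    final = target + cfg.allocentric_weight * shift
    return TrialSpec(target, landmark, shift, gaze0, final)


def render_trial_images(spec: TrialSpec, canvas: Canvas,
                        retinal: bool = True
                        ) -> tuple[StimulusImage, StimulusImage]:
    """Render the (encoding, decoding) pair for one trial."""
    enc = render_encoding_image(spec, canvas)
    dec = render_decoding_image(spec, canvas)
    if retinal:
        enc = retinal_transform(enc, spec.initial_gaze, canvas)
        dec = retinal_transform(dec, spec.initial_gaze, canvas)
    return enc, dec
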