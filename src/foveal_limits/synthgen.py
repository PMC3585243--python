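"""Synthetic ground-truth generators for the whole pipeline.

Everything the analysis consumes can be generated here with known truth:

* jittered triangular cone mosaics with eccentricity-dependent spacing and
  optional random cone loss (emulating a carrier retina with patchy cone
  degeneration);
* AOSLO-like frames (default 48 x 54 arcmin field, cones as Gaussian
  blobs, additive noise);
* fixational eye-motion traces (mean-reverting drift plus Poisson
  microsaccades);
* dual-wavelength TCA calibration videos alternating at 2 Hz with a known
  injected lateral shift;
* simulated psychophysical observers with an analytic Weibull psychometric
  function.

All randomness flows through per-call seeds; fixed seeds give bit-identical
outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from foveal_limits.mosaic import ConeMosaic, Frame
from foveal_limits.motionstats import MotionTrace
from foveal_limits.scaling import ScaleModel

DEFAULT_FIELD_ARCMIN = (48.0, 54.0)
DEFAULT_FRAME_RATE = 30.0  # Hz; explicit and configurable via MotionSpec


class InvalidSpecError(ValueError):
    """Raised when a generator spec cannot produce a usable artifact."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in centered arcmin coordinates."""

    x: float  # left edge
    y: float  # top edge (smaller y)
    w: float
    h: float

    def inside(self, field_arcmin: tuple[float, float]) -> bool:
        fx, fy = field_arcmin[0] / 2.0, field_arcmin[1] / 2.0
        return (
            self.x > -fx
            and self.y > -fy
            and self.x + self.w < fx
            and self.y + self.h < fy
        )

    def pixel_slices(self, frame: Frame) -> tuple[slice, slice]:
        (r0, c0), (r1, c1) = frame.to_pixels(
            np.array([[self.x, self.y], [self.x + self.w, self.y + self.h]])
        )
        return slice(int(round(r0)), int(round(r1))), slice(
            int(round(c0)), int(round(c1))
        )

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= self.x - margin)
            & (xy[:, 0] <= self.x + self.w + margin)
            & (xy[:, 1] >= self.y - margin)
            & (xy[:, 1] <= self.y + self.h + margin)
        )


def _yaml_mixin_to(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(obj), sort_keys=False))


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of a synthetic cone mosaic.

    ``peak_icd`` (arcmin) is the spacing at the PRLF; spacing grows linearly
    with radial eccentricity at ``icd_slope`` arcmin per degree.  ``jitter_sd``
    is positional jitter as a fraction of the local spacing; ``loss_fraction``
    deletes lattice sites independently (carrier-like patchy loss).
    ``extent`` is the half-width (radius) of the generated patch in degrees.
    """

    peak_icd: float = 0.58
    icd_slope: float = 0.35
    jitter_sd: float = 0.05
    loss_fraction: float = 0.0
    extent: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_icd <= 0:
            raise InvalidSpecError("peak_icd must be positive")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise InvalidSpecError("loss_fraction must be in [0, 1)")
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter_sd must be nonnegative")
        if self.extent <= 0:
            raise InvalidSpecError("extent must be positive")

    def spacing(self, ecc_deg):
        """Analytic local spacing (arcmin) at the given eccentricity (deg)."""
        return self.peak_icd + self.icd_slope * np.asarray(ecc_deg, dtype=float)

    def density(self, ecc_deg):
        """Triangular-packing areal density (cones/arcmin²) at eccentricity."""
        s = self.spacing(ecc_deg)
        return 2.0 / (math.sqrt(3.0) * s**2)

    def to_yaml(self, path) -> None:
        _yaml_mixin_to(path, self)

    @classmethod
    def from_yaml(cls, path) -> "MosaicSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class MotionSpec:
    """Fixational eye-motion parameters.

    Drift is a mean-reverting (AR(1)) random walk with per-frame step SD
    ``drift_sd`` arcmin, which makes the positional spread stationary and
    controllable; microsaccades arrive as a Poisson process at
    ``microsaccade_rate`` per second with fixed amplitude and uniformly
    random direction.
    """

    drift_sd: float = 0.15
    microsaccade_rate: float = 1.0
    microsaccade_amplitude: float = 4.0
    frame_rate: float = DEFAULT_FRAME_RATE
    n_frames: int = 300
    seed: int = 0
    reversion: float = 0.05  # AR(1) pull toward the fixation locus, per frame

    def __post_init__(self) -> None:
        for name in ("drift_sd", "microsaccade_rate", "microsaccade_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be nonnegative")
        if self.frame_rate <= 0 or self.n_frames < 1:
            raise InvalidSpecError("frame_rate and n_frames must be positive")

    def to_yaml(self, path) -> None:
        _yaml_mixin_to(path, self)

    @classmethod
    def from_yaml(cls, path) -> "MotionSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ObserverSpec:
    """Simulated observer: Weibull psychometric function on stimulus size.

    ``limit`` is the Weibull scale (arcmin, or contrast for 2IFC);
    P(correct | x) = guess + (1 - guess - lapse) * (1 - exp(-(x/limit)**slope)).
    """

    limit: float = 1.0
    slope: float = 3.5
    guess_rate: float = 0.25
    lapse_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise InvalidSpecError("limit must be positive")
        if self.guess_rate not in (0.25, 0.5):
            raise InvalidSpecError("guess_rate must be 0.25 (4AFC) or 0.5 (2IFC)")
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise InvalidSpecError("lapse_rate must be in [0, 0.05]")

    def to_yaml(self, path) -> None:
        _yaml_mixin_to(path, self)

    @classmethod
    def from_yaml(cls, path) -> "ObserverSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# mosaic generation


def _graded_hex(spec: MosaicSpec, radius: float, center: np.ndarray) -> np.ndarray:
    """Triangular lattice graded along the horizontal meridian.

    Columns run perpendicular to the meridian at positions marched outward
    from the PRLF with step ``(sqrt(3)/2) * s(|x|)``; within a column, cones
    are spaced ``s(|x|)`` with the half-spacing offset alternating between
    columns.  With zero slope this is an exact triangular lattice with a
    site at the PRLF.  With a gradient, spacing grows with meridional
    distance from the PRLF, which within the small patches used here agrees
    with radial eccentricity to second order; a radial gradient admits no
    defect-free lattice (the implied metric is curved), and this
    construction confines the residual mismatch to the off-axis direction.
    """
    x_hi = center[0] + radius
    x_lo = center[0] - radius
    max_abs = max(abs(x_hi), abs(x_lo)) + 2.0
    # march column positions outward from the PRLF (x = 0)
    cols_pos = [0.0]
    while cols_pos[-1] < max_abs:
        x = cols_pos[-1]
        cols_pos.append(x + (math.sqrt(3.0) / 2.0) * float(spec.spacing(abs(x) / 60.0)))
    columns = [(-k, -x) for k, x in enumerate(cols_pos) if k > 0][::-1] + [
        (k, x) for k, x in enumerate(cols_pos)
    ]
    pts = []
    for k, xk in columns:
        if not (x_lo - 1.0) <= xk <= (x_hi + 1.0):
            continue
        s = float(spec.spacing(abs(xk) / 60.0))
        offset = 0.5 * s if (k % 2) else 0.0
        n_y = int(math.ceil((radius + abs(center[1]) + 2.0) / s)) + 1
        ys = center[1] + offset + s * np.arange(-n_y, n_y + 1)
        # re-anchor the column to y = 0 (+offset) so the PRLF stays a site
        ys = offset + s * np.round((ys - offset) / s)
        pts.append(np.column_stack([np.full(ys.size, xk), ys]))
    allpts = np.vstack(pts)
    keep = np.hypot(allpts[:, 0] - center[0], allpts[:, 1] - center[1]) <= radius
    return allpts[keep]


def generate_mosaic(
    spec: MosaicSpec, center_deg: tuple[float, float] = (0.0, 0.0)
) -> ConeMosaic:
    """Generate a synthetic cone mosaic patch with known spacing truth.

    The patch is a disc of radius ``spec.extent`` degrees centered at
    ``center_deg`` (degrees from the PRLF; the default is the PRLF itself,
    and off-center patches emulate imaging along the meridian).  Positions
    are returned in arcmin relative to the PRLF.

    The lattice is triangular with spacing graded along the meridian (see
    :func:`_graded_hex`); with ``icd_slope == 0`` it is an exact triangular
    lattice with a site at the PRLF.  Jitter and loss are applied afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    radius = spec.extent * 60.0
    center = np.asarray(center_deg, dtype=float) * 60.0
    pts = _graded_hex(spec, radius, center)

    if spec.jitter_sd > 0:
        local_s = np.asarray(spec.spacing(np.hypot(pts[:, 0], pts[:, 1]) / 60.0))
        pts = pts + rng.normal(0.0, 1.0, size=pts.shape) * (
            spec.jitter_sd * local_s
        )[:, None]
    if spec.loss_fraction > 0:
        pts = pts[rng.uniform(size=pts.shape[0]) >= spec.loss_fraction]
    if pts.shape[0] < 7:
        raise InvalidSpecError(
            f"extent {spec.extent} deg yields only {pts.shape[0]} cones (< 7); "
            "increase extent or reduce loss"
        )
    return ConeMosaic(pts, source="truth")


# ---------------------------------------------------------------------------
# frame rendering


def _blob_sigmas(positions: np.ndarray, fallback: float = 1.0) -> np.ndarray:
    """Per-cone blob sigma = 0.25 x local spacing (nearest-neighbor based)."""
    from scipy.spatial import cKDTree

    n = positions.shape[0]
    if n < 2:
        return np.full(n, 0.25 * fallback)
    k = min(4, n)
    dist, _ = cKDTree(positions).query(positions, k=k)
    nn = np.mean(dist[:, 1:], axis=1) if k > 2 else dist[:, 1]
    return 0.25 * nn


def _splat_blobs(
    shape: tuple[int, int],
    rows: np.ndarray,
    cols: np.ndarray,
    sig_px: np.ndarray,
    amplitude: float,
    max_bins: int = 6,
) -> np.ndarray:
    """Render unit-peak Gaussian blobs by bilinear splatting + convolution.

    Sub-pixel centers are bilinearly splatted onto a delta canvas (which
    preserves each blob's centroid exactly) and convolved with a sampled
    Gaussian kernel; cones are grouped into at most ``max_bins`` sigma bins
    so mildly varying blob sizes stay accurate.
    """
    from scipy.ndimage import convolve1d

    out = np.zeros(shape)
    if rows.size == 0:
        return out
    h_px, w_px = shape
    uniq = np.unique(np.round(sig_px, 3))
    if uniq.size > max_bins:
        edges = np.quantile(sig_px, np.linspace(0, 1, max_bins + 1))
        which = np.clip(np.searchsorted(edges, sig_px, side="right") - 1, 0, max_bins - 1)
    else:
        which = np.searchsorted(uniq, np.round(sig_px, 3))
    for b in np.unique(which):
        sel = which == b
        sigma = float(np.mean(sig_px[sel]))
        canvas = np.zeros(shape)
        r, c = rows[sel], cols[sel]
        r0 = np.floor(r).astype(int)
        c0 = np.floor(c).astype(int)
        fr, fc = r - r0, c - c0
        for dr, dc, wgt in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr, cc = r0 + dr, c0 + dc
            ok = (rr >= 0) & (rr < h_px) & (cc >= 0) & (cc < w_px)
            np.add.at(canvas, (rr[ok], cc[ok]), wgt[ok])
        half = max(int(math.ceil(3.0 * sigma)), 1)
        k = np.arange(-half, half + 1)
        g = np.exp(-0.5 * (k / sigma) ** 2)
        canvas = convolve1d(canvas, amplitude * g, axis=0, mode="constant")
        out += convolve1d(canvas, g, axis=1, mode="constant")
    return out


def render_frame(
    mosaic: ConeMosaic,
    scale: ScaleModel | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    field_arcmin: tuple[float, float] = DEFAULT_FIELD_ARCMIN,
    pixels_per_arcmin: float = 8.0,
    background: float = 0.1,
    amplitude: float = 0.7,
    rng: np.random.Generator | None = None,
    blob_sigma_arcmin: np.ndarray | None = None,
) -> Frame:
    """Render a mosaic as a grayscale AOSLO-like frame.

    Cones become Gaussian intensity blobs (sigma = 0.25 x local spacing)
    over a uniform background; ``offset`` shifts the whole mosaic rigidly
    (arcmin); additive Gaussian noise of SD ``noise_sd`` is clipped with the
    image to [0, 1].
    """
    if scale is not None:
        pixels_per_arcmin = scale.pixels_per_arcmin
    w_px = int(round(field_arcmin[0] * pixels_per_arcmin))
    h_px = int(round(field_arcmin[1] * pixels_per_arcmin))
    img = np.full((h_px, w_px), background, dtype=float)

    pos = mosaic.positions + np.asarray(offset, dtype=float)
    if pos.shape[0]:
        if blob_sigma_arcmin is None:
            sig = _blob_sigmas(mosaic.positions)
        else:
            sig = np.broadcast_to(
                np.asarray(blob_sigma_arcmin, dtype=float), (pos.shape[0],)
            )
        sig_px = sig * pixels_per_arcmin
        cols = (pos[:, 0] + field_arcmin[0] / 2.0) * pixels_per_arcmin
        rows = (pos[:, 1] + field_arcmin[1] / 2.0) * pixels_per_arcmin
        margin = 3.0 * sig_px
        keep = (
            (cols > -margin)
            & (cols < w_px + margin)
            & (rows > -margin)
            & (rows < h_px + margin)
        )
        img += _splat_blobs(
            (h_px, w_px), rows[keep], cols[keep], sig_px[keep], amplitude
        )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return Frame(np.clip(img, 0.0, 1.0), field_arcmin=field_arcmin)


# ---------------------------------------------------------------------------
# motion


def generate_motion(spec: MotionSpec) -> MotionTrace:
    """Simulate a fixational eye-motion position trace (arcmin)."""
    rng = np.random.default_rng(spec.seed)
    pos = np.zeros((spec.n_frames, 2))
    p_saccade = spec.microsaccade_rate / spec.frame_rate
    x = np.zeros(2)
    for t in range(spec.n_frames):
        x = (1.0 - spec.reversion) * x + rng.normal(0.0, spec.drift_sd, size=2)
        if rng.uniform() < p_saccade and spec.microsaccade_amplitude > 0:
            theta = rng.uniform(0.0, 2.0 * math.pi)
            x = x + spec.microsaccade_amplitude * np.array(
                [math.cos(theta), math.sin(theta)]
            )
        pos[t] = x
    return MotionTrace(pos[:, 0], pos[:, 1], frame_rate=spec.frame_rate)


# ---------------------------------------------------------------------------
# TCA calibration videos


@dataclass
class VideoStack:
    """Frame stack with wavelength-alternation schedule and ground truth.

    ``channel`` is 0 for IR-only frames and 1 for frames whose window region
    was imaged in the second (red) wavelength.  ``truth`` carries the
    injected TCA shift and motion trace when the stack is synthetic.
    """

    frames: np.ndarray  # (n, rows, cols) float in [0, 1]
    field_arcmin: tuple[float, float] = DEFAULT_FIELD_ARCMIN
    frame_rate: float = DEFAULT_FRAME_RATE
    channel: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    window: Rect | None = None
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def pixels_per_arcmin(self) -> float:
        return self.frames.shape[2] / self.field_arcmin[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.frames[i], field_arcmin=self.field_arcmin)

    @property
    def first_red_frame(self) -> int:
        idx = np.nonzero(self.channel == 1)[0]
        if idx.size == 0:
            raise ValueError("video has no red frames")
        return int(idx[0])

    def save(self, tiff_path, sidecar_path=None) -> None:
        tiff_path = Path(tiff_path)
        tifffile.imwrite(
            tiff_path, (np.clip(self.frames, 0, 1) * 65535).astype(np.uint16)
        )
        meta = {
            "field_arcmin": list(self.field_arcmin),
            "frame_rate": self.frame_rate,
            "channel": self.channel.tolist(),
            "window": asdict(self.window) if self.window else None,
            "truth": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.truth.items()
            },
        }
        sidecar = (
            Path(sidecar_path)
            if sidecar_path
            else tiff_path.with_suffix(".json")
        )
        sidecar.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, tiff_path, sidecar_path=None) -> "VideoStack":
        tiff_path = Path(tiff_path)
        frames = tifffile.imread(tiff_path).astype(float) / 65535.0
        sidecar = (
            Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
        )
        meta = json.loads(sidecar.read_text())
        window = Rect(**meta["window"]) if meta.get("window") else None
        return cls(
            frames=frames,
            field_arcmin=tuple(meta["field_arcmin"]),
            frame_rate=meta["frame_rate"],
            channel=np.asarray(meta["channel"], dtype=int),
            window=window,
            truth=meta.get("truth", {}),
        )


def alternation_schedule(
    n_frames: int, frame_rate: float, alternation_hz: float
) -> np.ndarray:
    """Per-frame channel indices (0 = IR, 1 = red) for a square-wave schedule."""
    i = np.arange(n_frames)
    return (np.floor(i * 2.0 * alternation_hz / frame_rate) % 2).astype(int)


def generate_tca_video(
    mosaic: ConeMosaic,
    scale: ScaleModel | None,
    tca_shift: tuple[float, float],
    motion: MotionSpec,
    alternation_hz: float = 2.0,
    window: Rect | None = None,
    field_arcmin: tuple[float, float] = DEFAULT_FIELD_ARCMIN,
    pixels_per_arcmin: float = 8.0,
    noise_sd: float = 0.03,
) -> VideoStack:
    """Simulate a dual-wavelength TCA calibration video.

    The full field is imaged continuously in the IR channel while a window
    region alternates at ``alternation_hz`` between IR and a red channel
    whose retinal image is displaced by ``tca_shift`` (arcmin).  The whole
    frame additionally moves with a fixational motion trace.  Injected truth
    (shift, trace, schedule) is stored on the returned stack.
    """
    if scale is not None:
        pixels_per_arcmin = scale.pixels_per_arcmin
    if window is None:
        window = Rect(-12.0, -20.0, 24.0, 14.0)
    if not window.inside(field_arcmin):
        raise ValueError(f"window {window} not strictly inside field {field_arcmin}")
    trace = generate_motion(motion)
    channel = alternation_schedule(motion.n_frames, motion.frame_rate, alternation_hz)
    rng = np.random.default_rng(motion.seed + 1)
    # uniform blob size across the patch keeps per-frame rendering cheap
    sigmas = np.full(len(mosaic), float(np.mean(_blob_sigmas(mosaic.positions))))
    shift = np.asarray(tca_shift, dtype=float)

    frames = np.empty(
        (
            motion.n_frames,
            int(round(field_arcmin[1] * pixels_per_arcmin)),
            int(round(field_arcmin[0] * pixels_per_arcmin)),
        ),
        dtype=float,
    )
    # restrict the red-channel re-render to cones near the window
    pad = 6.0 + float(np.hypot(*shift))
    for t in range(motion.n_frames):
        off = (trace.x[t], trace.y[t])
        frame = render_frame(
            mosaic,
            offset=off,
            noise_sd=0.0,
            field_arcmin=field_arcmin,
            pixels_per_arcmin=pixels_per_arcmin,
            blob_sigma_arcmin=sigmas,
        )
        img = frame.image
        if channel[t] == 1:
            shifted = mosaic.positions + off + shift
            near = window.contains(mosaic.positions + off, margin=pad)
            red = render_frame(
                ConeMosaic(shifted[near], source="truth"),
                offset=(0.0, 0.0),
                noise_sd=0.0,
                field_arcmin=field_arcmin,
                pixels_per_arcmin=pixels_per_arcmin,
                blob_sigma_arcmin=sigmas[near],
            )
            rs, cs = window.pixel_slices(frame)
            img[rs, cs] = red.image[rs, cs]
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape), 0.0, 1.0)
        frames[t] = img

    return VideoStack(
        frames=frames,
        field_arcmin=field_arcmin,
        frame_rate=motion.frame_rate,
        channel=channel,
        window=window,
        truth={
            "tca_shift_arcmin": shift,
            "trace_x": trace.x,
            "trace_y": trace.y,
            "alternation_hz": alternation_hz,
        },
    )


# ---------------------------------------------------------------------------
# observers


class Observer:
    """Simulated forced-choice observer with a Weibull psychometric function.

    P(correct | x) = guess + (1 - guess - lapse) * (1 - exp(-(x/limit)**slope))

    where ``x`` is the stimulus magnitude (letter size in arcmin for the
    acuity task, contrast for the 2IFC task).  Responses are drawn with a
    seeded generator, so a fixed seed replays the same trial sequence.
    """

    def __init__(self, spec: ObserverSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)

    def p_correct(self, x) -> np.ndarray | float:
        s = self.spec
        x = np.asarray(x, dtype=float)
        p = s.guess_rate + (1.0 - s.guess_rate - s.lapse_rate) * (
            1.0 - np.exp(-((np.maximum(x, 0.0) / s.limit) ** s.slope))
        )
        return float(p) if p.ndim == 0 else p

    def respond(self, x) -> bool:
        """One trial at stimulus magnitude ``x``; True if correct."""
        return bool(self.rng.uniform() < self.p_correct(x))

    def criterion_size(self, p: float) -> float:
        """Stimulus magnitude at which P(correct) = p (analytic inverse)."""
        s = self.spec
        if not s.guess_rate < p < 1.0 - s.lapse_rate:
            raise ValueError(
                f"criterion {p} outside ({s.guess_rate}, {1 - s.lapse_rate})"
            )
        k = -math.log((1.0 - s.lapse_rate - p) / (1.0 - s.lapse_rate - s.guess_rate))
        return s.limit * k ** (1.0 / s.slope)


def make_observer(spec: ObserverSpec) -> Observer:
    return Observer(spec)


def spec_for_criterion(
    point: float,
    criterion: float = 0.825,
    slope: float = 3.5,
    guess_rate: float = 0.25,
    lapse_rate: float = 0.01,
    seed: int = 0,
) -> ObserverSpec:
    """ObserverSpec whose P(correct) hits ``criterion`` exactly at ``point``."""
    k = -math.log((1.0 - lapse_rate - criterion) / (1.0 - lapse_rate - guess_rate))
    limit = point / k ** (1.0 / slope)
    return ObserverSpec(
        limit=limit,
        slope=slope,
        guess_rate=guess_rate,
        lapse_rate=lapse_rate,
        seed=seed,
    )
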