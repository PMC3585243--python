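"""Cone localization and cone-mosaic spacing metrics (ICD, N_c).

Spacing is summarized per cone as the inter-cone distance (ICD): the mean
center-to-center distance from a cone to each of its Delaunay neighbors.
For triangular packing the Nyquist limit of the mosaic — the finest grating
half-period the cone array can represent — is the row spacing,
``N_c = (sqrt(3)/2) * ICD``.

Coordinates are in arcmin relative to the preferred retinal locus of
fixation (PRLF), which sits at the origin; eccentricity is radial distance
in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from skimage.feature import peak_local_max
from skimage.restoration import estimate_sigma

from foveal_limits.motionstats import MotionTrace
from foveal_limits.scaling import ScaleModel

SQRT3_OVER_2 = math.sqrt(3.0) / 2.0
MIN_SEPARATION_ARCMIN = 0.05


@dataclass(frozen=True)
class Frame:
    """A single grayscale AOSLO-like frame.

    ``image`` is (rows, cols) with intensities in [0, 1]; ``field_arcmin``
    is (width, height).  Arcmin coordinates are relative to the frame
    center, x along columns and y along rows (row = (y + height/2) * px/arcmin).
    """

    image: np.ndarray
    field_arcmin: tuple[float, float] = (48.0, 54.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "image", np.asarray(self.image, dtype=float))
        if self.image.ndim != 2:
            raise ValueError("frame image must be 2-D")

    @property
    def pixels_per_arcmin(self) -> float:
        return self.image.shape[1] / self.field_arcmin[0]

    def to_arcmin(self, rows_cols: np.ndarray) -> np.ndarray:
        """Convert (row, col) pixel coordinates to centered (x, y) arcmin."""
        s = self.pixels_per_arcmin
        rc = np.atleast_2d(rows_cols)
        x = rc[:, 1] / s - self.field_arcmin[0] / 2.0
        y = rc[:, 0] / s - self.field_arcmin[1] / 2.0
        return np.column_stack([x, y])

    def to_pixels(self, xy_arcmin: np.ndarray) -> np.ndarray:
        s = self.pixels_per_arcmin
        xy = np.atleast_2d(xy_arcmin)
        col = (xy[:, 0] + self.field_arcmin[0] / 2.0) * s
        row = (xy[:, 1] + self.field_arcmin[1] / 2.0) * s
        return np.column_stack([row, col])


@dataclass(frozen=True)
class ConeMosaic:
    """Cone center coordinates in arcmin relative to the PRLF."""

    positions: np.ndarray
    source: str = "truth"  # "truth" (synthetic) or "localized"
    warning: str | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if pos.size and not np.all(np.isfinite(pos)):
            raise ValueError("cone positions must be finite")
        if pos.shape[0] > 1:
            tree = cKDTree(pos)
            pairs = tree.query_pairs(MIN_SEPARATION_ARCMIN)
            if pairs:
                raise ValueError(
                    f"{len(pairs)} cone pairs closer than "
                    f"{MIN_SEPARATION_ARCMIN} arcmin; not a valid mosaic"
                )
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def eccentricity_deg(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1]) / 60.0

    def translated(self, dx: float, dy: float) -> "ConeMosaic":
        return ConeMosaic(self.positions + [dx, dy], source=self.source)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.positions, columns=["x_arcmin", "y_arcmin"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, source: str = "localized") -> "ConeMosaic":
        df = pd.read_csv(path)
        return cls(df[["x_arcmin", "y_arcmin"]].to_numpy(), source=source)


@dataclass(frozen=True)
class SpacingMetrics:
    """Per-cone ICD and Nyquist limit, with boundary (convex-hull) flags."""

    positions: np.ndarray
    icd: np.ndarray
    boundary: np.ndarray
    nc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nc is None:
            object.__setattr__(self, "nc", icd_to_nc(self.icd))

    @property
    def eccentricity(self) -> np.ndarray:
        """Radial eccentricity in degrees from the PRLF."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1]) / 60.0

    @property
    def interior_icd(self) -> np.ndarray:
        return self.icd[~self.boundary]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_arcmin": self.positions[:, 0],
                "y_arcmin": self.positions[:, 1],
                "ecc_deg": self.eccentricity,
                "icd_arcmin": self.icd,
                "nc_arcmin": self.nc,
                "boundary_flag": self.boundary,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def localize_cones(
    frame: Frame,
    scale: ScaleModel | None = None,
    min_distance_px: int = 3,
    noise_k: float = 5.0,
    refine_radius_px: int = 3,
) -> ConeMosaic:
    """Localize cone centers in a frame with sub-pixel precision.

    Local maxima of a lightly smoothed image above an adaptive threshold
    (median + ``noise_k`` x estimated noise SD) are refined by an
    intensity-weighted centroid over a small window.  A flat or saturated
    frame yields an empty mosaic carrying a warning flag.

    ``scale`` is accepted for interface symmetry with pixel-calibrated
    imagery; positions are returned in arcmin via the frame's field size.
    """
    img = frame.image
    rng = float(img.max() - img.min())
    saturated = float(np.mean(img >= 1.0 - 1e-9))
    if rng < 1e-6 or saturated > 0.5:
        reason = "flat frame" if rng < 1e-6 else "saturated frame"
        warnings.warn(f"localize_cones: {reason}; returning empty mosaic")
        return ConeMosaic(np.empty((0, 2)), source="localized", warning=reason)

    smoothed = ndimage.gaussian_filter(img, sigma=1.0)
    sigma_noise = float(estimate_sigma(img))
    threshold = float(np.median(smoothed)) + noise_k * sigma_noise
    peaks = peak_local_max(
        smoothed, min_distance=min_distance_px, threshold_abs=threshold
    )
    if peaks.size == 0:
        return ConeMosaic(np.empty((0, 2)), source="localized")

    # centroid refinement on background-subtracted intensities
    background = float(np.median(img))
    r = refine_radius_px
    refined = np.empty((peaks.shape[0], 2), dtype=float)
    rows, cols = img.shape
    for i, (pr, pc) in enumerate(peaks):
        r0, r1 = max(pr - r, 0), min(pr + r + 1, rows)
        c0, c1 = max(pc - r, 0), min(pc + r + 1, cols)
        patch = np.clip(img[r0:r1, c0:c1] - background, 0.0, None)
        total = patch.sum()
        if total <= 0:
            refined[i] = (pr, pc)
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        refined[i] = ((rr * patch).sum() / total, (cc * patch).sum() / total)

    xy = frame.to_arcmin(refined)
    xy = _merge_close(xy, MIN_SEPARATION_ARCMIN)
    return ConeMosaic(xy, source="localized")


def _merge_close(xy: np.ndarray, radius: float) -> np.ndarray:
    """Average together detections closer than ``radius`` arcmin."""
    if xy.shape[0] < 2:
        return xy
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius)
    if not pairs:
        return xy
    # union-find over close pairs
    parent = np.arange(xy.shape[0])

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        parent[find(a)] = find(b)
    roots = np.array([find(i) for i in range(xy.shape[0])])
    out = []
    for root in np.unique(roots):
        out.append(xy[roots == root].mean(axis=0))
    return np.asarray(out)


def _distance_to_hull(points: np.ndarray, hull: ConvexHull) -> np.ndarray:
    """Distance from each point to the convex-hull boundary polygon."""
    verts = points[hull.vertices]
    starts = verts
    ends = np.roll(verts, -1, axis=0)
    seg = ends - starts  # (m, 2)
    seg_len2 = np.maximum(np.sum(seg**2, axis=1), 1e-300)
    # (n, m) projections of every point onto every hull edge
    diff = points[:, None, :] - starts[None, :, :]
    t = np.clip(np.einsum("nmk,mk->nm", diff, seg) / seg_len2, 0.0, 1.0)
    proj = starts[None, :, :] + t[:, :, None] * seg[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def compute_icd(mosaic: ConeMosaic) -> SpacingMetrics:
    """Per-cone ICD from Delaunay neighbors; boundary cones flagged.

    Cones on the convex hull, or within three quarters of the median edge
    length of the hull boundary (the rim of a cropped patch, where Delaunay
    neighborhoods are truncated), keep their ICD value but are flagged so
    that summary statistics can exclude them.
    """
    pos = mosaic.positions
    if pos.shape[0] < 7:
        raise ValueError(f"need >= 7 cones for spacing metrics, got {pos.shape[0]}")
    try:
        tri = Delaunay(pos)
        hull = ConvexHull(pos)
    except QhullError as exc:
        raise ValueError(
            "degenerate cone configuration (collinear or coincident points): "
            f"{exc}"
        ) from exc

    n = pos.shape[0]
    neighbor_sum = np.zeros(n)
    neighbor_count = np.zeros(n, dtype=int)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    for a, b in edges:
        d = float(np.hypot(*(pos[a] - pos[b])))
        neighbor_sum[a] += d
        neighbor_sum[b] += d
        neighbor_count[a] += 1
        neighbor_count[b] += 1
    icd = neighbor_sum / np.maximum(neighbor_count, 1)
    median_edge = float(np.median([np.hypot(*(pos[a] - pos[b])) for a, b in edges]))
    boundary = _distance_to_hull(pos, hull) < 0.75 * median_edge
    boundary[hull.vertices] = True
    return SpacingMetrics(positions=pos, icd=icd, boundary=boundary)


def delaunay_neighbor_counts(mosaic: ConeMosaic) -> np.ndarray:
    """Number of Delaunay neighbors per cone (6 for a perfect lattice interior)."""
    pos = mosaic.positions
    tri = Delaunay(pos)
    counts = np.zeros(pos.shape[0], dtype=int)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    for a, b in edges:
        counts[a] += 1
        counts[b] += 1
    return counts


def icd_to_nc(icd):
    """Nyquist limit of a triangular mosaic from its ICD: ``(sqrt(3)/2)*ICD``."""
    icd = np.asarray(icd, dtype=float)
    if np.any(icd <= 0):
        raise ValueError("ICD must be positive")
    out = SQRT3_OVER_2 * icd
    return float(out) if out.ndim == 0 else out


def density_to_nc(d: float, m: float) -> float:
    """Nyquist limit (arcmin) from areal cone density.

    For triangular packing with density ``d`` cones/mm², the spacing is
    ``s = sqrt(2 / (sqrt(3) d))`` mm and ``N_c = (sqrt(3)/2) * s``, converted
    to arcmin with ``m`` mm/degree (60 arcmin per degree).
    """
    if d <= 0 or m <= 0:
        raise ValueError("density and magnification must be positive")
    s_mm = math.sqrt(2.0 / (math.sqrt(3.0) * d))
    return SQRT3_OVER_2 * s_mm / m * 60.0


def spacing_to_density(icd_arcmin: float, m: float) -> float:
    """Areal density (cones/mm²) of a triangular lattice with given ICD.

    Inverse of the density relation used by :func:`density_to_nc`:
    ``d = 2 / (sqrt(3) s²)`` with ``s`` in mm.
    """
    if icd_arcmin <= 0 or m <= 0:
        raise ValueError("spacing and magnification must be positive")
    s_mm = icd_arcmin / 60.0 * m
    return 2.0 / (math.sqrt(3.0) * s_mm**2)


def region_average_nc(
    metrics: SpacingMetrics,
    trace: MotionTrace,
    min_axis_arcmin: float = 1.0,
    include_boundary: bool = False,
) -> float:
    """Mean N_c over the ±2 SD elliptical stimulus region of a trace.

    The ellipse is centered on the mean stimulus position with semi-axes
    ``2*SD_x`` and ``2*SD_y``, floored at ``min_axis_arcmin`` so that a
    (near-)stationary trace still defines a usable region.
    """
    if len(trace) == 0:
        raise ValueError("empty motion trace")
    cx, cy = float(np.mean(trace.x)), float(np.mean(trace.y))
    ax = max(2.0 * float(np.std(trace.x)), min_axis_arcmin)
    ay = max(2.0 * float(np.std(trace.y)), min_axis_arcmin)
    dx = (metrics.positions[:, 0] - cx) / ax
    dy = (metrics.positions[:, 1] - cy) / ay
    inside = dx**2 + dy**2 <= 1.0
    if not include_boundary:
        inside &= ~metrics.boundary
    if not np.any(inside):
        raise ValueError(
            f"no cones inside the ±2 SD ellipse at ({cx:.2f}, {cy:.2f}) arcmin "
            f"with semi-axes ({ax:.2f}, {ay:.2f}); enlarge the region"
        )
    return float(np.mean(metrics.nc[inside]))


def minimum_icd(
    metrics: SpacingMetrics,
    smooth_radius_deg: float = 0.25,
    max_ecc_arcmin: float | None = 3.0,
    exclude_boundary: bool = True,
) -> float:
    """Minimum per-cone ICD after local smoothing, near the PRLF.

    Per-cone ICD is smoothed with a circular mean filter of radius
    ``smooth_radius_deg`` (to suppress single-cone noise) and the minimum is
    taken over cones within ``max_ecc_arcmin`` of the PRLF (pass None to
    search everywhere).
    """
    pos = metrics.positions
    tree = cKDTree(pos)
    radius = smooth_radius_deg * 60.0
    keep = ~metrics.boundary if exclude_boundary else np.ones(len(metrics.icd), bool)
    if max_ecc_arcmin is not None:
        keep &= np.hypot(pos[:, 0], pos[:, 1]) <= max_ecc_arcmin
    if not np.any(keep):
        raise ValueError("no cones in the minimum-ICD search region")
    smoothed = np.empty(pos.shape[0])
    candidates = np.nonzero(keep)[0]
    for i in candidates:
        idx = tree.query_ball_point(pos[i], radius)
        vals = metrics.icd[idx]
        flags = metrics.boundary[idx]
        use = vals[~flags] if exclude_boundary and np.any(~flags) else vals
        smoothed[i] = float(np.mean(use))
    return float(np.min(smoothed[candidates]))
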