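"""Cone-stimulus interaction: PSF-blurred letters integrated over cone apertures.

To visualize how many cones participate in resolving a letter at threshold,
the stimulus (a dark tumbling E on a bright field, Weber contrast -0.99) is
blurred by the diffraction-limited point-spread function of a 6 mm pupil at
the stimulating wavelength, and the blurred darkness profile is integrated
against each cone's aperture — a 2-D Gaussian with full width at half
maximum equal to 34% of the local inter-cone distance.  Per-cone values are
normalized to the maximum across cones, giving the "aperture filling" maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import j1

from foveal_limits.mosaic import ConeMosaic, SpacingMetrics

RAD_TO_ARCMIN = 180.0 / math.pi * 60.0
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
APERTURE_FWHM_FRACTION = 0.34
WEBER_CONTRAST = -0.99

ORIENTATION_ROTATIONS = {"right": 0, "up": 1, "left": 2, "down": 3}


@dataclass(frozen=True)
class PSF:
    """Sampled point-spread function kernel (unit sum)."""

    kernel: np.ndarray
    grid_arcmin: float
    pupil_mm: float
    wavelength_nm: float

    @property
    def airy_radius_arcmin(self) -> float:
        return airy_radius_arcmin(self.pupil_mm, self.wavelength_nm)

    @property
    def radius_arcmin(self) -> float:
        return (self.kernel.shape[0] // 2) * self.grid_arcmin


def airy_radius_arcmin(pupil_mm: float, wavelength_nm: float) -> float:
    """First minimum of the Airy pattern, 1.22 * lambda / D, in arcmin."""
    return 1.22 * (wavelength_nm * 1e-9) / (pupil_mm * 1e-3) * RAD_TO_ARCMIN


def diffraction_psf(
    pupil_mm: float = 6.0,
    wavelength_nm: float = 680.0,
    grid_arcmin: float = 0.025,
    n_zeros: float = 3.0,
) -> PSF:
    """Diffraction-limited PSF (Airy pattern) for a circular pupil.

    The kernel extends to ``n_zeros`` Airy radii and is normalized to unit
    sum.  ``grid_arcmin`` must resolve the Airy core (at most a quarter of
    the Airy radius).
    """
    r0 = airy_radius_arcmin(pupil_mm, wavelength_nm)
    if grid_arcmin > 0.25 * r0:
        raise ValueError(
            f"grid {grid_arcmin} arcmin too coarse for Airy radius {r0:.4f} "
            "arcmin (need <= 1/4 of it)"
        )
    half = int(math.ceil(n_zeros * r0 / grid_arcmin))
    ax = np.arange(-half, half + 1) * grid_arcmin
    xx, yy = np.meshgrid(ax, ax)
    theta = np.hypot(xx, yy) / RAD_TO_ARCMIN  # radians
    v = math.pi * (pupil_mm * 1e-3) / (wavelength_nm * 1e-9) * theta
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(v == 0.0, 1.0, 2.0 * j1(v) / np.where(v == 0.0, 1.0, v))
    kernel = amp**2
    kernel /= kernel.sum()
    return PSF(kernel=kernel, grid_arcmin=grid_arcmin, pupil_mm=pupil_mm,
               wavelength_nm=wavelength_nm)


def tumbling_e_mask(
    e_size: float, orientation: str, grid_arcmin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Darkness mask of a tumbling E and its axis (arcmin, letter-centered).

    The letter is a 5 x 5 grid of cells with side ``e_size / 5`` (stroke
    width = MAR convention): spine column plus three bars.  ``orientation``
    is the direction the letter's opening faces.  Darkness is
    ``|Weber contrast|`` inside strokes, 0 elsewhere.
    """
    if orientation not in ORIENTATION_ROTATIONS:
        raise ValueError(f"orientation {orientation!r} not in {list(ORIENTATION_ROTATIONS)}")
    half = e_size / 2.0
    n = max(int(round(e_size / grid_arcmin)), 5)
    ax = (np.arange(n) + 0.5) * grid_arcmin - half
    xx, yy = np.meshgrid(ax, ax)
    u = e_size / 5.0
    col = np.clip(((xx + half) / u).astype(int), 0, 4)
    row = np.clip(((yy + half) / u).astype(int), 0, 4)
    mask = (col == 0) | (row == 0) | (row == 2) | (row == 4)
    mask = np.rot90(mask, k=ORIENTATION_ROTATIONS[orientation])
    return abs(WEBER_CONTRAST) * mask.astype(float), ax


@dataclass(frozen=True)
class StimulationMap:
    """Normalized per-cone stimulation for one letter presentation."""

    positions: np.ndarray  # (n, 2) arcmin
    values: np.ndarray  # (n,) normalized to [0, 1]
    e_size: float
    orientation: str
    position: tuple[float, float]
    psf: PSF

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cone_index": np.arange(len(self.values)),
                "x_arcmin": self.positions[:, 0],
                "y_arcmin": self.positions[:, 1],
                "stimulation": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_overlay(self, path, floor: float = 0.0) -> None:
        """Figure-style overlay: cone apertures colored by stimulation."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axis = plt.subplots(figsize=(5, 5))
        sel = self.values >= floor
        sc = axis.scatter(
            self.positions[sel, 0],
            self.positions[sel, 1],
            c=self.values[sel],
            cmap="coolwarm",
            s=25,
            vmin=0.0,
            vmax=1.0,
        )
        fig.colorbar(sc, ax=axis, label="normalized cone stimulation")
        axis.set_xlabel("x (arcmin)")
        axis.set_ylabel("y (arcmin)")
        axis.set_aspect("equal")
        axis.invert_yaxis()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def stimulation_map(
    mosaic: ConeMosaic,
    metrics: SpacingMetrics,
    e_size: float,
    orientation: str = "right",
    position: tuple[float, float] = (0.0, 0.0),
    psf: PSF | None = None,
) -> StimulationMap:
    """Per-cone aperture filling by a PSF-blurred tumbling E.

    The blurred darkness profile is integrated against each cone's
    unit-integral Gaussian aperture (FWHM = 0.34 x local ICD from
    ``metrics``); the per-cone integrals are normalized by their maximum.
    An empty or out-of-reach cone set yields an all-zero map with a warning.
    """
    if psf is None:
        psf = diffraction_psf()
    if e_size <= 0:
        raise ValueError("e_size must be positive")
    h = psf.grid_arcmin
    darkness, _ = tumbling_e_mask(e_size, orientation, h)
    blurred = fftconvolve(darkness, psf.kernel, mode="full")
    # canvas coordinates (arcmin) relative to the letter center
    n_rows = blurred.shape[0]
    half_extent = (n_rows - 1) / 2.0 * h
    ax = np.linspace(-half_extent, half_extent, n_rows)

    pos = mosaic.positions
    n = pos.shape[0]
    values = np.zeros(n)
    if n == 0:
        warnings.warn("stimulation_map: empty cone set; all-zero map")
        return StimulationMap(pos, values, e_size, orientation, position, psf)

    sigma = APERTURE_FWHM_FRACTION * metrics.icd * FWHM_TO_SIGMA  # per cone, arcmin
    rel = pos - np.asarray(position, dtype=float)
    for i in range(n):
        s = sigma[i]
        reach = 3.0 * s
        if (
            rel[i, 0] + reach < ax[0]
            or rel[i, 0] - reach > ax[-1]
            or rel[i, 1] + reach < ax[0]
            or rel[i, 1] - reach > ax[-1]
        ):
            continue
        ix = np.searchsorted(ax, [rel[i, 0] - reach, rel[i, 0] + reach])
        iy = np.searchsorted(ax, [rel[i, 1] - reach, rel[i, 1] + reach])
        ix0, ix1 = max(ix[0] - 1, 0), min(ix[1] + 1, n_rows)
        iy0, iy1 = max(iy[0] - 1, 0), min(iy[1] + 1, n_rows)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        gx = np.exp(-0.5 * ((ax[ix0:ix1] - rel[i, 0]) / s) ** 2)
        gy = np.exp(-0.5 * ((ax[iy0:iy1] - rel[i, 1]) / s) ** 2)
        aperture = np.outer(gy, gx) / (2.0 * math.pi * s**2) * h**2
        values[i] = float(np.sum(blurred[iy0:iy1, ix0:ix1] * aperture))

    vmax = values.max()
    if vmax <= 0:
        warnings.warn("stimulation_map: stimulus does not reach any cone; zero map")
    else:
        values = values / vmax
    return StimulationMap(pos, values, e_size, orientation, position, psf)


def count_stimulated(smap: StimulationMap, floor: float = 0.5) -> int:
    """Number of cones with normalized stimulation at or above ``floor``."""
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must be in (0, 1)")
    return int(np.count_nonzero(smap.values >= floor))
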