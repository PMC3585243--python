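"""Sampling-limit models: midget-RGC Nyquist limit vs eccentricity.

Visual resolution in the central visual field is bounded by whichever neural
array samples most coarsely: the cone mosaic (Nyquist limit ``N_c``) at the
foveal center, and the midget retinal ganglion cell (mRGC) receptive-field
mosaic (``N_mRGC``) beyond it.  The mRGC receptive-field density model of
Drasdo et al. (2007), in the closed-form parameterization fit by Watson
(2014, J. Vision 14(7):15) for the temporal retinal meridian, supplies
``d_mRGCf(e)`` in receptive fields per deg².  ON- and OFF-center mRGC
sub-mosaics are treated as spatially redundant, so the Nyquist-relevant
density is one polarity's: half the total.

For a triangular array of density ``d`` (per deg²) the row spacing — the
Nyquist half-period — is ``(sqrt(3)/2) * sqrt(2 / (sqrt(3) d))`` degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from foveal_limits.mosaic import SpacingMetrics

# Watson (2014) Table 1, temporal meridian of the visual field; d(0) is the
# foveal-center mRGC receptive-field density, 2 x peak cone density.
_WATSON_TEMPORAL = {"d0": 29609.2, "a": 0.9851, "r2": 1.058, "re": 22.14}

ECC_MAX_DEG = 10.0


def _watson_density(ecc_deg, d0, a, r2, re):
    ecc = np.asarray(ecc_deg, dtype=float)
    return d0 * (a * (1.0 + ecc / r2) ** -2 + (1.0 - a) * np.exp(-ecc / re))


@dataclass(frozen=True)
class MRGCModel:
    """mRGC receptive-field density as a function of eccentricity.

    ``density`` maps eccentricity (degrees) to total mRGC receptive fields
    per deg² of visual field; it must be positive and strictly decreasing on
    (0, 10°].  The default is the Drasdo-model temporal-meridian fit.
    """

    density: Callable[[float], float] = field(
        default=lambda ecc: float(_watson_density(ecc, **_WATSON_TEMPORAL))
    )
    tag: str = "drasdo2007-watson2014-temporal"

    def rescaled(self, factor: Callable[[float], float], tag: str = "rescaled") -> "MRGCModel":
        """Model with density multiplied by ``factor(ecc)`` (e.g. coupled loss)."""
        base = self.density
        return MRGCModel(density=lambda ecc: base(ecc) * factor(ecc), tag=tag)


def triangular_nyquist_deg(density_per_deg2: float) -> float:
    """Nyquist half-period (deg) of a triangular array of given density."""
    if density_per_deg2 <= 0:
        raise ValueError("density must be positive")
    spacing = math.sqrt(2.0 / (math.sqrt(3.0) * density_per_deg2))
    return (math.sqrt(3.0) / 2.0) * spacing


def nmrgc(ecc: float, model: MRGCModel | None = None) -> float:
    """Nyquist limit of the mRGC receptive-field mosaic, in arcmin.

    Computed on the ON-subfield density (total / 2).  Valid for
    0 <= ecc <= 10 degrees, the range over which the parameterization is
    calibrated.
    """
    if model is None:
        model = MRGCModel()
    if not 0.0 <= ecc <= ECC_MAX_DEG:
        raise ValueError(f"eccentricity {ecc} outside calibrated range [0, {ECC_MAX_DEG}]")
    d_on = model.density(float(ecc)) / 2.0
    return 60.0 * triangular_nyquist_deg(d_on)


def eccentricity_shift(
    mar: float, observed_ecc: float, model: MRGCModel | None = None
) -> float:
    """Eccentricity displacement implied by a resolution measurement.

    Solves ``nmrgc(e*) = mar`` by bisection on [0, 10°] and returns
    ``e* - observed_ecc``: how far peripheral of the observed location a
    normal retina would have to be to show the same neural limit.
    """
    if model is None:
        model = MRGCModel()
    lo, hi = 0.0, ECC_MAX_DEG
    f_lo = nmrgc(lo, model) - mar
    f_hi = nmrgc(hi, model) - mar
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no eccentricity in [0, {ECC_MAX_DEG}] deg has N_mRGC = {mar} arcmin"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = nmrgc(mid, model) - mar
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi) - observed_ecc


@dataclass(frozen=True)
class LimitComparison:
    eccentricity: float
    mar_ao: float
    nc: float
    nmrgc: float
    predicted_mar: float

    @property
    def residual(self) -> float:
        return self.mar_ao - self.predicted_mar


def compare_limits(
    measurements: Sequence[tuple[float, float]],
    nc_at: Callable[[float], float] | SpacingMetrics,
    model: MRGCModel | None = None,
) -> list[LimitComparison]:
    """Tabulate measured resolution against the cone and mRGC Nyquist limits.

    Parameters
    ----------
    measurements : sequence of (eccentricity_deg, mar_ao_arcmin)
    nc_at : callable or SpacingMetrics
        Region-averaged cone Nyquist limit at each eccentricity.  A
        SpacingMetrics is evaluated by averaging interior cones within
        ±0.1° of the requested eccentricity.
    model : MRGCModel, optional

    The predicted limit is ``max(N_c, N_mRGC)``: resolution cannot beat the
    coarser of the two sampling arrays.
    """
    if model is None:
        model = MRGCModel()
    if isinstance(nc_at, SpacingMetrics):
        metrics = nc_at

        def nc_fn(ecc: float) -> float:
            sel = (~metrics.boundary) & (np.abs(metrics.eccentricity - ecc) <= 0.1)
            if not np.any(sel):
                raise ValueError(f"no interior cones within 0.1 deg of {ecc} deg")
            return float(np.mean(metrics.nc[sel]))

    else:
        nc_fn = nc_at
    out = []
    for ecc, mar_ao in measurements:
        nc_val = float(nc_fn(ecc))
        nm = nmrgc(ecc, model)
        out.append(
            LimitComparison(
                eccentricity=float(ecc),
                mar_ao=float(mar_ao),
                nc=nc_val,
                nmrgc=nm,
                predicted_mar=max(nc_val, nm),
            )
        )
    return out


def transition_eccentricity(
    nc_fn: Callable[[float], float],
    model: MRGCModel | None = None,
    lo: float = 0.0,
    hi: float = 1.0,
    n_grid: int = 2001,
) -> float:
    """Eccentricity where N_mRGC first overtakes N_c (the ``private line`` edge).

    Inside this eccentricity the cone mosaic is the bottleneck; outside it,
    mRGC convergence is.  Grid scan + sign change; raises if no crossing.
    """
    if model is None:
        model = MRGCModel()
    ecc = np.linspace(lo, hi, n_grid)
    diff = np.array([nmrgc(e, model) - nc_fn(e) for e in ecc])
    sign_change = np.nonzero(np.diff(np.signbit(diff)))[0]
    if sign_change.size == 0:
        raise ValueError(f"no N_c/N_mRGC crossing in [{lo}, {hi}] deg")
    i = sign_change[0]
    # linear interpolation within the bracketing grid cell
    e0, e1 = ecc[i], ecc[i + 1]
    d0, d1 = diff[i], diff[i + 1]
    return float(e0 - d0 * (e1 - e0) / (d1 - d0))
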