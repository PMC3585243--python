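"""Midget-RGC sampling limits and comparisons with measured resolution."""

import numpy as np
import pytest

from foveal_limits import limits
from foveal_limits.limits import (
    MRGCModel,
    compare_limits,
    eccentricity_shift,
    nmrgc,
    transition_eccentricity,
    triangular_nyquist_deg,
)
from foveal_limits.mosaic import icd_to_nc
from foveal_limits.synthgen import MosaicSpec


def test_inverse_at_carrier_acuity_lands_near_2p3_deg():
    """A 1.41-arcmin neural limit corresponds to ~2.3 deg in a normal retina."""
    shift = eccentricity_shift(1.41, observed_ecc=0.0)
    assert shift == pytest.approx(2.3, abs=0.15)
    # observed at 0.86 deg: the carrier retina is eccentricity-shifted ~1.44 deg
    assert eccentricity_shift(1.41, observed_ecc=0.86) == pytest.approx(1.44, abs=0.15)


def test_nmrgc_monotone_increasing():
    vals = [nmrgc(e) for e in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
    assert vals == sorted(vals)
    assert vals[0] < vals[-1]


def test_density_strictly_decreasing():
    model = MRGCModel()
    ecc = np.linspace(0.0, 10.0, 200)
    dens = np.array([model.density(e) for e in ecc])
    assert np.all(np.diff(dens) < 0)
    assert np.all(dens > 0)


def test_foveal_private_line_equals_cone_limit():
    """With a 2:1 mRGC:cone ratio, the ON-subfield density equals cone
    density, so the mRGC Nyquist limit equals N_c at the foveal center."""
    model = MRGCModel()
    d_cone = model.density(0.0) / 2.0  # receptive fields per deg², one polarity
    nc = 60.0 * triangular_nyquist_deg(d_cone)
    assert nmrgc(0.0, model) == pytest.approx(nc, rel=1e-12)


def test_out_of_range_eccentricity():
    with pytest.raises(ValueError):
        nmrgc(12.0)
    with pytest.raises(ValueError):
        nmrgc(-0.1)


def test_bisection_matches_grid_scan():
    mar = 1.2
    grid = np.linspace(0.0, 10.0, 1001)
    vals = np.array([nmrgc(e) for e in grid])
    idx = int(np.argmin(np.abs(vals - mar)))
    e_star = eccentricity_shift(mar, observed_ecc=0.0)
    assert abs(e_star - grid[idx]) <= grid[1] - grid[0]


def test_shift_roundtrip_identity():
    e0 = 1.7
    mar = nmrgc(e0)
    assert eccentricity_shift(mar, observed_ecc=e0) == pytest.approx(0.0, abs=1e-6)


def test_no_root_raises():
    with pytest.raises(ValueError, match="no eccentricity"):
        eccentricity_shift(0.01, observed_ecc=0.0)


def test_single_crossing_below_one_degree():
    """For a normal mosaic the cone limit exceeds the mRGC limit at the
    fovea center and falls below it before 1 degree (private-line zone)."""
    spec = MosaicSpec(peak_icd=0.58, icd_slope=0.35)
    nc_fn = lambda e: float(icd_to_nc(spec.spacing(e)))
    e_cross = transition_eccentricity(nc_fn)
    assert 0.0 < e_cross < 1.0
    # single crossing: sign pattern of (nmrgc - nc) changes exactly once
    ecc = np.linspace(0.001, 1.0, 400)
    diff = np.array([nmrgc(e) - nc_fn(e) for e in ecc])
    assert np.count_nonzero(np.diff(np.signbit(diff))) == 1


def test_compare_limits_residual_zero_at_prlf():
    spec = MosaicSpec(peak_icd=0.58, icd_slope=0.35)
    nc_fn = lambda e: float(icd_to_nc(spec.spacing(e)))
    mar0 = nc_fn(0.0)  # at the PRLF, resolution equals the cone limit
    table = compare_limits([(0.0, mar0)], nc_fn)
    assert table[0].predicted_mar == pytest.approx(nc_fn(0.0))
    assert table[0].residual == pytest.approx(0.0, abs=1e-12)


def test_compare_limits_slope_near_unity(rng):
    """Parameter recovery: simulated MAR = max(N_c, N_mRGC) + noise gives a
    regression of measured on predicted with slope ~1."""
    spec = MosaicSpec(peak_icd=0.58, icd_slope=0.35)
    nc_fn = lambda e: float(icd_to_nc(spec.spacing(e)))
    eccs = np.tile(np.linspace(0.0, 2.5, 6), 8)
    meas = [
        (e, max(nc_fn(e), nmrgc(e)) + rng.normal(0.0, 0.05)) for e in eccs
    ]
    table = compare_limits(meas, nc_fn)
    pred = np.array([c.predicted_mar for c in table])
    obs = np.array([c.mar_ao for c in table])
    slope = np.polyfit(pred, obs, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.1)


def test_coupled_loss_model_flattens_residuals(rng):
    """Carrier-like data: with the mRGC model rescaled to the local cone
    limit, residuals vanish; with the normal model they are positive
    off-PRLF."""
    spec = MosaicSpec(peak_icd=0.75, icd_slope=0.45)  # enlarged spacing
    nc_fn = lambda e: float(icd_to_nc(spec.spacing(e)))
    normal_spec = MosaicSpec(peak_icd=0.58, icd_slope=0.35)
    nc_normal = lambda e: float(icd_to_nc(normal_spec.spacing(e)))
    model = MRGCModel()
    coupled = model.rescaled(lambda e: (nc_normal(e) / nc_fn(e)) ** 2, tag="coupled")

    eccs = [0.5, 1.0, 1.5, 2.0, 2.5]
    meas = [(e, max(nc_fn(e), nmrgc(e, coupled))) for e in eccs]
    coupled_table = compare_limits(meas, nc_fn, model=coupled)
    normal_table = compare_limits(meas, nc_fn, model=model)
    assert np.allclose([c.residual for c in coupled_table], 0.0, atol=1e-9)
    assert all(c.residual > 0 for c in normal_table)


def test_compare_limits_accepts_metrics(graded_patch_1deg):
    from foveal_limits.mosaic import compute_icd

    spec, patch = graded_patch_1deg
    metrics = compute_icd(patch)
    table = compare_limits([(1.0, 1.0)], metrics)
    assert table[0].nc == pytest.approx(float(icd_to_nc(spec.spacing(1.0))), rel=0.03)
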