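"""Cone localization, ICD/N_c metrics, density conversions, region averages."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from foveal_limits import mosaic, synthgen
from foveal_limits.groupstats import round_half_up
from foveal_limits.mosaic import (
    ConeMosaic,
    Frame,
    compute_icd,
    density_to_nc,
    icd_to_nc,
    localize_cones,
    minimum_icd,
    region_average_nc,
    spacing_to_density,
)
from foveal_limits.motionstats import MotionTrace
from foveal_limits.synthgen import MosaicSpec


def test_perfect_lattice_icd_exact(lattice_metrics):
    interior = lattice_metrics.interior_icd
    assert interior == pytest.approx(0.84, abs=1e-9)


def test_square_lattice_icd_range():
    # 10x10 unit grid: diagonal Delaunay edges lift interior ICD above s
    xx, yy = np.mgrid[0:10, 0:10]
    met = compute_icd(ConeMosaic(np.column_stack([xx.ravel() * 1.0, yy.ravel() * 1.0])))
    assert np.all(met.interior_icd >= 1.0 - 1e-12)
    assert np.all(met.interior_icd <= 1.21)


@pytest.mark.parametrize(
    "icd,expected",
    [(0.84, 0.73), (0.76, 0.66), (0.79, 0.68)],
)
def test_icd_to_nyquist_printed_pairs(icd, expected):
    assert round_half_up(icd_to_nc(icd), 2) == expected


def test_icd_to_nyquist_identity():
    assert icd_to_nc(2.0 / math.sqrt(3.0)) == pytest.approx(1.0, rel=1e-12)


def test_mean_minimum_nyquist():
    nc = icd_to_nc(np.array([0.84, 0.79, 0.79, 0.76]))
    assert round_half_up(float(np.mean(nc)), 2) == 0.69


def test_density_to_nyquist():
    assert round_half_up(density_to_nc(199_000, 0.289), 2) == 0.43


def test_density_spacing_roundtrip():
    # lattice with ICD 1 arcmin: density -> N_c closes the loop exactly
    m = 0.289
    d = spacing_to_density(1.0, m)
    assert density_to_nc(d, m) == pytest.approx(math.sqrt(3.0) / 2.0, rel=1e-12)


def test_density_scaling_law():
    base = density_to_nc(150_000, 0.289)
    assert density_to_nc(300_000, 0.289) == pytest.approx(base / math.sqrt(2.0))
    with pytest.raises(ValueError):
        density_to_nc(-1.0, 0.289)


def test_localize_noiseless_lattice_recall(lattice_mosaic):
    frame = synthgen.render_frame(lattice_mosaic, noise_sd=0.0)
    found = localize_cones(frame)
    truth = lattice_mosaic.positions
    d, _ = cKDTree(found.positions).query(truth)
    recall = np.mean(d < 0.5 * 0.84)
    assert recall >= 0.99
    assert np.sqrt(np.mean(d[d < 0.42] ** 2)) < 0.05


def test_localize_pure_noise_few_spurious(rng):
    img = np.clip(rng.normal(0.2, 0.05, (432, 384)), 0, 1)
    found = localize_cones(Frame(img))
    assert len(found) <= 5


def test_localize_single_cone():
    m = ConeMosaic(np.array([[0.0, 0.0]]))
    frame = synthgen.render_frame(m, noise_sd=0.0, blob_sigma_arcmin=0.25)
    found = localize_cones(frame)
    assert len(found) == 1
    assert np.hypot(*found.positions[0]) < 0.05


def test_localize_flat_frame_warns():
    with pytest.warns(UserWarning, match="flat"):
        found = localize_cones(Frame(np.full((100, 100), 0.5)))
    assert len(found) == 0 and found.warning == "flat frame"


def test_empty_mosaic_renders_uniform_background():
    frame = synthgen.render_frame(ConeMosaic(np.empty((0, 2))), noise_sd=0.0)
    assert np.ptp(frame.image) == 0.0


def test_compute_icd_requires_enough_cones():
    with pytest.raises(ValueError, match=">= 7"):
        compute_icd(ConeMosaic(np.array([[0, 0], [1, 0], [0, 1.0]])))


def test_collinear_input_names_degeneracy():
    pts = np.column_stack([np.arange(8.0), np.zeros(8)])
    with pytest.raises(ValueError, match="degenerate|collinear"):
        compute_icd(ConeMosaic(pts))


def test_duplicate_positions_rejected():
    with pytest.raises(ValueError, match="closer"):
        ConeMosaic(np.array([[0.0, 0.0], [0.01, 0.0]]))


def test_region_average_uniform_mosaic(lattice_metrics, rng):
    trace = MotionTrace(rng.normal(0, 2.0, 120), rng.normal(0, 2.0, 120))
    avg = region_average_nc(lattice_metrics, trace)
    assert avg == pytest.approx(icd_to_nc(0.84), rel=1e-6)


def test_region_average_zero_variance_trace(lattice_metrics):
    trace = MotionTrace(np.zeros(50), np.zeros(50))
    avg = region_average_nc(lattice_metrics, trace)
    # floored 1-arcmin ellipse ~ the nearest-cone neighborhood
    pos = lattice_metrics.positions
    near = np.hypot(pos[:, 0], pos[:, 1]) <= 1.0
    expected = float(np.mean(lattice_metrics.nc[near & ~lattice_metrics.boundary]))
    assert avg == pytest.approx(expected)


def test_region_average_gradient_matches_analytic(graded_patch_1deg, rng):
    spec, patch = graded_patch_1deg
    metrics = compute_icd(patch)
    trace = MotionTrace(60.0 + rng.normal(0, 1.5, 240), rng.normal(0, 1.5, 240))
    avg = region_average_nc(metrics, trace)
    assert avg == pytest.approx(icd_to_nc(spec.spacing(1.0)), rel=0.02)


def test_region_average_empty_region(lattice_metrics):
    trace = MotionTrace(np.full(50, 500.0), np.full(50, 500.0))
    with pytest.raises(ValueError, match="enlarge"):
        region_average_nc(lattice_metrics, trace)


def test_pipeline_translation_invariance():
    spec = MosaicSpec(peak_icd=1.0, icd_slope=0.0, jitter_sd=0.04, extent=0.3, seed=9)
    m = synthgen.generate_mosaic(spec)
    base = compute_icd(m)
    shifted = compute_icd(m.translated(3.0, -2.0))
    a = float(np.mean(base.interior_icd))
    b = float(np.mean(shifted.interior_icd))
    assert b == pytest.approx(a, rel=0.005)


def test_minimum_icd_near_prlf():
    spec = MosaicSpec(peak_icd=0.8, icd_slope=0.35, jitter_sd=0.04, extent=0.2, seed=5)
    patch = synthgen.generate_mosaic(spec)
    metrics = compute_icd(patch)
    # tight smoothing so the gradient does not inflate the local average
    m_min = minimum_icd(metrics, smooth_radius_deg=0.05, max_ecc_arcmin=3.0)
    assert m_min == pytest.approx(spec.peak_icd, rel=0.05)
    # a wider smoothing disk mixes in larger eccentric spacings
    wide = minimum_icd(metrics, smooth_radius_deg=0.25, max_ecc_arcmin=3.0)
    assert wide >= m_min


def test_cone_csv_roundtrip(tmp_path, lattice_mosaic):
    path = tmp_path / "cones.csv"
    lattice_mosaic.to_csv(path)
    back = ConeMosaic.from_csv(path)
    np.testing.assert_allclose(back.positions, lattice_mosaic.positions)
    assert back.source == "localized"
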