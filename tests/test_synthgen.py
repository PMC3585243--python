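"""Ground-truth generators: mosaics, frames, motion, videos, observers."""

import math

import numpy as np
import pytest
from scipy import stats
from skimage.registration import phase_cross_correlation

from foveal_limits import mosaic, synthgen
from foveal_limits.mosaic import compute_icd, delaunay_neighbor_counts
from foveal_limits.synthgen import (
    InvalidSpecError,
    MosaicSpec,
    MotionSpec,
    ObserverSpec,
    Rect,
    VideoStack,
    alternation_schedule,
    generate_mosaic,
    generate_motion,
    generate_tca_video,
    make_observer,
    render_frame,
    spec_for_criterion,
)


def test_lattice_spacing_exact_at_center(lattice_metrics):
    center = np.hypot(*lattice_metrics.positions.T) < 3.0
    assert lattice_metrics.icd[center & ~lattice_metrics.boundary] == pytest.approx(
        0.84, abs=1e-9
    )


def test_graded_mosaic_spacing_at_2deg():
    spec = MosaicSpec(peak_icd=0.5, icd_slope=0.35, jitter_sd=0.05, loss_fraction=0.0,
                      extent=0.2, seed=1)
    m = generate_mosaic(spec, center_deg=(2.0, 0.0))
    met = compute_icd(m)
    sel = (~met.boundary) & (np.abs(met.eccentricity - 2.0) < 0.05)
    measured = float(np.mean(met.icd[sel]))
    assert measured == pytest.approx(1.2, rel=0.05)


def test_cone_loss_is_binomial():
    base = MosaicSpec(peak_icd=0.8, icd_slope=0.0, jitter_sd=0.0, loss_fraction=0.0,
                      extent=0.25, seed=7)
    lossy = MosaicSpec(peak_icd=0.8, icd_slope=0.0, jitter_sd=0.0, loss_fraction=0.5,
                       extent=0.25, seed=7)
    n0 = len(generate_mosaic(base))
    n1 = len(generate_mosaic(lossy))
    # 4-sigma binomial band around the expected survival count
    expected, sd = 0.5 * n0, math.sqrt(n0 * 0.25)
    assert abs(n1 - expected) < 4.0 * sd


def test_interior_cones_have_six_neighbors(lattice_mosaic, lattice_metrics):
    counts = delaunay_neighbor_counts(lattice_mosaic)
    assert np.all(counts[~lattice_metrics.boundary] == 6)


def test_fixed_seed_reproducibility():
    spec = MosaicSpec(peak_icd=0.6, icd_slope=0.3, jitter_sd=0.08, loss_fraction=0.2,
                      extent=0.15, seed=42)
    a, b = generate_mosaic(spec), generate_mosaic(spec)
    assert np.array_equal(a.positions, b.positions)
    ms = MotionSpec(seed=42, n_frames=100)
    ta, tb = generate_motion(ms), generate_motion(ms)
    assert np.array_equal(ta.positions, tb.positions)


def test_extent_too_small_raises():
    with pytest.raises(InvalidSpecError, match="< 7"):
        generate_mosaic(MosaicSpec(peak_icd=1.0, icd_slope=0.0, jitter_sd=0.0,
                                   extent=0.01))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(peak_icd=-1.0),
        dict(loss_fraction=1.0),
        dict(jitter_sd=-0.1),
    ],
)
def test_mosaic_spec_validation(kwargs):
    with pytest.raises(InvalidSpecError):
        MosaicSpec(**kwargs)


def test_spec_yaml_roundtrip(tmp_path):
    spec = MosaicSpec(peak_icd=0.7, icd_slope=0.2, jitter_sd=0.03, loss_fraction=0.1,
                      extent=0.2, seed=5)
    spec.to_yaml(tmp_path / "m.yaml")
    assert MosaicSpec.from_yaml(tmp_path / "m.yaml") == spec
    ospec = ObserverSpec(limit=1.3, seed=2)
    ospec.to_yaml(tmp_path / "o.yaml")
    assert ObserverSpec.from_yaml(tmp_path / "o.yaml") == ospec


def test_rendered_offset_recovered_by_registration(lattice_mosaic):
    """Independent oracle: phase correlation recovers a rigid 1-arcmin shift."""
    f0 = render_frame(lattice_mosaic, offset=(0.0, 0.0), noise_sd=0.0)
    f1 = render_frame(lattice_mosaic, offset=(1.0, 0.0), noise_sd=0.0)
    shift_px, _, _ = phase_cross_correlation(f0.image, f1.image, upsample_factor=20)
    ppa = f0.pixels_per_arcmin
    # skimage returns the shift of f1 relative to f0 as (row, col), negated
    dx, dy = -shift_px[1] / ppa, -shift_px[0] / ppa
    assert dx == pytest.approx(1.0, abs=0.1)
    assert dy == pytest.approx(0.0, abs=0.1)


def test_motion_trace_stationary_spread():
    spec = MotionSpec(drift_sd=0.1, microsaccade_rate=0.0, n_frames=4000, seed=3)
    trace = generate_motion(spec)
    # AR(1) stationary SD = step_sd / sqrt(1 - (1-lambda)^2)
    expected = spec.drift_sd / math.sqrt(1.0 - (1.0 - spec.reversion) ** 2)
    assert np.std(trace.x) == pytest.approx(expected, rel=0.25)


def test_tca_video_schedule_and_truth(tca_video):
    assert set(np.unique(tca_video.channel)) == {0, 1}
    # 2 Hz alternation at 30 Hz: half-cycles of 7-8 frames
    runs = np.diff(np.nonzero(np.diff(tca_video.channel))[0])
    assert set(runs.tolist()) <= {7, 8}
    assert tuple(tca_video.truth["tca_shift_arcmin"]) == (2.752, 0.500)
    assert len(tca_video.truth["trace_x"]) == len(tca_video)


def test_tca_video_window_must_be_inside():
    m = generate_mosaic(MosaicSpec(peak_icd=1.0, icd_slope=0.0, jitter_sd=0.0,
                                   extent=0.15, seed=1))
    with pytest.raises(ValueError, match="window"):
        generate_tca_video(
            m, None, tca_shift=(1.0, 0.0),
            motion=MotionSpec(n_frames=30),
            window=Rect(0.0, 0.0, 100.0, 10.0),
        )


def test_video_tiff_roundtrip(tmp_path, tca_video):
    path = tmp_path / "video.tiff"
    tca_video.save(path)
    back = VideoStack.load(path)
    assert back.frames.shape == tca_video.frames.shape
    assert np.max(np.abs(back.frames - tca_video.frames)) < 1e-4  # uint16 quantization
    assert np.array_equal(back.channel, tca_video.channel)
    assert back.window == tca_video.window


def test_alternation_schedule_duty_cycle():
    sched = alternation_schedule(300, 30.0, 2.0)
    assert abs(np.mean(sched) - 0.5) < 0.05


def test_observer_asymptotes():
    obs = make_observer(ObserverSpec(limit=1.0, slope=3.5, guess_rate=0.25,
                                     lapse_rate=0.02))
    assert obs.p_correct(1e6) == pytest.approx(0.98, abs=1e-9)
    assert obs.p_correct(1e-9) == pytest.approx(0.25, abs=1e-6)


def test_observer_empirical_matches_analytic():
    spec = ObserverSpec(limit=1.0, slope=3.5, guess_rate=0.25, lapse_rate=0.01, seed=0)
    obs = make_observer(spec)
    n = 10_000
    hits = sum(obs.respond(1.0) for _ in range(n))
    p = obs.p_correct(1.0)
    lo, hi = stats.binom.interval(0.99, n, p)
    assert lo <= hits <= hi


def test_spec_for_criterion_places_crossing():
    spec = spec_for_criterion(1.37, criterion=0.825)
    obs = make_observer(spec)
    assert obs.p_correct(1.37) == pytest.approx(0.825, rel=1e-9)
    assert obs.criterion_size(0.825) == pytest.approx(1.37, rel=1e-12)


@pytest.mark.parametrize(
    "kwargs", [dict(limit=-1.0), dict(guess_rate=0.3), dict(lapse_rate=0.2)]
)
def test_observer_spec_validation(kwargs):
    with pytest.raises(InvalidSpecError):
        ObserverSpec(**kwargs)
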