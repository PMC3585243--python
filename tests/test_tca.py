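"""Stabilization and transverse-chromatic-aberration estimation."""

import numpy as np
import pytest

from conftest import IR_REGION, small_tca_video
from foveal_limits import synthgen, tca
from foveal_limits.synthgen import MosaicSpec, MotionSpec, Rect, VideoStack


def _plain_video(motion_trace, noise_sd=0.0, seed=0):
    """Single-channel video of a jittered mosaic moving along a known trace."""
    m = synthgen.generate_mosaic(
        MosaicSpec(peak_icd=0.9, icd_slope=0.0, jitter_sd=0.08, extent=0.35, seed=seed)
    )
    rng = np.random.default_rng(seed + 1)
    frames = []
    for dx, dy in motion_trace:
        f = synthgen.render_frame(
            m, offset=(dx, dy), noise_sd=0.0, field_arcmin=(36.0, 36.0),
        )
        img = f.image
        if noise_sd:
            img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, 1)
        frames.append(img)
    return VideoStack(
        frames=np.stack(frames), field_arcmin=(36.0, 36.0),
        channel=np.zeros(len(frames), dtype=int),
    )


def test_static_video_zero_trace():
    video = _plain_video([(0.0, 0.0)] * 8)
    trace, stabilized = tca.stabilize(video, IR_REGION)
    assert np.max(np.abs(trace.positions)) < 1e-6
    assert stabilized is not None


def test_stabilize_recovers_injected_translation(rng):
    truth = np.column_stack([rng.uniform(-2, 2, 12), rng.uniform(-2, 2, 12)])
    truth[0] = 0.0  # reference frame
    video = _plain_video(truth, noise_sd=0.02)
    trace, _ = tca.stabilize(video, IR_REGION, resample=False)
    err_px = (trace.positions - truth) * video.pixels_per_arcmin
    assert np.sqrt(np.mean(err_px**2)) < 0.1


def test_blank_frame_interpolated():
    truth = np.column_stack([np.linspace(0, 2.0, 10), np.zeros(10)])
    video = _plain_video(truth)
    video.frames[5] = 0.0  # blink surrogate
    trace, _ = tca.stabilize(video, IR_REGION, resample=False)
    # displacement of the blank frame is filled from neighbors
    assert trace.x[5] == pytest.approx((trace.x[4] + trace.x[6]) / 2.0, abs=1e-9)


def test_stabilize_fails_when_mostly_blank():
    video = _plain_video([(0.0, 0.0)] * 8)
    video.frames[2:] = 0.0
    with pytest.raises(RuntimeError, match="confidence"):
        tca.stabilize(video, IR_REGION)


def test_estimate_recovers_injected_shift(tca_video):
    res = tca.estimate_tca(tca_video, IR_REGION, tca_video.window)
    assert res.horizontal == pytest.approx(2.752, abs=0.1)
    assert res.vertical == pytest.approx(0.500, abs=0.1)
    assert res.n_cycles_used >= 3


def test_zero_shift_below_noise_floor():
    video = small_tca_video(tca_shift=(0.0, 0.0), seed=5)
    res = tca.estimate_tca(video, IR_REGION, video.window)
    assert abs(res.horizontal) < 0.05
    assert abs(res.vertical) < 0.05


def test_outlier_cycles_rejected():
    # 3 corrupted cycles out of 20: at ~15% contamination the spurious
    # shifts sit beyond 2 SD of the cycle mean and are rejected
    video = small_tca_video(n_cycles=20, seed=2)
    clean = tca.estimate_tca(video, IR_REGION, video.window)
    # corrupt three red half-cycles with a large spurious displacement
    corrupted = VideoStack(
        frames=video.frames.copy(), field_arcmin=video.field_arcmin,
        frame_rate=video.frame_rate, channel=video.channel,
        window=video.window, truth=video.truth,
    )
    red_runs = [
        (start, stop)
        for ch, start, stop in tca._half_cycle_runs(video.channel)
        if ch == 1
    ]
    px = int(round(5.0 * video.pixels_per_arcmin))
    # displace only the alternating-window content (a stabilization-error
    # surrogate); a whole-frame shift would be absorbed by the first pass
    rs, cs = video.window.pixel_slices(video.frame(0))
    for start, stop in red_runs[1:4]:
        corrupted.frames[start:stop, rs, cs] = np.roll(
            corrupted.frames[start:stop, rs, cs], px, axis=2
        )
    res = tca.estimate_tca(corrupted, IR_REGION, corrupted.window)
    assert res.n_rejected >= 3
    assert res.horizontal == pytest.approx(clean.horizontal, abs=0.1)
    assert res.vertical == pytest.approx(clean.vertical, abs=0.1)


def test_swapping_channels_negates_shift(tca_video):
    res = tca.estimate_tca(tca_video, IR_REGION, tca_video.window)
    first_ir = int(np.nonzero(tca_video.channel == 0)[0][0])
    swapped = tca.estimate_tca(
        tca_video, IR_REGION, tca_video.window, first_red_frame=first_ir
    )
    assert swapped.horizontal == pytest.approx(-res.horizontal, abs=0.1)
    assert swapped.vertical == pytest.approx(-res.vertical, abs=0.1)


def test_recovery_error_grows_with_motion():
    """Sanity curve: more drift, no better recovery (weak monotonicity)."""

    def mean_err(drift, seeds=(11, 12)):
        errs = []
        for s in seeds:
            v = small_tca_video(drift_sd=drift, seed=s, n_cycles=6)
            r = tca.estimate_tca(v, IR_REGION, v.window)
            errs.append(np.hypot(r.horizontal - 2.752, r.vertical - 0.500))
        return float(np.mean(errs))

    assert mean_err(0.05) <= mean_err(1.2) + 0.02


def test_phase_index_validation(tca_video):
    with pytest.raises(ValueError, match="outside video"):
        tca.estimate_tca(tca_video, IR_REGION, tca_video.window,
                         first_red_frame=10_000)


def test_too_few_cycles_raises():
    video = small_tca_video(n_cycles=2, seed=3)
    with pytest.raises(RuntimeError, match="cycles"):
        tca.estimate_tca(video, IR_REGION, video.window)


def test_result_json(tmp_path, tca_video):
    res = tca.estimate_tca(tca_video, IR_REGION, tca_video.window)
    res.to_json(tmp_path / "tca.json")
    import json

    data = json.loads((tmp_path / "tca.json").read_text())
    assert data["horizontal_arcmin"] == pytest.approx(res.horizontal)
    assert data["n_cycles_used"] == res.n_cycles_used
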