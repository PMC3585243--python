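"""Transverse chromatic aberration (TCA) from dual-wavelength calibration videos.

TCA displaces the retinal image formed at one wavelength laterally relative
to another.  It is measured offline from a calibration video in which a
window region alternates at a known frequency between the imaging (IR) and
stimulating (red) wavelengths while the surround stays IR:

1. stabilize the video against a region imaged in a single wavelength
   (FFT cross-correlation peak, sub-pixel parabolic interpolation);
2. re-run the same stabilization on the wavelength-alternating region of
   the stabilized video — its residual motion trace is a square wave
   phase-locked to the alternation, whose amplitude is the TCA shift;
3. average per cycle, reject per-cycle shifts beyond 2 SD of the mean
   (stabilization errors from blinks/large saccades), and re-average.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from foveal_limits.motionstats import MotionTrace
from foveal_limits.synthgen import Rect, VideoStack

MIN_PEAK_CORRELATION = 0.15


@dataclass(frozen=True)
class TCAResult:
    """Estimated TCA shift in arcmin with per-cycle bookkeeping."""

    horizontal: float
    vertical: float
    n_cycles_used: int
    n_rejected: int
    per_cycle: np.ndarray  # (n_cycles, 2) raw per-cycle shifts, arcmin

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "horizontal_arcmin": self.horizontal,
                    "vertical_arcmin": self.vertical,
                    "n_cycles_used": self.n_cycles_used,
                    "n_rejected": self.n_rejected,
                    "per_cycle": self.per_cycle.tolist(),
                },
                indent=1,
            )
        )


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> tuple[float, float, float]:
    """Sub-pixel (dx, dy) shift of ``img`` relative to ``ref`` and confidence.

    Peak of the FFT cross-correlation with 3-point parabolic interpolation on
    each axis; confidence is the normalized correlation peak in [0, 1].
    """
    a = ref - ref.mean()
    b = img - img.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0, 0.0, 0.0
    corr = np.real(np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))))
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    rows, cols = corr.shape
    confidence = float(corr[peak] / (na * nb))

    def interp(axis: int) -> float:
        i = peak[axis]
        n = corr.shape[axis]
        if axis == 0:
            cm, c0, cp = corr[(i - 1) % n, peak[1]], corr[i, peak[1]], corr[(i + 1) % n, peak[1]]
        else:
            cm, c0, cp = corr[peak[0], (i - 1) % n], corr[peak[0], i], corr[peak[0], (i + 1) % n]
        denom = cm - 2.0 * c0 + cp
        frac = 0.0 if abs(denom) < 1e-15 else 0.5 * (cm - cp) / denom
        val = i + float(np.clip(frac, -0.5, 0.5))
        return val - n if val > n / 2 else val

    dy = interp(0)
    dx = interp(1)
    return dx, dy, confidence


def stabilize(
    video: VideoStack,
    region: Rect,
    ref_index: int = 0,
    min_confidence: float = MIN_PEAK_CORRELATION,
    resample: bool = True,
) -> tuple[MotionTrace, VideoStack | None]:
    """Motion trace of a region and the motion-compensated video.

    Each frame's displacement relative to the reference frame is the FFT
    cross-correlation peak over ``region`` with parabolic sub-pixel
    interpolation.  Frames whose correlation confidence falls below
    ``min_confidence`` (blinks, blanks) are flagged and their displacement
    interpolated from neighboring valid frames; if more than half the
    frames fail, stabilization aborts with diagnostics.

    The returned trace is in arcmin; the stabilized video is each frame
    resampled by the negated trace (bilinear).  ``resample=False`` skips the
    resampling and returns None for the video (when only the trace is
    needed).
    """
    frame0 = video.frame(ref_index)
    rs, cs = region.pixel_slices(frame0)
    ref_patch = video.frames[ref_index, rs, cs]
    n = len(video)
    disp = np.zeros((n, 2))
    valid = np.ones(n, dtype=bool)
    for t in range(n):
        dx, dy, conf = _xcorr_shift(ref_patch, video.frames[t, rs, cs])
        disp[t] = (dx, dy)
        valid[t] = conf >= min_confidence
    if np.count_nonzero(~valid) > n / 2:
        raise RuntimeError(
            f"stabilization failed: {np.count_nonzero(~valid)}/{n} frames below "
            f"confidence {min_confidence} over region {region}"
        )
    if not valid.all():
        idx = np.arange(n)
        for axis in range(2):
            disp[~valid, axis] = np.interp(idx[~valid], idx[valid], disp[valid, axis])

    ppa = video.pixels_per_arcmin
    trace = MotionTrace(disp[:, 0] / ppa, disp[:, 1] / ppa, frame_rate=video.frame_rate)
    if not resample:
        return trace, None
    stabilized = np.empty_like(video.frames)
    for t in range(n):
        stabilized[t] = ndimage.shift(
            video.frames[t], shift=(-disp[t, 1], -disp[t, 0]), order=1, mode="nearest"
        )
    out = VideoStack(
        frames=stabilized,
        field_arcmin=video.field_arcmin,
        frame_rate=video.frame_rate,
        channel=video.channel,
        window=video.window,
        truth=video.truth,
    )
    return trace, out


def _schedule_from_phase(
    n_frames: int, frame_rate: float, alternation_hz: float, first_red_frame: int
) -> np.ndarray:
    """Channel schedule (0 = IR, 1 = red) with a red half-cycle starting at
    ``first_red_frame``."""
    t = np.arange(n_frames) - first_red_frame
    half_cycles = np.floor(t * 2.0 * alternation_hz / frame_rate)
    return (half_cycles % 2 == 0).astype(int)


def _half_cycle_runs(channel: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (channel, start, stop) runs of the alternation schedule."""
    runs = []
    start = 0
    for i in range(1, len(channel) + 1):
        if i == len(channel) or channel[i] != channel[start]:
            runs.append((int(channel[start]), start, i))
            start = i
    return runs


def estimate_tca(
    video: VideoStack,
    ir_region: Rect,
    alternating_region: Rect,
    first_red_frame: int | None = None,
    alternation_hz: float = 2.0,
    guard: int = 1,
    reject_sd: float = 2.0,
) -> TCAResult:
    """Estimate the TCA shift (arcmin) from a calibration video.

    ``first_red_frame`` sets the phase of the wavelength alternation; if
    None, the video's stored channel schedule is used.  Within each
    half-cycle only the second half of the frames (and at least ``guard``
    frames past the transition) contribute, to avoid transition frames.
    Per-cycle shifts are the red-phase minus the preceding IR-phase mean of
    the residual trace; per-axis outliers beyond ``reject_sd`` standard
    deviations of the mean are rejected in a single pass.
    """
    n = len(video)
    if first_red_frame is not None:
        if not 0 <= first_red_frame < n:
            raise ValueError(f"first_red_frame {first_red_frame} outside video [0, {n})")
        channel = _schedule_from_phase(
            n, video.frame_rate, alternation_hz, first_red_frame
        )
    else:
        if video.channel.size != n:
            raise ValueError("video carries no channel schedule; pass first_red_frame")
        channel = video.channel

    ref_ir = int(np.nonzero(channel == 0)[0][0])
    _, stabilized = stabilize(video, ir_region, ref_index=ref_ir)
    residual, _ = stabilize(
        stabilized, alternating_region, ref_index=ref_ir, resample=False
    )
    raw = residual.positions  # (n, 2) arcmin; ~0 in IR phase, ~TCA in red phase

    runs = _half_cycle_runs(channel)
    # a user-supplied phase can misplace half-cycle boundaries by a frame, so
    # trim the trailing frame of each half-cycle in that case
    end_guard = 1 if first_red_frame is not None else 0

    def usable(start: int, stop: int) -> np.ndarray:
        length = stop - start
        lo = start + max(length // 2, guard)
        return np.arange(lo, stop - end_guard)

    cycles = []
    for i in range(1, len(runs)):
        ch, start, stop = runs[i]
        if ch != 1:
            continue
        prev_ch, p_start, p_stop = runs[i - 1]
        if prev_ch != 0:
            continue
        red_idx = usable(start, stop)
        ir_idx = usable(p_start, p_stop)
        if red_idx.size == 0 or ir_idx.size == 0:
            continue
        cycles.append(raw[red_idx].mean(axis=0) - raw[ir_idx].mean(axis=0))
    cycles = np.asarray(cycles)
    if cycles.shape[0] < 3:
        raise RuntimeError(
            f"only {cycles.shape[0]} usable alternation cycles; need >= 3"
        )

    means = []
    rejected = np.zeros(cycles.shape[0], dtype=bool)
    for axis in range(2):
        vals = cycles[:, axis]
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        keep = np.abs(vals - mu) <= reject_sd * sd if sd > 0 else np.ones_like(vals, bool)
        rejected |= ~keep
        means.append(float(np.mean(vals[keep])))
    return TCAResult(
        horizontal=means[0],
        vertical=means[1],
        n_cycles_used=int(cycles.shape[0]),
        n_rejected=int(np.count_nonzero(rejected)),
        per_cycle=cycles,
    )
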