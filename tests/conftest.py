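import numpy as np
import pytest

from foveal_limits import mosaic, synthgen
from foveal_limits.synthgen import MosaicSpec, MotionSpec, Rect


@pytest.fixture(scope="session")
def lattice_mosaic():
    """Perfect triangular lattice, spacing 0.84 arcmin, PRLF-centered."""
    spec = MosaicSpec(
        peak_icd=0.84, icd_slope=0.0, jitter_sd=0.0, loss_fraction=0.0,
        extent=0.15, seed=1,
    )
    return synthgen.generate_mosaic(spec)


@pytest.fixture(scope="session")
def lattice_metrics(lattice_mosaic):
    return mosaic.compute_icd(lattice_mosaic)


@pytest.fixture(scope="session")
def graded_patch_1deg():
    """Jittered graded mosaic patch centered at 1 degree temporal."""
    spec = MosaicSpec(
        peak_icd=0.58, icd_slope=0.35, jitter_sd=0.05, loss_fraction=0.0,
        extent=0.2, seed=3,
    )
    return spec, synthgen.generate_mosaic(spec, center_deg=(1.0, 0.0))


def small_tca_video(
    tca_shift=(2.752, 0.500),
    n_cycles=6,
    seed=0,
    drift_sd=0.15,
    noise_sd=0.03,
    field=(36.0, 36.0),
):
    """Compact calibration video for unit tests (smaller field, fewer cycles)."""
    m = synthgen.generate_mosaic(
        MosaicSpec(peak_icd=0.9, icd_slope=0.0, jitter_sd=0.08, extent=0.35,
                   seed=1000 + seed)
    )
    frame_rate = 30.0
    n_frames = int(n_cycles * frame_rate / 2.0)
    video = synthgen.generate_tca_video(
        m,
        None,
        tca_shift=tca_shift,
        motion=MotionSpec(drift_sd=drift_sd, microsaccade_rate=0.5,
                          microsaccade_amplitude=2.0, n_frames=n_frames,
                          frame_rate=frame_rate, seed=seed),
        window=Rect(-10.0, -14.0, 20.0, 10.0),
        field_arcmin=field,
        noise_sd=noise_sd,
    )
    return video


@pytest.fixture(scope="session")
def tca_video():
    return small_tca_video()


IR_REGION = Rect(-14.0, 0.0, 28.0, 14.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
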