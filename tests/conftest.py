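import numpy as np
import pytest

from canaloflow import analyze_stack, generate, preset
from canaloflow.synth import SectorKinetics, SyntheticSpec


def make_small_spec(seed: int = 0, noise_sd: float = 0.0,
                    n_frames: int = 16, **overrides) -> SyntheticSpec:
    """A fast small-image synthetic eye: 96x96 px, one frame per 30 s."""
    duration = 30.0 * (n_frames - 1)
    scale = duration / 450.0   # reference kinetics defined for 16 frames
    sectors = overrides.pop("sectors", None) or {
        "IN": SectorKinetics(1000.0, 120.0 * scale, 30.0 * scale, 10.0),
        "SN": SectorKinetics(1000.0, 150.0 * scale, 30.0 * scale, 10.0),
        "ST": SectorKinetics(1000.0, 240.0 * scale, 30.0 * scale, 10.0),
        "IT": SectorKinetics(1000.0, 300.0 * scale, 30.0 * scale, 10.0),
    }
    return SyntheticSpec(shape=(96, 96), n_frames=n_frames,
                         frame_interval_s=30.0, center_row=48.0,
                         center_col=48.0, corneal_radius_px=12.0,
                         outer_radius_px=42.0, sectors=sectors,
                         noise_sd=noise_sd, seed=seed, **overrides)


@pytest.fixture(scope="session")
def whole_eye_run():
    """One full-size whole-eye preset analyzed end to end (shared)."""
    spec = preset("whole_eye", seed=1)
    stack, truth = generate(spec)
    result = analyze_stack(stack, spec.geometry())
    return spec, stack, truth, result


@pytest.fixture(scope="session")
def small_run():
    """Small noiseless synthetic eye analyzed end to end (shared)."""
    spec = make_small_spec(seed=3, noise_sd=0.0)
    stack, truth = generate(spec, grid_rows=16, grid_cols=16)
    result = analyze_stack(stack, spec.geometry(), grid_rows=16, grid_cols=16)
    return spec, stack, truth, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
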