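import numpy as np
import pytest

from leafmsi.calibrate import CalibrationBundle
from leafmsi.pipeline import PipelineConfig, process_stack
from leafmsi.segment import SegmentedLeaf, rotate_to_horizontal
from leafmsi.simulate import SceneParams, generate_scene
from leafmsi.stack import CalibratedStack, MultispectralStack, default_manifest


def make_flat_bundle(
    shape=(8, 8), mm_per_px=0.1, white=100.0, dark=0.0, coeffs=(0, 0, 0, 0, 0), K=None
) -> CalibrationBundle:
    """A spatially uniform calibration bundle for geometry-only tests."""
    h, w = shape
    if K is None:
        K = np.array([[800.0, 0, (w - 1) / 2], [0, 800.0, (h - 1) / 2], [0, 0, 1.0]])
    wref = MultispectralStack(np.full((4, h, w), white), default_manifest())
    dref = MultispectralStack(np.full((4, h, w), dark), default_manifest())
    return CalibrationBundle(wref, dref, K, np.asarray(coeffs, float), mm_per_px)


def scene_bundle(white, dark, params: SceneParams) -> CalibrationBundle:
    """Bundle using a scene's own reference stacks (zero distortion)."""
    h, w = params.image_size
    K = np.array([[1000.0, 0, (w - 1) / 2], [0, 1000.0, (h - 1) / 2], [0, 0, 1.0]])
    return CalibrationBundle(white, dark, K, np.zeros(5), params.mm_per_px)


def rotate_truth_mask(mask: np.ndarray, theta_deg: float) -> np.ndarray:
    """Apply the pipeline's own rotation to a ground-truth mask so masks can
    be compared in the rotated frame."""
    stack = CalibratedStack(np.zeros((4,) + mask.shape), default_manifest())
    return rotate_to_horizontal(SegmentedLeaf(stack, mask), theta_deg).mask


@pytest.fixture(scope="session")
def noiseless_scene():
    """One deterministic noiseless scene at 25° with its ground truth."""
    params = SceneParams(seed=11, noise_sd=0.0, orientation_deg=20.0)
    raw, white, dark, gt = generate_scene(params)
    return params, raw, white, dark, gt


@pytest.fixture(scope="session")
def processed_noiseless(noiseless_scene):
    """Full pipeline result on the noiseless scene."""
    params, raw, white, dark, gt = noiseless_scene
    bundle = scene_bundle(white, dark, params)
    result = process_stack(raw, bundle, PipelineConfig())
    return params, gt, bundle, result
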