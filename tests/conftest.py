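"""Shared fixtures: small rendered scenes with known ground truth.

All scenes use a 50 um baseline radius, a 3.2 Hz fundamental and the default
acquisition model (120 Hz, 2.4 um/pixel, vessel/background gray 60/180) on
128 x 128 frames, which keeps a full render + analysis round under two seconds.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from camwall import (
    AcquisitionSpec,
    MotionLaw,
    SyntheticScene,
    VesselGeometry,
    compute_map_set,
    render_video,
)

RADIUS_UM = 50.0
FUND_HZ = 3.2
ACQ_128 = AcquisitionSpec(frame_shape=(128, 128))
PADDED_BIN_HZ = ACQ_128.frame_rate_hz / (4 * ACQ_128.n_frames)  # pad_factor 4


def vertical_centerline(acq: AcquisitionSpec, radius_um: float = RADIUS_UM):
    """A vertical centerline overshooting the frame so no tube end-cap shows."""
    h_um = (acq.frame_shape[0] - 1) * acq.pixel_pitch_um
    w_um = (acq.frame_shape[1] - 1) * acq.pixel_pitch_um
    return [[-2 * radius_um, w_um / 2], [h_um + 2 * radius_um, w_um / 2]]


def straight_scene(motion: MotionLaw, seed: int, acq: AcquisitionSpec = ACQ_128):
    return SyntheticScene(
        geometry=VesselGeometry(vertical_centerline(acq), RADIUS_UM, "straight"),
        motion=motion,
        acquisition=acq,
        rng_seed=seed,
    )


def brute_force_boundary_sets(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Boundary pixels of every 8-connected object, from the definition.

    A boundary pixel of an object is an object pixel that is not interior to
    the object's filled silhouette (erosion with the full 3 x 3 structure,
    image border counting as outside).  Sets are returned in scan order of the
    objects' first pixels, matching connected-component labeling.
    """
    eight = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask, structure=eight)
    out = []
    for lab in range(1, n + 1):
        comp = labels == lab
        filled = ndimage.binary_fill_holes(comp)
        interior = ndimage.binary_erosion(np.pad(filled, 1), eight)[1:-1, 1:-1]
        boundary = comp & ~interior
        out.append({(int(r), int(c)) for r, c in zip(*np.nonzero(boundary))})
    return out


# --- dilating vessel: fundamental + half-amplitude second harmonic ----------


@pytest.fixture(scope="session")
def dilation_scene():
    return straight_scene(MotionLaw(FUND_HZ, harmonic_amplitudes=(0.06, 0.03)), seed=1)


@pytest.fixture(scope="session")
def dilation_stack(dilation_scene):
    return render_video(dilation_scene)


@pytest.fixture(scope="session")
def dilation_maps(dilation_stack):
    return compute_map_set(dilation_stack)


# --- rigid lateral translation ----------------------------------------------


@pytest.fixture(scope="session")
def translation_scene():
    return straight_scene(
        MotionLaw(FUND_HZ, translation_amplitude_um=6.0, translation_direction_deg=0.0),
        seed=2,
    )


@pytest.fixture(scope="session")
def translation_stack(translation_scene):
    return render_video(translation_scene)


@pytest.fixture(scope="session")
def translation_maps(translation_stack):
    return compute_map_set(translation_stack)


# --- along-vessel phase gradient --------------------------------------------


@pytest.fixture(scope="session")
def gradient_scene():
    return straight_scene(
        MotionLaw(FUND_HZ, harmonic_amplitudes=(0.06,), harmonic_phases_deg=((0.0, 120.0),)),
        seed=3,
    )


@pytest.fixture(scope="session")
def gradient_stack(gradient_scene):
    return render_video(gradient_scene)


@pytest.fixture(scope="session")
def gradient_maps(gradient_stack):
    return compute_map_set(gradient_stack)


# --- asymmetric waveform (fast systolic upstroke) ----------------------------


@pytest.fixture(scope="session")
def asymmetric_scene():
    acq = AcquisitionSpec(frame_shape=(64, 64), duration_s=2.0)
    return SyntheticScene(
        geometry=VesselGeometry(vertical_centerline(acq), RADIUS_UM, "straight"),
        motion=MotionLaw(FUND_HZ, harmonic_amplitudes=(0.1,), asymmetry=0.5),
        acquisition=acq,
        rng_seed=5,
    )


@pytest.fixture(scope="session")
def asymmetric_stack(asymmetric_scene):
    return render_video(asymmetric_scene)


# --- second harmonic gated on at mid-record ----------------------------------


@pytest.fixture(scope="session")
def gated_scene():
    return straight_scene(
        MotionLaw(
            FUND_HZ,
            harmonic_amplitudes=(0.06, 0.03),
            harmonic_onsets_s=(None, ACQ_128.duration_s / 2),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def gated_stack(gated_scene):
    return render_video(gated_scene)
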