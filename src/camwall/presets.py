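"""Bundled synthetic scenes mirroring the motion regimes seen in CAM arteries.

Each preset is a fully specified :class:`SyntheticScene`: lateral translation of
a straight artery, weak and strong radial dilation, a curved vessel, a
bifurcation with an along-vessel phase gradient, and a dilation whose second
harmonic switches on halfway through the recording.  Defaults: 256 x 256 frames
at 2.4 um/pixel, 120 Hz for 3 s (360 frames), fundamental 3.2 Hz, baseline
radius 50 um, vessel/background gray 60/180, PSF sigma 8 um, noise sigma 1.
"""

from __future__ import annotations

from .synthetic_video import (
    AcquisitionSpec,
    MotionLaw,
    SyntheticScene,
    VesselGeometry,
)

__all__ = ["PRESETS", "get_preset", "preset_names"]

_ACQ = AcquisitionSpec()  # the package defaults; see AcquisitionSpec

_FUND_HZ = 3.2
_RADIUS_UM = 50.0


def _extent_um(acq: AcquisitionSpec) -> tuple[float, float]:
    h, w = acq.frame_shape
    return (h - 1) * acq.pixel_pitch_um, (w - 1) * acq.pixel_pitch_um


def _vertical_centerline(acq: AcquisitionSpec):
    h_um, w_um = _extent_um(acq)
    # extend past the frame so no tube end-cap is visible
    return [[-2 * _RADIUS_UM, w_um / 2], [h_um + 2 * _RADIUS_UM, w_um / 2]]


def straight_translation(seed: int = 0, acq: AcquisitionSpec = _ACQ) -> SyntheticScene:
    """Rigid lateral translation, the dominant motion of case-1-type arteries."""
    return SyntheticScene(
        geometry=VesselGeometry(_vertical_centerline(acq), _RADIUS_UM, "straight"),
        motion=MotionLaw(
            fundamental_hz=_FUND_HZ,
            translation_amplitude_um=6.0,
            translation_direction_deg=0.0,
        ),
        acquisition=acq,
        rng_seed=seed,
    )


def straight_dilation(seed: int = 0, acq: AcquisitionSpec = _ACQ) -> SyntheticScene:
    """Radial dilation with a second harmonic at half the fundamental amplitude."""
    return SyntheticScene(
        geometry=VesselGeometry(_vertical_centerline(acq), _RADIUS_UM, "straight"),
        motion=MotionLaw(
            fundamental_hz=_FUND_HZ, harmonic_amplitudes=(0.06, 0.03), asymmetry=0.5
        ),
        acquisition=acq,
        rng_seed=seed,
    )


def straight_dilation_weak(seed: int = 0, acq: AcquisitionSpec = _ACQ) -> SyntheticScene:
    """Barely observable wall motion (case-2-type artery)."""
    return SyntheticScene(
        geometry=VesselGeometry(_vertical_centerline(acq), _RADIUS_UM, "straight"),
        motion=MotionLaw(fundamental_hz=_FUND_HZ, harmonic_amplitudes=(0.02,)),
        acquisition=acq,
        rng_seed=seed,
    )


def curved(seed: int = 0, acq: AcquisitionSpec = _ACQ) -> SyntheticScene:
    """A curved artery: dilation plus a translation component."""
    h_um, w_um = _extent_um(acq)
    centerline = [
        [-0.2 * h_um, 0.25 * w_um],
        [0.25 * h_um, 0.35 * w_um],
        [0.5 * h_um, 0.55 * w_um],
        [0.75 * h_um, 0.6 * w_um],
        [1.2 * h_um, 0.5 * w_um],
    ]
    return SyntheticScene(
        geometry=VesselGeometry(centerline, _RADIUS_UM, "curved"),
        motion=MotionLaw(
            fundamental_hz=_FUND_HZ,
            harmonic_amplitudes=(0.05, 0.02),
            translation_amplitude_um=3.0,
            translation_direction_deg=30.0,
        ),
        acquisition=acq,
        rng_seed=seed,
    )


def bifurcated_phase_gradient(seed: int = 0, acq: AcquisitionSpec = _ACQ) -> SyntheticScene:
    """Parent splitting into two daughters, fundamental phase shifting along the vessel."""
    h_um, w_um = _extent_um(acq)
    parent = [[0.5 * h_um, -0.2 * w_um], [0.5 * h_um, 0.45 * w_um]]
    branch = parent[-1]
    upper = [branch, [0.2 * h_um, 1.2 * w_um]]
    lower = [branch, [0.8 * h_um, 1.2 * w_um]]
    return SyntheticScene(
        geometry=VesselGeometry(
            parent,
            _RADIUS_UM,
            "bifurcated",
            daughter_centerlines=(upper, lower),
            daughter_radii=(0.7 * _RADIUS_UM, 0.7 * _RADIUS_UM),
        ),
        motion=MotionLaw(
            fundamental_hz=_FUND_HZ,
            harmonic_amplitudes=(0.06,),
            harmonic_phases_deg=((0.0, 120.0),),  # phase shift toward the daughters
        ),
        acquisition=acq,
        rng_seed=seed,
    )


def gated_second_harmonic(seed: int = 0, acq: AcquisitionSpec = _ACQ) -> SyntheticScene:
    """Second harmonic switching on at mid-record (the scalogram localization case)."""
    return SyntheticScene(
        geometry=VesselGeometry(_vertical_centerline(acq), _RADIUS_UM, "straight"),
        motion=MotionLaw(
            fundamental_hz=_FUND_HZ,
            harmonic_amplitudes=(0.06, 0.03),
            harmonic_onsets_s=(None, acq.duration_s / 2),
        ),
        acquisition=acq,
        rng_seed=seed,
    )


PRESETS = {
    "straight-translation": straight_translation,
    "straight-dilation": straight_dilation,
    "straight-dilation-weak": straight_dilation_weak,
    "curved": curved,
    "bifurcated-phase-gradient": bifurcated_phase_gradient,
    "gated-second-harmonic": gated_second_harmonic,
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str, seed: int = 0, acquisition: AcquisitionSpec | None = None):
    """Instantiate a bundled scene by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {preset_names()}") from None
    if acquisition is None:
        return factory(seed)
    return factory(seed, acquisition)
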