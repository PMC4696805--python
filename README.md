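# camwall

Pulsatile wall-motion analysis for microscope videos of small arteries, such as
the vessels of the chick chorioallantoic membrane (CAM) imaged in ex ovo
culture. Given a high-speed grayscale video stack, the package

- **detects vessel boundaries** frame by frame (thresholding + Moore-Neighbor
  contour tracing with Jacob's stopping criterion) and superimposes the
  peak-systolic and late-diastolic boundaries to visualize wall displacement
  over a cardiac cycle;
- **maps the pulsation spectrally**: each pixel's brightness series is
  detrended and Fourier transformed, producing co-registered maps of RMS
  amplitude, fundamental and second-harmonic magnitude, their percentage
  ratio, and the phase angle of the fundamental — the quantity whose
  histogram separates radial dilation (one phase mode) from rigid lateral
  translation (two modes ~180° apart);
- **resolves harmonics in time** with a real-Morlet continuous wavelet
  transform, so a harmonic that strengthens partway through a recording shows
  up at the right time in the scalogram;
- **simulates pulsating vessels** with fully known ground truth (geometry,
  per-harmonic amplitude/phase, rigid translation, waveform asymmetry, optics
  and sensor noise), which is how the whole pipeline is tested without
  microscope data.

All analysis assumes dark vessels on a bright background, 8-bit grayscale
frames, and a known frame rate (the bundled defaults follow a typical
configuration: 120 Hz for 3 s, 2.4 µm/pixel).

## Worked example

Render a dilating vessel (50 µm baseline radius, 3.2 Hz fundamental with a
half-amplitude second harmonic, asymmetric waveform) and run the full
analysis:

```python
import numpy as np
from camwall import (
    get_preset, render_video, compute_map_set, detect_cardiac_phases,
    suggest_threshold, systole_diastole_overlay, cwt_scalogram,
    frequency_to_scale,
)
from camwall.measure import wall_displacement_amplitude, phase_modes

scene = get_preset("straight-dilation", seed=1)
stack = render_video(scene)
print(f"rendered {stack.n_frames} frames of {stack.frame_shape[0]}x{stack.frame_shape[1]} px")

maps = compute_map_set(stack)
print(f"fundamental frequency: {maps.fundamental_hz:.3f} Hz")
print(f"wall pixels in the 6 dB mask: {maps.mask.sum()}")
print(f"median fundamental/second-harmonic ratio: {np.nanmedian(maps.ratio_map[maps.mask]):.0f}%")
print(f"phase modes: {phase_modes(maps)}")

r, c = np.unravel_index(np.argmax(maps.rms_map), maps.rms_map.shape)
phases = detect_cardiac_phases(stack.pixel_series(int(r), int(c)),
                               fundamental_hz=maps.fundamental_hz)
threshold = suggest_threshold(stack.frames[phases.late_diastolic_frame])
sys_traces, dia_traces, overlay = systole_diastole_overlay(stack, phases, threshold)
amp = wall_displacement_amplitude(sys_traces, dia_traces, stack.frame_shape,
                                  scene.acquisition.pixel_pitch_um)
print(f"peak systole at frame {phases.peak_systolic_frame}, "
      f"late diastole at frame {phases.late_diastolic_frame}")
print(f"recovered wall displacement amplitude: {amp:.2f} um "
      f"(imposed: {50.0 * 0.06:.2f} um)")

scalo = cwt_scalogram(stack.pixel_series(int(r), int(c)))
print(f"scale for 3.2 Hz at 120 Hz: {frequency_to_scale(3.2, 120.0):.1f}")
```

Output:

```
rendered 360 frames of 256x256 px
fundamental frequency: 3.167 Hz
wall pixels in the 6 dB mask: 4096
median fundamental/second-harmonic ratio: 335%
phase modes: [(177.5, 2865), (-92.5, 0)]
peak systole at frame 338, late diastole at frame 28
recovered wall displacement amplitude: 2.73 um (imposed: 3.00 um)
scale for 3.2 Hz at 120 Hz: 30.5
```

Reading the numbers: the estimated 3.167 Hz sits within one padded FFT bin
(1/12 Hz) of the imposed 3.2 Hz; the phase histogram has a single dominant
mode (the second entry is an empty bin), the signature of radial dilation;
and the recovered wall displacement of 2.73 µm matches the imposed
`baseline_radius × a₁ = 50 µm × 0.06 = 3 µm` to well within one pixel
(2.4 µm). The ratio exceeds the naive `100 × a₁/a₂ = 200 %` because this
preset also skews the waveform (fast systolic upstroke), which shifts
harmonic content; a symmetric-waveform scene recovers ≈ 200 %.

## Command-line pipeline

```bash
# render a bundled preset (or pass --config scene.yaml)
camwall simulate --preset straight-dilation --seed 1 --out runs/sim

# full analysis: maps + overlay + phase histogram + per-pixel scalograms
camwall analyze --in runs/sim/stack.tif --pixels "128,90;128,166" --out runs/analysis

# boundary tracing on a single frame
camwall trace --in runs/sim/stack.tif --frame 0 --out runs/trace.csv
```

`simulate` writes `stack.tif` (+ a JSON frame-rate sidecar), `ground_truth.csv`
and the fully resolved `scene.yaml`; `analyze` writes each map as PNG + CSV,
`phase_histogram.csv`, the systole/diastole `overlay.png`, one scalogram per
requested pixel, and a `run.log`. Presets:
`straight-translation`, `straight-dilation`, `straight-dilation-weak`,
`curved`, `bifurcated-phase-gradient`, `gated-second-harmonic`.

## Documentation and tests

- `docs/methods.md` — the numerical methods, conventions and default
  parameters, with rationale.
- `tests/` — unit and property tests per module plus end-to-end acceptance
  tests (`tests/test_acceptance.py`) that recover imposed motion parameters
  from rendered videos at stated tolerances. The whole suite runs in well
  under a minute.
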