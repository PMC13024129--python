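"""Simulate an FMCW radar cube of a breathing chest and recover the pulse.

Builds 20 s of chest motion (cardiac 0.2 mm at 1.2 Hz on 1.5 mm
respiratory drift), simulates the 77 GHz 4-channel echo with stationary
clutter and DC offsets, then runs the full DSP chain: clutter suppression,
range FFT, beamforming with range/angle selection, DACM phase demodulation
and heart-band extraction.  Prints the selected range bin / steering angle
and the correlation between the recovered pulse wave and the (band-passed)
true cardiac displacement — near 1.0 means the chain inverted the
displacement-to-phase map 4*pi*x/lambda faithfully.
"""

import numpy as np

from radarbp.dsp import PhaseSignal, extract_rpw, process_cube
from radarbp.synth import RadarConfig, make_chest_motion, simulate_radar_cube

cfg = RadarConfig(n_chirps=4000)         # 20 s at the 200 Hz frame rate
motion = make_chest_motion(duration=20.0, heart_rate=1.2)
cube = simulate_radar_cube(motion, cfg, clutter_amp=0.8,
                           dc_offset=0.2 + 0.1j, rng_seed=5,
                           target_angle=np.deg2rad(10.0), noise_sd=0.02)
print(f"cube: {cube.shape[0]} chirps x {cube.shape[1]} fast-time samples "
      f"x {cube.shape[2]} channels")

rpw, range_bin, theta = process_cube(cube, cfg)
true_range = motion.static_range
print(f"selected range bin {range_bin} "
      f"(= {range_bin * cfg.range_resolution:.3f} m, truth {true_range} m), "
      f"steering angle {np.rad2deg(theta):.1f} deg (truth 10.0 deg)")

reference = extract_rpw(PhaseSignal(phi=4 * np.pi * motion.cardiac / cfg.wavelength,
                                    fs=cfg.slow_rate))
n = min(len(rpw), len(reference))
r = np.corrcoef(rpw[:n], reference[:n])[0, 1]
print(f"Pearson r between recovered and true cardiac pulse: {r:.4f}")
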