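"""Recover an injected tremor from a simulated 10-s controller recording.

Simulates a postural recording with a 4.7 Hz, 1 cm tremor plus sensor
noise, runs the trim/resample/detrend + Welch pipeline, and prints the
dominant frequency and peak power. The frequency should land within one
0.35 Hz resolution bin of the injected value; the peak power scales with
the square of the tremor amplitude.
"""

import vrmotor as vm

trace = vm.simulate_tremor_trace(
    amp=0.01, freq=4.7, duration=10, rate=90, noise_sd=5e-4, seed=5
)
feats = vm.trace_features(trace)

print("injected tremor: 4.7 Hz, amplitude 0.010 m")
print(f"dominant frequency: {feats.dominant_frequency:.3f} Hz")
print(f"peak power:         {feats.peak_power:.3e} m^2/Hz")
print("-> the spectral peak identifies the tremor despite noise and drift;")
print("   doubling the amplitude would roughly quadruple the peak power.")
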