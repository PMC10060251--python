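"""Phase-lag index and phase crossings on a single simulated channel pair.

Builds two theta-band channels sharing one oscillator at a 60 degree lag
whose sign flips at 1 Hz, then measures PLI and the crossing train.
"""

import numpy as np

from tbpc.connectivity import crossings, phase_difference, pli, sign_series
from tbpc.preprocessing import DEFAULT_BANDS
from tbpc.simulate import CouplingEdge, CouplingSpec, gen_recording

fs = 250.0
theta = (DEFAULT_BANDS[1],)

for switch_rate in (0.0, 1.0):
    spec = CouplingSpec(
        edges=[CouplingEdge("E01", "E02", "theta", np.pi / 3, 1.0, switch_rate)],
        noise_sd=0.0, seed=7)
    rec, _ = gen_recording(spec, n_channels=2, fs=fs, duration=30.0, bands=theta)
    d = phase_difference(rec.channel("E01"), rec.channel("E02"), fs)
    train = crossings(sign_series(d), fs)
    print(f"switch rate {switch_rate:3.1f} Hz:  PLI = {pli(d):.3f}   "
          f"crossings/s = {train.n_crossings / train.duration:.2f}")

print()
print("With a constant lag the phase difference never changes sign: PLI is 1")
print("and there are almost no crossings.  Once the lag sign flips at 1 Hz the")
print("positive and negative episodes balance out - PLI collapses toward 0 and")
print("is blind to the (still perfectly coupled) pair, while the crossing")
print("train records every switching event.  That is the gap TBPC fills.")
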