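"""Design the preprocessing cascade and verify its frequency response.

Prints the realized -3 dB points of the low- and high-pass sections, the
notch minimum, and the composite response at a few landmark frequencies —
the numbers that define the ~70-110 Hz high-gamma passband.
"""

import numpy as np
from scipy import signal as sps

from ecogmap import CascadeSpec, design_cascade
from ecogmap.dsp import cascade_sos

spec = CascadeSpec()
sections = design_cascade(spec)


def response_db(sos, n_fft=2**15):
    x = np.zeros(n_fft)
    x[0] = 1.0
    h = sps.sosfilt(sos, x)
    f = np.fft.rfftfreq(n_fft, d=1 / spec.fs_native_hz)
    return f, 20 * np.log10(np.maximum(np.abs(np.fft.rfft(h)), 1e-300))


def crossing(f, db, level, rising):
    flips = np.flatnonzero((db > level)[:-1] != (db > level)[1:])
    i = flips[0] if rising else flips[-1]
    return f[i] + (level - db[i]) * (f[i + 1] - f[i]) / (db[i + 1] - db[i])


level = 20 * np.log10(1 / np.sqrt(2))
f, db = response_db(sections["lowpass"])
print(f"low-pass  (order {spec.lowpass_order}): -3 dB at "
      f"{crossing(f, db, level, rising=False):7.2f} Hz (designed {spec.lowpass_hz})")
f, db = response_db(sections["highpass"])
print(f"high-pass (order {spec.highpass_order}): -3 dB at "
      f"{crossing(f, db, level, rising=True):7.2f} Hz (designed {spec.highpass_hz})")
f, db = response_db(sections["notch"], n_fft=10000)
sel = (f >= 40) & (f <= 80)
print(f"notch     (order {spec.notch_order}): minimum at {f[sel][np.argmin(db[sel])]:.1f} Hz, "
      f"depth {db[sel].min():.0f} dB")

f, db = response_db(cascade_sos(spec))
for freq in (30, 60, 90, 200):
    print(f"composite response at {freq:3d} Hz: {db[np.argmin(np.abs(f - freq))]:7.1f} dB")
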