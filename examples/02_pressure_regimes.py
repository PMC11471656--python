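"""Pressure regimes and the pulsatile inlet waveform.

Prints the three simulated blood-pressure regimes, the derived outlet
pressure (10 mmHg below diastolic), and verifies that the periodic inlet
waveform hits the stated systolic/diastolic extrema exactly.  Instant.
"""

import numpy as np

from dissectflow import build_waveform, heart_rate_bpm, make_pressure_regime
from dissectflow.conditions import REGIMES, pa_to_mmhg

print(f"cardiac cycle 0.86 s  ->  {heart_rate_bpm(0.86)} bpm\n")

for name in REGIMES:
    r = make_pressure_regime(name)
    w = build_waveform(r, period=0.86)
    t = np.linspace(0.0, w.period, 20001)
    p = w(t)
    print(f"{name:<13s} {r.systolic:.0f}/{r.diastolic:.0f} mmHg, "
          f"outlet {r.outlet_pressure:.0f} mmHg | waveform peak "
          f"{pa_to_mmhg(p.max()):.2f}, trough {pa_to_mmhg(p.min()):.2f} mmHg, "
          f"mean {pa_to_mmhg(w.mean()):.1f} mmHg")
# The waveform is a quarter-sine systolic upstroke (35% of the cycle) and an
# exponential diastolic decay; peak and trough match the regime exactly.
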