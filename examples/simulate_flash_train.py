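"""Simulate a flash oxygen train with the extended Joliot–Kok model.

Builds the efficient-system parameter set (miss 0.100, double-hit 0.050,
hit 0.820, backward 0.020, inactivation 0.010) starting from the
dark-adapted distribution (75% S1, 25% S0) and prints the per-flash
oxygen yields.  The maximum on flash 3 is the classic signature of a
dark-adapted sample dominated by S1 centers.
"""

import numpy as np

from kokwave import DARK_ADAPTED_INIT, EFFICIENT_SYSTEM_PARAMS, simulate_yields

seq = simulate_yields(EFFICIENT_SYSTEM_PARAMS, DARK_ADAPTED_INIT, 20)

print("flash  yield")
for n, y in zip(seq.flashes, seq.yields):
    bar = "#" * int(60 * y / seq.yields.max())
    print(f"{n:5d}  {y:.4f}  {bar}")

print(f"\nmaximum yield on flash {np.argmax(seq.yields) + 1} "
      "(period-four oscillation, damping toward steady state)")
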