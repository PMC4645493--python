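"""Measure each model's limit-cycle frequency as 2*pi over the period.

The trajectory is integrated with a fine fixed step, the transient discarded,
and the period taken from the mean interval between successive interpolated
maxima of the protein readout.  Note the cycle frequency differs from the
linearized rotation rate at the steady state (the spiral tightens as the
orbit grows out to the cycle).
"""

import numpy as np

from eftdrk import limit_cycle_frequency, per_circadian_system, two_gene_system

jobs = [
    (two_gene_system(), np.array([0.6, 0.8, 0.4, 0.6]), 200.0, 200.0, 0.005, 2),
    (per_circadian_system(), np.array([0.1, 0.25, 0.25, 0.25, 0.25]), 300.0, 300.0, 0.01, 4),
]
for system, y0, burn_in, window, h, comp in jobs:
    est = limit_cycle_frequency(system, y0, burn_in, window, h, comp)
    print(f"{system.name}: omega = {est.omega:.6f} rad/time "
          f"(period {est.period:.4f}, {est.n_peaks} peaks, "
          f"interval std {est.interval_std:.1e}, reliable={est.reliable})")
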