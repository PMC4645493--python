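"""Locate the positive steady states of both benchmark models and diagnose
their oscillatory character from the Jacobian eigenvalues.

An eigenvalue pair with positive real part and nonzero imaginary part means
the steady state is an unstable spiral: nearby trajectories wind outward
onto a limit cycle, which is what makes these models oscillators.
"""

import numpy as np

from eftdrk import find_steady_state, per_circadian_system, two_gene_system

for system, guess in [
    (two_gene_system(), np.full(4, 0.5)),
    (per_circadian_system(), np.ones(5)),
]:
    report = find_steady_state(system, guess)
    print(f"\n{system.name}: steady state found in {report.n_iterations} Newton steps"
          f" (residual {report.residual_norm:.1e})")
    for name, value in zip(system.state_names, report.y_star):
        print(f"  {name:>3} = {value:.6f}")
    print("  eigenvalues of the Jacobian there:")
    for ev in report.eigenvalues:
        print(f"    {ev.real:+.6f} {ev.imag:+.6f}i")
    print(f"  oscillatory: {report.oscillatory} "
          f"(linearized rotation rate {report.linear_frequency:.6f} rad/time)")
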