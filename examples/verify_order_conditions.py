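"""Certify algebraic order six and the exponential-fitting property.

The ten order conditions couple the tableau with the nu-dependent update
weights; they are checked coefficientwise on the exact rational Taylor
series, so any transcription fault in the tabulated coefficients would be
caught.  The fitting residual then shows the one-step defect operator
annihilating method a's reference set {exp(+-iwt), t exp(+-iwt)} at machine
precision, while a function outside the set leaves a visible residual.
"""

from eftdrk import (
    REFERENCE_SETS,
    check_order_conditions,
    coefficient_series,
    fitting_residual,
    limit_tableau,
)

tableau = limit_tableau()
for method in ("a", "b", "c"):
    results = check_order_conditions(coefficient_series(method), tableau)
    status = "all pass" if all(r.passed for r in results) else "FAILED"
    print(f"method {method}: {len(results)} order conditions -> {status}")

print("\nfitting residuals of method a at nu = 0.5 (t = 0.9, h = 0.5):")
for ref in REFERENCE_SETS["a"] + ("exp_2iwt",):
    r = abs(fitting_residual("a", 0.5, ref, t=0.9, h=0.5))
    member = "in set" if ref in REFERENCE_SETS["a"] else "NOT in set"
    print(f"  |L[{ref}]| = {r:.2e}   ({member})")
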