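"""Predict Phi_e,C (and carbon fixation) with packaged regional algorithms.

Loads the published registry, evaluates the global and a regional model on
an environment record, and converts an ETR into a carbon fixation rate.
"""

import warnings

from phiec import etr_to_carbon, load_published_algorithms, predict_phi

registry = load_published_algorithms()
print(f"{len(registry)} published algorithms; e.g.:")
for rid in ("global", "bedford_basin", "gof_cluster_b"):
    alg = registry[rid]
    print(f"  {rid:18s} Phi_e,C = {alg.equation_string()}   (R^2={alg.r_squared})")

env = {"temperature": 10.0, "NO3": 1.0, "PO4": 0.1}
pred = predict_phi(registry["global"], env)
print(f"\nglobal model at T=10, NO3=1, PO4=0.1: Phi_e,C = {pred.value:.3f}")

etr = 0.010  # mol e- (mg chl a)^-1 h^-1
print(f"ETR {etr} -> carbon fixation {etr_to_carbon(etr, pred.value):.5f} "
      f"mol C (mg chl a)^-1 h^-1")

# The positivity guard: a linear model extrapolated to warm water can cross
# zero, which is physically meaningless and therefore flagged.
with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    bad = predict_phi(registry["bedford_basin"], {"temperature": 9.0})
print(f"\nBedford model at T=9: {bad.value:.3f} -> valid={bad.valid} "
      f"({caught[-1].message})")
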