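"""Derive the equilibrium rate constraints of the airway models.

Balancing every compartment at equilibrium ties the process rates
together: with 11 processes in 3 compartments only 8 rates are free, and
each dependent rate is a fixed linear combination of the free ones.
"""

from lineagecalc import constraint_system, solve_rates
from lineagecalc.airway import (FULL_DEPENDENT, REDUCED_DEPENDENT,
                                airway_full_model, airway_reduced_model)

full = airway_full_model()
cs = constraint_system(full, dependent=list(FULL_DEPENDENT))
print(f"full model: rank {cs.rank} -> {cs.n_free} free rates "
      f"({', '.join(cs.free_names)})")
for dep in cs.to_dict()["dependent"]:
    terms = " + ".join(f"{c:g}*{n}" for n, c in dep["coefficients"].items())
    print(f"  {dep['name']} = {terms}")

reduced = airway_reduced_model()
cs_r = constraint_system(reduced, dependent=list(REDUCED_DEPENDENT))
print(f"\nreduced model: rank {cs_r.rank}, free rates {cs_r.free_names}")
sol = solve_rates(reduced, {"Q4": 0.002, "Q5": 0.1, "Q7": 0.9, "Q8": 0.006},
                  dependent=list(REDUCED_DEPENDENT))
print(f"example solve (Q4=0.002, Q5=0.1, Q7=0.9, Q8=0.006): "
      f"{ {k: round(v, 6) for k, v in sol.as_mapping().items()} }")
print(f"feasible: {sol.feasible}")
print("-> Q6 (de-differentiation) is forced to zero at homeostasis: it "
      "only activates when stem cells are lost.")

bad = solve_rates(reduced, {"Q4": 0.005, "Q5": 0.5, "Q7": 0.3, "Q8": 0.01},
                  dependent=list(REDUCED_DEPENDENT))
print(f"\ninfeasible assignment gives Q9 = {bad.as_mapping()['Q9']:.3f} < 0 "
      f"-> feasible={bad.feasible} (flagged, not raised)")
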