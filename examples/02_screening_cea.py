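"""Population screening vs no screening, per infant.

Nests the treatment cohorts in the per-infant decision tree: every infant
pays the screening test; the rare true positives (birth incidence 2/100,000,
sensitivity 99.5%) are confirmed and treated early; false positives
(0.03% of healthy infants) pay the confirmatory work-up; without screening
only the 20% with a family history are caught early. Prints per-infant
expected costs, SCID-attributable QALYs, and the incremental
cost-effectiveness ratio (ICER) in $/QALY.
"""

from scidcea import ParameterSet, default_life_table, evaluate_screening

params = ParameterSet()
life_table = default_life_table()

for horizon in (5, 60):
    screen, no_screen, cea = evaluate_screening(params, life_table, horizon)
    print(f"\n--- {horizon}-year horizon, per infant screened ---")
    for s in (no_screen, screen):
        print(f"  {s.label:10s} cost ${s.cost:6.2f}   QALY {s.qaly:.6f}")
    scaled = cea.per_100k()
    print(f"  screening adds ${cea.delta_cost:.2f} and {cea.delta_qaly:.6f} QALYs"
          f" per infant (${scaled['delta_cost_per_100k']/1e6:.2f}M and "
          f"{scaled['delta_qaly_per_100k']:.1f} QALYs per 100,000 births)")
    print(f"  ICER: ${cea.icer:,.0f} per QALY gained")
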