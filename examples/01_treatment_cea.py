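"""Compare early vs late HSCT for one SCID patient.

Builds both disease-course cohorts from the published expected parameter
values, runs them over 5- and 60-year horizons at 3% annual discounting,
and prints total discounted costs and QALYs. Early transplantation is
*dominant*: it both saves money (it avoids the expensive late transplant
and pre-treatment infection care) and gains quality-adjusted life-years
(higher survival and a healthier post-transplant mix).
"""

from scidcea import ParameterSet, default_life_table, treatment_cea

params = ParameterSet()
life_table = default_life_table()

for horizon in (5, 60):
    early, late, cea = treatment_cea(params, life_table, horizon)
    print(f"\n--- {horizon}-year horizon, per SCID patient (discounted 3%/yr) ---")
    for r in (late, early):
        print(f"  {r.strategy:5s} HSCT: cost ${r.total_cost:>10,.0f}   "
              f"QALYs {r.total_qaly:7.4f}")
    print(f"  increment (early - late): ${cea.delta_cost:,.0f}, "
          f"{cea.delta_qaly:+.4f} QALYs -> {cea.dominance}")
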