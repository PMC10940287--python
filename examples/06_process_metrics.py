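"""Process accounting for the all-in intensification campaign.

Recomputes the specific catalyst productivity (mmol·g⁻¹·h⁻¹) for every
campaign scenario from its loadings, plus titre and crude-yield examples.
"""

from microaqua import (ReactionRecord, gen_table1_scenarios, molar_mass,
                       percent_yield, specific_productivity, titre)

print("substrate  cat[g/L]  beads[g/L]  H2O[mL/L]  t[h]  productivity")
for s in gen_table1_scenarios():
    rec = ReactionRecord(s.substrate_m, s.conversion, s.catalyst_g_per_l, s.time_h)
    p = specific_productivity(rec)
    print(f"{s.substrate_m:9.1f}  {s.catalyst_g_per_l:8.0f}  {s.support_bead_g_per_l:10.0f}"
          f"  {s.free_water_ml_per_l:9.0f}  {s.time_h:4.1f}  {p:7.2f}"
          f"   (reported {s.productivity_printed} ± {s.productivity_sd})")

ams = molar_mass("C11H12O3")
print(f"\n0.1 M product titre: {titre(0.1, ams):.1f} g/L (AMS, M = {ams:.2f} g/mol)")
print(f"crude yield, 4-acetoxystyrene 14.5 mg at 0.1 mmol: "
      f"{percent_yield(14.5, 0.1, molar_mass('C10H10O2')):.1f} %")
# Productivity stays near 24-28 mmol/g/h across a 20-fold substrate range
# once beads buffer the water activity - the basis for intensification.
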