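"""Water capacity and activity of a reacting CPME mixture.

Calibrates the water–CPME interaction to the 0.7 wt% dissolved-water
anchor, then shows how dissolving ferulic acid (FA) raises the medium's
water capacity while converting it to 4-vinylguaiacol (4VG) lowers it
again — the polarity see-saw that drives water activity during the
reaction.
"""

from microaqua import (MixtureComposition, calibrate_water_cpme,
                       default_model, water_activity, water_capacity)

a_wc = calibrate_water_cpme(0.007)
print(f"calibrated water-CPME Margules parameter: A = {a_wc:.4f}")

model = default_model()
for label, solutes in [
    ("pure CPME", {"CPME": 8.586}),
    ("+100 mM FA", {"CPME": 8.586, "FA": 0.1}),
    ("after conversion to 4VG", {"CPME": 8.586, "4VG": 0.1}),
]:
    cap = water_capacity(MixtureComposition(solutes), model)
    print(f"{label:28s} capacity = {100 * cap.x_sat:.3f} mol% water")

# a saturated binary water/CPME mixture sits at unit water activity
x_sat = water_capacity(MixtureComposition({"CPME": 1.0}), model).x_sat
sat = MixtureComposition({"CPME": 1.0 - x_sat, "H2O": x_sat})
print(f"water activity at saturation: a_W = {water_activity(sat, model):.6f}")

# Capacity is the mole fraction of water the medium can hold in equilibrium
# with a (nearly pure) water phase; the FA-containing mixture holds more
# water than pure CPME, the 4VG mixture less than the FA one.
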