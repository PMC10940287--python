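"""Saturation scan: where does added water stop entering the bulk phase?

A series of bulk water fractions at increasing total water counts shows a
lag (water coordinates to the surface first), a linear rise, and a plateau
once the system saturates.  The segmented fit locates the plateau start.
"""

from microaqua import gen_saturation_series, saturation_scan

series = gen_saturation_series(lag_end=200, slope=1e-5, n_sat=1400,
                               noise_sd=0.0012, seed=5)
result = saturation_scan(series)

print("N_H2O   x_H2O(bulk)")
for n, x in series:
    print(f"{n:6.0f}  {x:.5f}")
print(f"\nsaturated: {result.saturated}")
print(f"lag end:   N = {result.lag_end:g}")
print(f"N_sat:     N = {result.n_sat:g}")
# N_sat is the water count at which the bulk stops taking up further water;
# beyond it, excess water only fluctuates (droplet formation).
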