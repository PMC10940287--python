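"""All-in operation: solid substrate reserve and the capacity zenith.

Charging 0.5 M ferulic acid at once exceeds its ~31 g/L solubility in wet
CPME: the dissolved phase saturates, the excess is held as a solid reserve
that redissolves as conversion frees capacity, and the water capacity of
the medium passes through an interior maximum ("zenith") before the
homogeneous finish.
"""

from microaqua import FeedSchedule, ReservoirSpec, simulate

result = simulate(FeedSchedule.all_in(0.5, grid=11), ReservoirSpec())
df = result.to_dataframe()
print(df[["coordinate", "FA_mol", "solid_FA_mol", "VG4_mol",
          "capacity_molpct", "a_w", "stage"]].to_string(index=False))
print()
for key, val in result.summary.items():
    print(f"{key}: {val}")
# The solid reserve depletes monotonically; capacity climbs while dissolved
# FA is pinned at saturation and 4VG accumulates, then falls once the last
# FA converts — the single interior maximum reported as the zenith.
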