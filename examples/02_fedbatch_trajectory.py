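"""Fed-batch reaction-coordinate simulation with and without reservoirs.

Three 100 mM substrate batches are fed and converted in sequence.  Without
reservoirs the water activity dips after every feed (capacity jumps up) and
recovers within the batch (capacity decays); moist beads plus free water at
a 4:1 (g:mL) ratio buffer the dips.
"""

from microaqua import FeedSchedule, ReservoirSpec, simulate

schedule = FeedSchedule.fed_batch(n_batches=3, feed_m=0.1, grid=6)

bare = simulate(schedule, ReservoirSpec())
buffered = simulate(schedule, ReservoirSpec(free_water_ml=4.0, bead_g=16.0))

print("coordinate  capacity[mol%]  a_W(bare)  a_W(buffered)")
for s_bare, s_buf in zip(bare.states, buffered.states):
    print(f"{s_bare.coordinate:10.2f}  {100 * s_bare.capacity:14.3f}"
          f"  {s_bare.a_w:9.4f}  {s_buf.a_w:13.4f}")

print("\nsummary (bare run):", bare.summary)
# Capacity rises at each feed and falls as FA converts to 4VG; a_W mirrors
# it inversely.  The buffered run holds a_W at 1.0 throughout, which is why
# reservoir water keeps the enzyme active at high loadings.
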