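"""Zone occupancy, locomotion, barcoding and feeding-bout segmentation.

Simulates tracking plus a per-frame ethogram for one test session, then
computes the video metrics: per-zone frequency/duration/latency, total
distance and mean velocity, the behavioural-barcode percentages over the
first 10 in-context minutes, and eating-bout segmentation.
"""
import numpy as np

import photocif as pc

zones = pc.ZoneSet()
protocol = pc.Protocol.test(context_id="A", familiar=True,
                            rng=np.random.default_rng(2))
track, eth = pc.simulate_tracking(protocol, zones, seed=2)

zm = pc.zone_metrics(track, zones)
print(zm.to_string(index=False))
print(f"durations sum to session length: "
      f"{np.isclose(zm['duration_s'].sum(), track.duration)}")

dist, vel = pc.locomotion_metrics(track)
print(f"distance {dist:.0f} cm, mean velocity {vel:.1f} cm/s")

entry = protocol.context_entry_time
bins, percent, agg = pc.barcode(eth, window=(entry, entry + 600.0), bin_s=30.0)
print("time budget (% of first 10 in-context minutes):")
print(percent.round(1).to_string())
print(f"food-related vs non-food: {agg['food_related']:.1f}% / {agg['non_food']:.1f}%")

bouts = pc.detect_bouts(eth)
print(f"{bouts.count} eating bouts, {bouts.total_duration:.1f} s total "
      f"(programmed: {len(protocol.bout_schedule)})")
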