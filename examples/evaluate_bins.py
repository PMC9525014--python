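"""Scoring bins: marker-based quality and label-based purity/completeness.

Shows both evaluation views on a small hand-built example: the
marker-based scores used for training-checkpoint selection (no ground
truth needed) and the bp-weighted label metrics used on communities with
known genome membership.
"""

from collections import Counter

from sagebin.clustering import BinAssignment
from sagebin.evaluation import hq_call, label_metrics, marker_quality
from sagebin.graph_io import MarkerTable

# two bins; bin 0 holds all five markers once, bin 1 misses two and
# carries one duplicate
markers = MarkerTable(
    {
        "a1": Counter({"m1": 1, "m2": 1}),
        "a2": Counter({"m3": 1, "m4": 1, "m5": 1}),
        "b1": Counter({"m1": 1, "m2": 2}),
        "b2": Counter({"m3": 1}),
    }
)
bins = BinAssignment({"a1": 0, "a2": 0, "b1": 1, "b2": 1})
quality = marker_quality(bins, markers)
for b, (comp, cont, _) in sorted(quality.per_bin.items()):
    print(f"bin {b}: completeness {comp:.0f}%  contamination {cont:.0f}%")
print(f"HQ bins (>90/<5, strict): {sorted(hq_call(quality))}\n")

# label-based view: one bin mixes 800 bp of genome A with 200 bp of B
gold = {"x": "A", "y": "B"}
lengths = {"x": 800, "y": 200}
mixed = BinAssignment({"x": 0, "y": 0})
m = label_metrics(mixed, gold, lengths)
print(f"mixed bin: purity {m.average_purity_bp:.2f} (bp-weighted), "
      f"completeness {m.average_completeness_bp:.2f}, F1 {m.f1:.2f}")
print("-> contamination = 1 - purity = 0.20 for the 800/200 mixture")
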