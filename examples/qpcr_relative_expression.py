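"""Relative expression from qPCR threshold cycles.

Expression of a target gene relative to a reference gene (e.g. GAPDH) is
2^(Ct_reference - Ct_target): a target crossing the detection threshold
five cycles after the reference is ~2^-5 = 3.1% of the reference level;
five cycles earlier, 32-fold above it.
"""

from transclip import CtMeasurement, relative_expression

measurements = [
    CtMeasurement("low_expresser", ct_reference=20.0, ct_target=25.0),
    CtMeasurement("equal_to_reference", ct_reference=22.5, ct_target=22.5),
    CtMeasurement("high_expresser", ct_reference=25.0, ct_target=20.0),
]

print(f"{'sample':20s} {'Ct ref':>7s} {'Ct tgt':>7s} {'relative':>10s}")
for m in measurements:
    rel = relative_expression(m)
    print(f"{m.sample_id:20s} {m.ct_reference:7.1f} {m.ct_target:7.1f} "
          f"{rel:10.5g}")
print("\nValues above 1 mean the target outruns the reference; each qPCR "
      "cycle is a factor of two.")
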