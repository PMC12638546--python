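"""Full pipeline on the four reference blink patterns.

Each fixture runs video -> signals -> detection -> eyelid -> matrix ->
phases; the printed parameters are the blink's phase durations, the
closed-phase ratio, and the displacement numbers behind the pattern labels
(normal / incomplete / consecutive).
"""

import blinkscope as bs

for name, (seq, gt) in bs.standard_fixtures().items():
    result = bs.analyze_sequence(seq)
    (blink,) = result.blinks
    p = blink.record.params
    print(f"{name:12s} label={blink.record.label:11s} "
          f"phases {p['closing_ms']:.0f}/{p['closed_ms']:.0f}/{p['opening_ms']:.0f} ms "
          f"(total {p['total_duration_ms']:.0f} ms, closed {p['closed_ratio_pct']:.1f}%) "
          f"min_d={p['min_displacement']:.3f} travel={p['total_displacement']:.3f}")

print()
print("closing/closed/opening are the three phases of one blink on the")
print("0.2-0.7 displacement scale; a minimum above 0.3 is an incomplete")
print("blink, and a second descent before full reopening is consecutive.")
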