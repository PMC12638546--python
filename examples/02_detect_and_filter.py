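"""Detect blink candidates in a multi-blink video and apply the filters.

Three blinks plus one eyelid flutter are rendered; detection finds the
events on the intensity/event profiles and the duration filter rejects the
flutter (under 50 ms), leaving three accepted blinks.
"""

import blinkscope as bs

blinks = [
    bs.BlinkSpec(pre_open_ms=500, close_ms=116, closed_ms=30, open_ms=216,
                 post_open_ms=300, amplitude=1.0),
    bs.BlinkSpec(pre_open_ms=400, close_ms=15, closed_ms=0, open_ms=20,
                 post_open_ms=300, amplitude=0.15),  # flutter, not a blink
    bs.BlinkSpec(pre_open_ms=400, close_ms=100, closed_ms=60, open_ms=200,
                 post_open_ms=300, amplitude=1.0),
    bs.BlinkSpec(pre_open_ms=400, close_ms=80, closed_ms=0, open_ms=120,
                 post_open_ms=500, amplitude=0.5),  # incomplete blink
]
seq, _ = bs.render_blink_video(blinks, bs.SceneSpec(noise_sd=2.0, seed=7), fps=240.0)

intensity = bs.mean_intensity_profile(seq)
events = bs.simulate_events(seq)
cands = bs.detect_candidates(intensity, events)
bs.filter_candidates(cands, seq.fps)

for c in cands:
    print(f"frames {c.x1:4d}-{c.x3:4d}  {c.duration_ms(seq.fps):6.1f} ms  "
          f"{c.status:8s}  reason: {c.reject_reason}")
accepted = sum(c.status == "accepted" for c in cands)
print(f"\n{accepted} accepted of {len(cands)} candidates.")
print("Durations outside 50-1500 ms (flutters, micro-sleeps) are rejected;")
print("the 20% rise/fall symmetry gate removes environmental intensity shifts.")
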