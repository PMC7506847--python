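"""Run the streaming threshold detector on a fall and on each ADL kind.

The detector arms when the acceleration magnitude crosses below 0.95 g,
then checks the next 0.4 s: a fall verdict needs at least half the frames
inside 0.6-0.9 g with angular velocity under 100 deg/s.  The verdict
always lands exactly 400 ms after the candidate start frame.
"""

import numpy as np

import fallcam as fc

fall = fc.simulate_fall(fc.FallProfile(), fs=50.0, seed=3)
events = fc.run_detector(fall)
for e in events:
    print(f"fall trial: verdict={e.verdict} start={e.start_frame} "
          f"qualifying={e.qualifying_count}/20 latency={e.latency_ms:.0f} ms")
print(f"(true fall start frame: {fall.fall_start_frame})")

for kind in ("walk", "jog", "jump", "stand_up", "lie_down"):
    prof = fc.sample_adl_profile(kind, np.random.default_rng(1))
    tr = fc.simulate_adl(prof, fs=50.0, seed=1)
    evs = fc.run_detector(tr)
    verdicts = [e.verdict for e in evs] or ["never armed"]
    print(f"{kind:9s}: {len(evs)} candidate window(s) -> {set(verdicts)}")
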