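"""From an annotated EDF recording to normalized windowed power.

Crops a 4 s clip around the seizure annotation, notch-filters and
bandpasses 80-250 Hz (the high-frequency-oscillation band), computes
mean squared amplitude over 24-sample windows, and min-max scales
globally. Bursts propagate along electrode A with 100 ms steps.
"""

import tempfile
from pathlib import Path

import numpy as np

from seegviz import (
    PhantomSpec,
    apply_filters,
    crop_around_event,
    make_ct_phantom,
    make_recording,
    minmax_normalize,
    read_recording,
    windowed_power,
)

_, _, truth = make_ct_phantom(PhantomSpec(seed=1))
edf = Path(tempfile.mkdtemp()) / "recording.edf"
edf, truth = make_recording(truth, edf, seed=1)

rec = read_recording(edf)
clip, event_s = crop_around_event(rec, "seizure onset")
print(f"clip: {clip.duration_s:.0f} s, event at {event_s:.1f} s into the clip")

trace = minmax_normalize(windowed_power(apply_filters(clip)))
print(f"power trace: {len(trace.channels)} contacts x {trace.n_windows} windows")
print("-> rendered at 1 s per window, a 4 s clip becomes a "
      f"{trace.n_windows} s animation")

for ch in [c for c in trace.channels if c.startswith('A')]:
    i = trace.channels.index(ch)
    w = int(np.argmax(trace.values[i]))
    print(f"  {ch}: peak power {trace.values[i].max():.2f} at window {w} "
          f"({w * trace.window_s:.2f} s of data time)")
# Peak windows increase along A1..A6: the burst arrives ~100 ms later at
# each successive contact, the sequential-activation pattern the
# animation is designed to make visible.
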