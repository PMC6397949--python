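"""Render blink footage, extract motion energy, and detect the blinks back.

Motion energy — the mean absolute frame-to-frame intensity difference over
the eye region — is zero for a static scene and pulses during each blink,
so peak detection on it recovers the blink train.
"""

import numpy as np

from blinksync import (ROIWindow, compute_motion_energy, detect_blinks,
                       render_blink_video)

events = np.array([1.0, 2.4, 4.1, 5.0, 7.3])
fs = 30.0
stack = render_blink_video(events, fs, frame_shape=(48, 64), duration=9.0)
print(f"rendered {stack.frames.shape[0]} frames of {stack.frames.shape[1:]} "
      f"at {fs:.0f} frames/s")

roi = ROIWindow(top=0, left=0, height=48, width=64)
me = compute_motion_energy(stack, roi)
print(f"motion energy: {len(me)} samples, "
      f"{np.count_nonzero(me.values)} non-zero "
      f"(non-zero only while an eyelid is moving)")

detected = detect_blinks(me)
print(f"true blink onsets:  {events}")
print(f"detected peaks at:  {np.round(detected.times, 2)}")
print("each detection falls inside its blink: the peak sits at the fastest "
      "phase of the eyelid sweep, a few frames after the onset")
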