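"""Imaging inverse stack on a drifting rendered movie.

Renders ten bright spots drifting linearly, detects them frame by frame,
links tracks, estimates and removes the stage drift, and extracts a
background-corrected intensity trace; prints the drift recovery and the
photometry error.
"""

import numpy as np
import pandas as pd

from poretrace.simulate import (NoiseParams, acquisition_schedule,
                                render_movie)
from poretrace.tracking import (correct_drift, detect_spots, estimate_drift,
                                extract_trace, link_tracks)
from poretrace.transport import Vesicle

n_frames, drift_true = 40, (0.12, -0.07)
rng = np.random.default_rng(0)
positions = [(float(x), float(y))
             for x, y in rng.uniform(20, 100, size=(10, 2))]
schedule = acquisition_schedule(1, 1, 0.1, 0.0, n_cycles=n_frames,
                                channel_labels=("dye",))
vesicles = [Vesicle(id=i, diameter=200.0, content={}, position=p)
            for i, p in enumerate(positions)]
traces_in = pd.DataFrame([{"vesicle_id": i, "frame": f,
                           "clean_intensity": 4000.0}
                          for f in range(n_frames) for i in range(10)])
movie, _ = render_movie(vesicles, traces_in, schedule,
                        drift=np.tile(drift_true, (n_frames, 1)),
                        noise=NoiseParams(read_sigma=3.0, background=100.0),
                        canvas=128, seed=1)
frames = movie.frames.astype(float)

per_frame = [detect_spots(frames[f], sigma=1.2, k_mad=5.0, frame_index=f)
             for f in range(n_frames)]
tracks = link_tracks(per_frame, max_disp=3.0, max_gap=1)
drift = estimate_drift(tracks, n_frames=n_frames)
est = drift.pairwise.mean(axis=0)
print(f"applied drift {drift_true} px/frame, "
      f"recovered ({est[0]:+.3f}, {est[1]:+.3f}) px/frame")

corrected = correct_drift(frames, drift, margin=10)
x0, y0 = positions[0]
trace = extract_trace(corrected, x0 + 10, y0 + 10, aperture_radius=4.0,
                      bg_annulus=(6.0, 9.0))
print(f"extracted flux {trace.mean():.0f} +/- {trace.std():.0f} counts "
      f"(rendered 4000)")
print("The per-frame-pair mean displacement recovers the stage drift; "
      "after integer-shift correction the aperture photometry returns the "
      "rendered spot flux.")
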