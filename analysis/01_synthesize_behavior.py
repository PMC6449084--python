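#!/usr/bin/env python
"""Generate the synthetic behavioural dataset used by the later stages.

Writes a long spontaneous-swimming kinematics record (with escape trials
triggered by simulated stimuli), its ground-truth episode table, and a
short rendered video of a swimming fish under results/synthetic/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from zfswim import io as zio
from zfswim.synth import SynthConfig, make_kinematics
from zfswim.synth.render import render_frames

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

config = SynthConfig()
config.to_yaml(OUT / "config.yaml")

# Spontaneous record with periodic escape stimuli
stimuli = list(np.arange(50.0, 600.0, 60.0))
kin, truth = make_kinematics(config, duration_s=600.0, seed=101,
                             stimulus_times_s=stimuli)
zio.write_kinematics_csv(OUT / "kinematics.csv", kin)
pd.DataFrame([
    {
        "onset_s": ep.onset_s, "offset_s": ep.offset_s, "category": ep.category,
        "first_bend_amplitude_deg": ep.first_bend_amplitude_deg,
        "n_bends": len(ep.bend_peak_times_s),
        "beat_freq_hz": ep.beat_freq_hz,
        "stimulus_time_s": ep.stimulus_time_s,
    }
    for ep in truth.episodes
]).to_csv(OUT / "episode_truth.csv", index=False)

counts = {c: truth.categories.count(c) for c in sorted(set(truth.categories))}
print(f"generated {len(truth.episodes)} episodes over 600 s: {counts}")

# Short rendered movie (2 s) for the tracking stage
kin_mov, truth_mov = make_kinematics(
    config, duration_s=2.0, seed=202,
    episodes=[{"onset_s": 0.4, "category": "scoot"},
              {"onset_s": 1.2, "category": "routine_turn"}],
)
stack, midlines = render_frames(kin_mov, None, config, seed=203)
zio.write_tiff_stack(OUT / "movie.tiff", stack, dtype=np.uint8)
zio.write_midlines_h5(OUT / "movie_true_midlines.h5", midlines)
zio.write_kinematics_csv(OUT / "movie_true_kinematics.csv", kin_mov)
print(f"rendered {stack.n_frames} frames ({stack.frames.shape[1]}×{stack.frames.shape[2]} px) to movie.tiff")
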