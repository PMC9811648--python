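"""Preprocess audio and extract the 21 per-frame vocal characteristics.

Reads the synthesized calls, converts to 16-bit PCM, removes the DC mean,
applies pre-emphasis, cuts annotated segments into 50 %-overlapping 40-ms
Blackman frames, drops silent frames, and writes the frame table
(results/run/frames.csv): one row per frame with caller metadata, the
distress rating and the binary label.
"""

import pandas as pd
from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("extract", config())
    tab = pd.read_csv(out / "frames.csv")
    print(
        f"{len(tab)} non-silent frames from {tab['segment_id'].nunique()} segments, "
        f"{tab['caller_id'].nunique()} callers"
    )
    print(f"high-distress prevalence: {tab['label'].mean():.3f}")
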