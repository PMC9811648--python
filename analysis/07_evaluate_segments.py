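"""Aggregate frame probabilities to segment-level classifications.

Each annotated segment is called high distress when its mean out-of-fold
frame probability reaches the Youden threshold; writes frame- and
segment-level confusion summaries and the misclassified-segment report.
"""

import json

import pandas as pd
from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("evaluate", config())
    ev = json.loads((out / "evaluation.json").read_text())
    print(ev["summary"])
    mis = pd.read_csv(out / "misclassified_segments.csv")
    if len(mis):
        print(f"\n{len(mis)} misclassified segments:")
        for r in mis.itertuples():
            print(f"  {r.segment_id}: {r.direction} (mean prob {r.mean_prob:.2f}, {r.n_frames} frames)")
    else:
        print("no misclassified segments")
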