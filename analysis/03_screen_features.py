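"""Remove highly correlated vocal characteristics before model fitting.

Greedy correlation pruning at |r| >= 0.9 (caret-style victim selection);
writes the reduced frame table and the screening report.
"""

import json

from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("screen", config())
    rep = json.loads((out / "screening.json").read_text())
    print(f"kept {len(rep['kept'])} features at |r| < {rep['r_threshold']}")
    for d in rep["dropped"]:
        partner = f" (with {d['partner']}, |r|={d['abs_r']:.3f})" if d["partner"] else ""
        print(f"  dropped {d['feature']}: {d['reason']}{partner}")
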