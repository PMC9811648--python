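"""Select distress predictors with the penalized additive mixed model.

Fits a binomial GAMM with per-sex smooths of each screened feature and a
caller random intercept, writes the term table (beta, SE, CI, edf, F, p
per feature and sex) and the selected predictor set.
"""

import json

import pandas as pd
from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("select", config())
    tt = pd.read_csv(out / "term_table.csv")
    sel = json.loads((out / "selection.json").read_text())
    sig = tt[tt["p"] < 0.05]
    print(f"deviance explained (adjusted): {sel['deviance_explained']:.3f}")
    print(f"significant terms at alpha=0.05:")
    for r in sig.itertuples():
        print(f"  {r.feature} [{r.sex}]: beta={r.beta:+.2f} edf={r.edf:.2f} p={r.p:.3g}")
    print(f"selected features: {sel['features']} (fallback={sel['fallback']})")
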