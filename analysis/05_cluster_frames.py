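"""Group speech frames by k-means and derive cluster principal components.

Builds the explained-variance scree over k = 1..5, picks the elbow,
reports the 2-cluster solution's association with caller sex (Cramer's V)
and its logistic validation, and appends the two leading principal
components of the screened feature space to the frame table as extra
predictors for the classifier.
"""

import json

from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("cluster", config())
    rep = json.loads((out / "cluster.json").read_text())
    print("scree (between-cluster variance fraction):")
    for k, v in rep["scree"].items():
        print(f"  k={k}: {v:.3f}")
    print(f"chosen k: {rep['chosen_k']}")
    print(f"2-cluster vs sex Cramer's V: {rep['cramers_v_sex']:.3f}")
    print(f"cluster validation pseudo-R2: {rep['pseudo_r2']:.3f}")
    for flag in rep["flags"]:
        print(f"  note: {flag}")
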