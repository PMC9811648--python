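"""Classify frames by component-wise gradient boosting, validated LOCO.

Base learners: P-splines per selected feature, sex-difference P-splines,
a caller-intercept ridge, and P-splines of the two cluster principal
components.  The stopping iteration comes from caller-grouped 10-fold CV
inside each leave-one-caller-out fold; reports out-of-fold AUROC/AUPRC
with caller-bootstrap CIs, the Youden threshold, and risk-reduction
variable importance.
"""

import json

from _common import config

from vocaldistress.pipeline import run_stage

if __name__ == "__main__":
    out = run_stage("train", config())
    m = json.loads((out / "metrics.json").read_text())
    print(f"LOCO AUROC : {100 * m['auroc']:.2f}% (95% CI {100 * m['auroc_ci'][0]:.2f}-{100 * m['auroc_ci'][1]:.2f})")
    print(f"LOCO AUPRC : {100 * m['auprc']:.2f}% (95% CI {100 * m['auprc_ci'][0]:.2f}-{100 * m['auprc_ci'][1]:.2f})")
    print(f"Youden threshold: {m['youden_threshold']:.3f}")
    print("variable importance (fraction of in-sample risk reduction):")
    for name, frac in sorted(m["importance"].items(), key=lambda kv: -kv[1]):
        if frac > 0.01:
            print(f"  {name}: {100 * frac:.1f}%")
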