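"""Correlation screening of the frame-level feature set.

Highly collinear acoustic features (e.g. near-duplicate frequency
quantiles) destabilize the additive model downstream, so the feature set
is pruned greedily: while any pair of kept features correlates at or above
the threshold, the member of the worst pair with the larger mean absolute
correlation to everything else is dropped (the caret convention), with an
alphabetical tie-break so the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreeningReport", "prune_correlated", "DEFAULT_R_THRESHOLD"]

DEFAULT_R_THRESHOLD = 0.9


@dataclass
class ScreeningReport:
    kept: list[str]
    dropped: list[dict] = field(default_factory=list)  # {feature, partner, abs_r, reason}
    r_threshold: float = DEFAULT_R_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": self.dropped,
            "r_threshold": self.r_threshold,
        }


def prune_correlated(
    table: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    feature_cols: list[str] | None = None,
) -> ScreeningReport:
    """Greedily drop features until no kept pair has |Pearson r| >= threshold.

    Zero-variance columns are dropped first (correlation undefined).
    Missing values are ignored pairwise.  The result is invariant to row
    order and fully deterministic.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if table[c].dtype.kind == "f"]
    if len(feature_cols) < 2:
        raise ValueError("need at least 2 feature columns to screen")
    if len(table) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")

    dropped: list[dict] = []
    kept = sorted(feature_cols)
    for col in list(kept):
        if np.nanstd(table[col].to_numpy(dtype=float)) == 0.0:
            kept.remove(col)
            dropped.append(
                {"feature": col, "partner": None, "abs_r": None, "reason": "zero variance"}
            )

    corr = table[kept].corr(method="pearson").abs()
    np.fill_diagonal(corr.values, 0.0)

    while len(kept) >= 2:
        sub = corr.loc[kept, kept]
        worst = float(sub.values.max())
        if worst < r_threshold:
            break
        i, j = np.unravel_index(int(np.argmax(sub.values)), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        mean_a, mean_b = float(sub.loc[a].mean()), float(sub.loc[b].mean())
        if mean_a > mean_b or (mean_a == mean_b and a > b):
            victim, partner = a, b
        else:
            victim, partner = b, a
        kept.remove(victim)
        dropped.append(
            {"feature": victim, "partner": partner, "abs_r": worst, "reason": "correlated"}
        )

    # preserve original column order in the kept list
    kept = [c for c in feature_cols if c in set(kept)]
    return ScreeningReport(kept=kept, dropped=dropped, r_threshold=r_threshold)
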