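"""Component-wise gradient boosting for frame-level distress classification.

Functional gradient descent on the binomial deviance: the additive
predictor starts at the log-odds of the prevalence; at each iteration every
base learner is fitted to the negative gradient (y - p) by penalized least
squares, the learner with the smallest residual sum of squares wins, and a
shrunken step (nu) of its fit is added.  Base learners are P-splines per
feature, sex-difference P-splines (so moderation by sex is selectable per
component), a ridge block of caller intercepts (the random effect), and
linear learners for the cluster principal components.  Because only one
learner moves per iteration the selection path doubles as a variable
importance decomposition: each learner is credited with the in-sample risk
reduction of its iterations.

Validation is grouped: 10-fold caller-grouped CV picks the stopping
iteration, and leave-one-caller-out (LOCO) CV measures generalization to
unseen callers, whose random-effect contribution is fixed at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import brentq

__all__ = [
    "BaseLearner",
    "BoostModel",
    "DiscriminationReport",
    "make_learners",
    "fit_cgb",
    "select_mstop_cv",
    "predict_prob",
    "youden_threshold",
    "loco_cv",
    "auroc",
    "auprc",
    "discrimination",
    "variable_importance",
]

SPLINE_DEGREE = 3
N_BASIS = 9
DF_TARGET = 4.0


def _pspline_knots(x: np.ndarray, n_basis: int = N_BASIS) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-6)
    n_interior = n_basis - SPLINE_DEGREE - 1
    inner = np.linspace(lo - 1e-3 * span, hi + 1e-3 * span, n_interior + 2)
    return np.concatenate(
        [np.full(SPLINE_DEGREE, inner[0] - 1e-3 * span), inner,
         np.full(SPLINE_DEGREE, inner[-1] + 1e-3 * span)]
    )


def _eval_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo = knots[SPLINE_DEGREE] + 1e-12
    hi = knots[-SPLINE_DEGREE - 1] - 1e-12
    return BSpline.design_matrix(np.clip(x, lo, hi), knots, SPLINE_DEGREE).toarray()


@dataclass
class BaseLearner:
    """One selectable model component with a fixed effective df."""

    name: str
    kind: str  # {intercept, pspline, pspline_by_sex, ridge_caller, linear}
    feature: str | None = None
    df_target: float = DF_TARGET
    # fitted-at-build state
    knots: np.ndarray | None = None
    center: np.ndarray | None = None
    lam: float = 0.0
    solver: np.ndarray | None = None  # (p_j, n) map from gradient to coefficients
    design: np.ndarray | None = None  # (n, p_j) training design block
    caller_index: dict | None = None
    sex_center: float = 0.0
    x_mean: float = 0.0
    x_sd: float = 1.0
    df_actual: float = 0.0
    coef: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def new_data_design(self, table: pd.DataFrame) -> np.ndarray:
        if self.kind == "intercept":
            return np.ones((len(table), 1))
        if self.kind == "ridge_caller":
            Z = np.zeros((len(table), len(self.caller_index)))
            for i, c in enumerate(table["caller_id"]):
                j = self.caller_index.get(c)
                if j is not None:  # unseen caller -> all-zero row (effect 0)
                    Z[i, j] = 1.0
            return Z
        if self.feature not in table.columns:
            raise KeyError(f"table lacks feature column {self.feature!r}")
        z = (table[self.feature].to_numpy(dtype=float) - self.x_mean) / self.x_sd
        if self.kind == "linear":
            return z[:, None]
        B = _eval_basis(z, self.knots) - self.center
        if self.kind == "pspline_by_sex":
            male = (table["sex"].to_numpy() == "male").astype(float) - self.sex_center
            B = B * male[:, None]
        return B


def _df_for_lambda(XtX: np.ndarray, S: np.ndarray, lam: float) -> float:
    H = XtX + lam * S
    try:
        return float(np.trace(np.linalg.solve(H, XtX)))
    except np.linalg.LinAlgError:  # rank-deficient block at tiny lambda
        return float(np.trace(np.linalg.pinv(H) @ XtX))


def _solve_lambda_for_df(XtX: np.ndarray, S: np.ndarray, df: float) -> float:
    """Bisection for the penalty weight hitting the df target."""
    p = XtX.shape[0]
    if df >= p - 0.05:
        return 0.0
    f = lambda loglam: _df_for_lambda(XtX, S, 10.0**loglam) - df
    lo, hi = -8.0, 12.0
    if f(lo) < 0:  # block rank below target even unpenalized
        return 10.0**lo
    return 10.0 ** brentq(f, lo, hi, xtol=1e-3)


def make_learners(
    table: pd.DataFrame,
    features: list[str],
    pc_cols: list[str] = (),
    with_caller: bool = True,
    with_sex: bool = True,
    with_intercept: bool = False,
    df_target: float = DF_TARGET,
) -> list[BaseLearner]:
    """Build and pre-factorize the base-learner set on the training table.

    Every feature contributes a shared P-spline learner and (when sex
    moderation is on) a sex-difference P-spline learner; caller intercepts
    form one ridge learner; each principal-component column a linear
    learner.  Each learner's penalty is tuned so its effective df matches
    df_target (within 0.1), making selection fair across learner types.
    """
    n = len(table)
    learners: list[BaseLearner] = []
    male_frac = float(np.mean(table["sex"].to_numpy() == "male")) if "sex" in table.columns else 0.0

    def finalize(lrn: BaseLearner, X: np.ndarray, S: np.ndarray) -> BaseLearner:
        XtX = X.T @ X
        lam = _solve_lambda_for_df(XtX, S, lrn.df_target)
        H = XtX + lam * S + 1e-10 * np.eye(X.shape[1])
        lrn.lam = lam
        lrn.solver = np.linalg.solve(H, X.T)
        lrn.design = X
        lrn.df_actual = float(np.trace(np.linalg.solve(H, XtX)))
        lrn.coef = np.zeros(X.shape[1])
        return lrn

    D2 = np.diff(np.eye(N_BASIS), n=2, axis=0)
    S_spline = D2.T @ D2 + 1e-8 * np.eye(N_BASIS)

    if with_intercept:
        lrn = BaseLearner(name="intercept", kind="intercept", df_target=1.0)
        learners.append(finalize(lrn, np.ones((n, 1)), np.eye(1)))

    for feat in features:
        raw = table[feat].to_numpy(dtype=float)
        mu, sd = float(np.mean(raw)), float(np.std(raw))
        sd = sd if sd > 0 else 1.0
        z = (raw - mu) / sd
        knots = _pspline_knots(z)
        B = _eval_basis(z, knots)
        center = B.mean(axis=0)
        Bc = B - center
        lrn = BaseLearner(
            name=f"pspline({feat})", kind="pspline", feature=feat, df_target=df_target,
            knots=knots, center=center, x_mean=mu, x_sd=sd,
        )
        learners.append(finalize(lrn, Bc, S_spline))
        if with_sex and "sex" in table.columns and table["sex"].nunique() > 1:
            male = (table["sex"].to_numpy() == "male").astype(float) - male_frac
            lrn2 = BaseLearner(
                name=f"pspline_by_sex({feat})", kind="pspline_by_sex", feature=feat,
                df_target=df_target, knots=knots, center=center, x_mean=mu, x_sd=sd,
            )
            lrn2.sex_center = male_frac
            learners.append(finalize(lrn2, Bc * male[:, None], S_spline))

    if with_caller and "caller_id" in table.columns:
        callers = sorted(table["caller_id"].unique().tolist())
        index = {c: i for i, c in enumerate(callers)}
        Z = np.zeros((n, len(callers)))
        Z[np.arange(n), [index[c] for c in table["caller_id"]]] = 1.0
        lrn = BaseLearner(
            name="ridge_caller", kind="ridge_caller", df_target=min(df_target, len(callers) - 0.5),
            caller_index=index,
        )
        learners.append(finalize(lrn, Z, np.eye(len(callers))))

    # cluster principal components enter like any other predictor: P-spline
    # learners at the common df so selection between components stays fair
    for pc in pc_cols:
        x = table[pc].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x))
        sd = sd if sd > 0 else 1.0
        z = (x - mu) / sd
        knots = _pspline_knots(z)
        B = _eval_basis(z, knots)
        center = B.mean(axis=0)
        lrn = BaseLearner(
            name=f"pspline({pc})", kind="pspline", feature=pc, df_target=df_target,
            knots=knots, center=center, x_mean=mu, x_sd=sd,
        )
        learners.append(finalize(lrn, B - center, S_spline))
    return learners


@dataclass
class BoostModel:
    learners: list[BaseLearner]
    nu: float
    mstop: int
    offset: float
    selection_path: list[int]
    risk_path: list[float]  # mean negative log-likelihood per iteration (incl. start)
    risk_reduction: np.ndarray  # per learner, summed over its winning iterations
    youden_threshold_: float | None = None

    @property
    def prevalence(self) -> float:
        return 1.0 / (1.0 + np.exp(-self.offset))


def _mean_nll(y: np.ndarray, f: np.ndarray) -> float:
    p = np.clip(1.0 / (1.0 + np.exp(-f)), 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_cgb(
    table: pd.DataFrame,
    labels: np.ndarray,
    learners: list[BaseLearner],
    nu: float = 0.1,
    mstop: int = 100,
    track: pd.DataFrame | None = None,
    offset: float | None = None,
) -> BoostModel | tuple[BoostModel, np.ndarray]:
    """Boost mstop iterations; optionally track held-out scores along the path.

    Learner selection minimizes residual SS against the negative gradient
    (the functional-gradient reading of "best reduction in classification
    error").  The training risk path is recorded and is non-increasing.
    With track=table_test, also returns the (n_test, mstop+1) score path
    used by the CV routines.
    """
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("labels are single-class")
    if not learners:
        raise ValueError("no base learners")
    if mstop < 0:
        raise ValueError("mstop must be >= 0")
    learners = [  # fresh coefficient state; design stays shared
        BaseLearner(**{**lrn.__dict__, "coef": np.zeros(lrn.solver.shape[0])})
        for lrn in learners
    ]
    if offset is None:
        prev = y.mean()
        offset = float(np.log(prev / (1.0 - prev)))
    n = len(y)
    f = np.full(n, offset)
    path: list[int] = []
    risk = [_mean_nll(y, f)]
    reduction = np.zeros(len(learners))

    test_path = None
    test_designs = None
    if track is not None:
        test_designs = [lrn.new_data_design(track) for lrn in learners]
        test_path = np.empty((len(track), mstop + 1))
        f_test = np.full(len(track), offset)
        test_path[:, 0] = f_test

    for m in range(mstop):
        p = 1.0 / (1.0 + np.exp(-f))
        u = y - p  # negative gradient of the deviance risk
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"non-finite gradient at iteration {m}")
        best_j, best_ss, best_coef, best_fit = -1, np.inf, None, None
        for j, lrn in enumerate(learners):
            coef = lrn.solver @ u
            fit_j = lrn.design @ coef
            ss = float(np.sum((u - fit_j) ** 2))
            if ss < best_ss - 1e-12:
                best_j, best_ss, best_coef, best_fit = j, ss, coef, fit_j
        f = f + nu * best_fit
        learners[best_j].coef = learners[best_j].coef + nu * best_coef
        path.append(best_j)
        new_risk = _mean_nll(y, f)
        reduction[best_j] += max(risk[-1] - new_risk, 0.0)
        risk.append(new_risk)
        if test_path is not None:
            f_test = f_test + nu * (test_designs[best_j] @ best_coef)
            test_path[:, m + 1] = f_test

    model = BoostModel(
        learners=learners, nu=nu, mstop=mstop, offset=offset,
        selection_path=path, risk_path=risk, risk_reduction=reduction,
    )
    if track is not None:
        return model, test_path
    return model


def predict_prob(model: BoostModel, table: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of offset + learner contributions; unseen callers get 0."""
    f = np.full(len(table), model.offset)
    for lrn in model.learners:
        if np.any(lrn.coef):
            f = f + lrn.new_data_design(table) @ lrn.coef
    return 1.0 / (1.0 + np.exp(-f))


def _grouped_stratified_folds(
    callers: np.ndarray, labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Caller-grouped folds, balanced on caller-level prevalence."""
    ids = pd.unique(callers)
    rng = np.random.default_rng(seed)
    prev = np.array([labels[callers == c].mean() for c in ids])
    order = np.argsort(prev + 1e-9 * rng.random(len(ids)))
    folds_of = np.empty(len(ids), dtype=int)
    snake = list(range(n_folds)) + list(range(n_folds - 1, -1, -1))
    for rank, ci in enumerate(order):
        folds_of[ci] = snake[rank % len(snake)]
    fold_masks = []
    for k in range(n_folds):
        members = set(ids[folds_of == k])
        fold_masks.append(np.array([c in members for c in callers]))
    return [m for m in fold_masks if m.any()]


def select_mstop_cv(
    table: pd.DataFrame,
    labels: np.ndarray,
    learner_builder,
    folds: int = 10,
    mstop_grid: np.ndarray | None = None,
    nu: float = 0.1,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose mstop by caller-grouped k-fold CV minimizing out-of-fold deviance.

    learner_builder(table) -> learner list, rebuilt inside every fold so no
    test-fold information leaks into knots, penalties or caller indices.
    Returns (chosen mstop, per-grid summary with a one-standard-error flag).
    """
    grid = np.asarray(mstop_grid if mstop_grid is not None else [25, 50, 100, 150], dtype=int)
    if len(grid) == 1:
        return int(grid[0]), pd.DataFrame({"mstop": grid, "mean_deviance": [np.nan]})
    y = np.asarray(labels, dtype=float)
    callers = table["caller_id"].to_numpy()
    n_callers = len(pd.unique(callers))
    if n_callers < folds:
        warnings.warn(f"only {n_callers} callers; reducing folds", stacklevel=2)
        folds = max(2, n_callers)
    masks = _grouped_stratified_folds(callers, y, folds, seed)
    mmax = int(grid.max())
    base = float(np.log(y.mean() / (1.0 - y.mean())))  # common base rate
    dev = np.zeros((len(masks), len(grid)))
    for i, test_mask in enumerate(masks):
        tr, te = ~test_mask, test_mask
        if y[tr].min() == y[tr].max() or not te.any():
            dev[i] = np.nan
            continue
        lrns = learner_builder(table[tr])
        _, fpath = fit_cgb(
            table[tr], y[tr], lrns, nu=nu, mstop=mmax, track=table[te], offset=base
        )
        for g, m in enumerate(grid):
            dev[i, g] = _mean_nll(y[te], fpath[:, m])
    mean_dev = np.nanmean(dev, axis=0)
    se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(dev[:, 0])))
    best = int(np.nanargmin(mean_dev))
    within_1se = mean_dev <= mean_dev[best] + se_dev[best]
    summary = pd.DataFrame(
        {"mstop": grid, "mean_deviance": mean_dev, "se": se_dev, "within_1se": within_1se}
    )
    return int(grid[best]), summary


def youden_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Cutpoint maximizing Youden J = sensitivity + specificity - 1.

    Candidates are the observed probabilities; ties in J break toward the
    candidate nearest 0.5.  Degenerate inputs (constant probabilities)
    return that value with a warning.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("labels are single-class")
    cand = np.unique(p)
    if cand.size == 1:
        warnings.warn("all probabilities identical: J = 0", stacklevel=2)
        return float(cand[0])
    n_pos, n_neg = y.sum(), (1 - y).sum()
    # J(tau) over candidate cutpoints (predict high iff p >= tau)
    best_j, best_tau = -np.inf, 0.5
    for tau in cand:
        pred = p >= tau
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (
            abs(j - best_j) <= 1e-12 and abs(tau - 0.5) < abs(best_tau - 0.5)
        ):
            best_j, best_tau = j, float(tau)
    return best_tau


def loco_cv(
    table: pd.DataFrame,
    labels: np.ndarray,
    learner_builder,
    nu: float = 0.1,
    mstop_rule=None,
    fixed_mstop: int | None = None,
    inner_folds: int = 10,
    mstop_grid: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-caller-out out-of-fold probabilities, in original row order.

    One fold per caller; the fold model never sees the held-out caller, and
    that caller's random-effect contribution is necessarily zero at predict
    time.  mstop per fold comes from the caller-grouped k-fold rule on the
    training portion (or fixed_mstop to skip the inner CV).  All folds share
    the pooled base-rate offset: a per-fold offset anti-correlates with the
    held-out caller's prevalence and injects spurious (negative) pooled
    discrimination.
    """
    y = np.asarray(labels, dtype=float)
    callers = table["caller_id"].to_numpy()
    ids = pd.unique(callers)
    if len(ids) < 2:
        raise ValueError("need >= 2 callers for leave-one-caller-out")
    probs = np.full(len(table), np.nan)
    base = float(np.log(y.mean() / (1.0 - y.mean())))
    for c in ids:
        te = callers == c
        tr = ~te
        if y[tr].min() == y[tr].max():
            warnings.warn(f"training folds single-class without caller {c}; skipped", stacklevel=2)
            continue
        if fixed_mstop is not None:
            m = fixed_mstop
        else:
            m, _ = select_mstop_cv(
                table[tr], y[tr], learner_builder, folds=inner_folds,
                mstop_grid=mstop_grid, nu=nu, seed=seed,
            )
        lrns = learner_builder(table[tr])
        _, fpath = fit_cgb(
            table[tr], y[tr], lrns, nu=nu, mstop=m, track=table[te], offset=base
        )
        probs[te] = 1.0 / (1.0 + np.exp(-fpath[:, m]))
    return probs


def auroc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by the rank statistic with midranks for ties."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auprc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by stepwise integration."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    n_pos = y.sum()
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("both classes required")
    # collapse tied scores to the last index of each tie block
    last_of_tie = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tp, fp = tp[last_of_tie], fp[last_of_tie]
    precision = tp / np.maximum(tp + fp, 1)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class DiscriminationReport:
    auroc: float
    auroc_ci: tuple[float, float]
    auprc: float
    auprc_ci: tuple[float, float]
    threshold: float
    confusion: dict
    n_boot: int
    seed: int


def discrimination(
    probs: np.ndarray,
    labels: np.ndarray,
    callers: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> DiscriminationReport:
    """AUROC/AUPRC with percentile bootstrap CIs resampling callers.

    Resampling whole callers (not frames) respects the within-caller
    dependence of consecutive frames; with callers=None frames are
    resampled i.i.d. as a fallback.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    point_roc = auroc(p, y)
    point_pr = auprc(p, y)
    tau = youden_threshold(p, y)
    pred = (p >= tau).astype(int)
    confusion = {
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
    }
    rng = np.random.default_rng(seed)
    rocs, prs = [], []
    if callers is not None:
        ids = pd.unique(np.asarray(callers))
        groups = {c: np.flatnonzero(np.asarray(callers) == c) for c in ids}
        for _ in range(n_boot):
            pick = rng.choice(ids, size=len(ids), replace=True)
            idx = np.concatenate([groups[c] for c in pick])
            if y[idx].min() == y[idx].max():
                continue
            rocs.append(auroc(p[idx], y[idx]))
            prs.append(auprc(p[idx], y[idx]))
    else:
        n = len(y)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if y[idx].min() == y[idx].max():
                continue
            rocs.append(auroc(p[idx], y[idx]))
            prs.append(auprc(p[idx], y[idx]))
    def ci(vals, point):
        if len(vals) < 10:
            return (point, point)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (float(min(lo, point)), float(max(hi, point)))
    return DiscriminationReport(
        auroc=point_roc, auroc_ci=ci(rocs, point_roc),
        auprc=point_pr, auprc_ci=ci(prs, point_pr),
        threshold=tau, confusion=confusion, n_boot=n_boot, seed=seed,
    )


def variable_importance(model: BoostModel) -> dict[str, float]:
    """Per-learner fraction of total in-sample risk reduction (sums to 1)."""
    total = model.risk_reduction.sum()
    if model.mstop == 0 or total <= 0:
        warnings.warn("no boosting iterations: importance undefined", stacklevel=2)
        return {}
    return {
        lrn.name: float(r / total)
        for lrn, r in zip(model.learners, model.risk_reduction)
    }
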