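"""Penalized binomial additive mixed model with per-sex smooths.

The selection model regresses the binary frame label (high vs low
distress) on smooth functions of each z-scored acoustic feature, separately
for male and female callers, plus a caller random intercept:

    logit P(high) = b0 + b_sex * male + sum_{j,s} f_{j,s}(x_j) * [sex = s] + u_caller

Each smooth is a centered cubic B-spline block with a second-difference
(curvature) penalty; an additional null-space "shrinkage" penalty lets the
linear component of a smooth be penalized to zero as well, so whole terms
can be selected out — the device realizing "penalized" selection.  Caller
intercepts enter as a ridge-penalized indicator block; the ridge weight
plays the role of 1/variance of the random effect.  Smoothing weights are
chosen by generalized cross-validation on the converged working model
(performance iteration), scanned over a log-spaced grid.

Term significance uses Wood-style approximate tests: the statistic
b_j' V_j^{-(r)} b_j with rank r tied to the term's estimated degrees of
freedom, referred to an F distribution.  Terms with p below alpha, per
(feature, sex), form the reduced predictor set for the later stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GammSpec",
    "GammDesign",
    "GammFit",
    "SelectionResult",
    "build_design",
    "fit_pgamm",
    "term_table",
    "select_predictors",
    "partial_effect_curves",
]

SPLINE_DEGREE = 3
DEFAULT_N_BASIS = 9


@dataclass
class GammSpec:
    predictors: list[str]
    n_basis: int = DEFAULT_N_BASIS
    sex_moderation: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_basis < 4:
            raise ValueError("need at least 4 basis functions per smooth")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SmoothTerm:
    feature: str
    sex: str  # "male" / "female" / "all"
    sl: slice  # column slice in the design matrix
    knots: np.ndarray
    center: np.ndarray  # column means subtracted within the sex stratum
    x_mean: float  # z-scoring parameters of the raw feature
    x_sd: float
    S: np.ndarray  # curvature penalty (normalized)
    N: np.ndarray  # null-space (shrinkage) penalty


@dataclass
class GammDesign:
    X: np.ndarray
    terms: list[SmoothTerm]
    intercept_idx: int
    sex_idx: int | None
    caller_sl: slice | None
    caller_ids: list
    col_names: list[str]
    sex_values: np.ndarray
    cluster_values: np.ndarray | None = None  # segment ids for robust inference
    dropped_terms: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _bspline_knots(x: np.ndarray, n_basis: int) -> np.ndarray:
    """Uniform knot vector giving n_basis cubic B-splines over the data range.

    Uniform spacing makes the second-difference coefficient penalty's null
    space correspond exactly to linear functions of x (the P-spline
    construction), so "penalized to linear" means genuinely linear.
    """
    n_interior = n_basis - SPLINE_DEGREE - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-6)
    inner = np.linspace(lo - 1e-3 * span, hi + 1e-3 * span, n_interior + 2)
    step = inner[1] - inner[0]
    return np.concatenate(
        [inner[0] - step * np.arange(SPLINE_DEGREE, 0, -1), inner,
         inner[-1] + step * np.arange(1, SPLINE_DEGREE + 1)]
    )


def _basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo = knots[SPLINE_DEGREE] + 1e-12
    hi = knots[-SPLINE_DEGREE - 1] - 1e-12
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, SPLINE_DEGREE).toarray()


def _penalties(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(curvature penalty, null-space shrinkage penalty), both normalized."""
    D2 = np.diff(np.eye(k), n=2, axis=0)
    S = D2.T @ D2
    S = S / np.linalg.eigvalsh(S).max()
    w, v = np.linalg.eigh(S)
    null = v[:, w < 1e-10]
    N = null @ null.T
    return S, N


def build_design(table: pd.DataFrame, spec: GammSpec) -> GammDesign:
    """Assemble the penalized design: intercept, sex, per-sex smooths, callers.

    Predictors are z-scored internally.  Each smooth block is evaluated on
    the rows of its sex stratum, column-centered within the stratum (zero
    elsewhere) so that smooths are identifiable against the intercept and
    the sex main effect.
    """
    n = len(table)
    sex = table["sex"].to_numpy() if "sex" in table.columns else np.full(n, "all")
    cols: list[np.ndarray] = [np.ones((n, 1))]
    names = ["intercept"]
    sex_idx = None
    strata: list[tuple[str, np.ndarray]]
    if spec.sex_moderation:
        male = (sex == "male").astype(float)
        cols.append((male - male.mean())[:, None])
        names.append("sex_male")
        sex_idx = 1
        strata = [("male", sex == "male"), ("female", sex == "female")]
    else:
        strata = [("all", np.ones(n, dtype=bool))]

    terms: list[SmoothTerm] = []
    dropped: list[tuple[str, str]] = []
    pos = len(names)
    for feat in spec.predictors:
        raw = table[feat].to_numpy(dtype=float)
        mu, sd = float(np.nanmean(raw)), float(np.nanstd(raw))
        if sd == 0.0:
            warnings.warn(f"predictor {feat} constant overall; dropped", stacklevel=2)
            dropped.extend((feat, s) for s, _ in strata)
            continue
        z = (raw - mu) / sd
        for sname, mask in strata:
            if mask.sum() < spec.n_basis + 2 or np.nanstd(z[mask]) == 0.0:
                warnings.warn(
                    f"predictor {feat} unusable within sex={sname}; term dropped",
                    stacklevel=2,
                )
                dropped.append((feat, sname))
                continue
            knots = _bspline_knots(z[mask], spec.n_basis)
            B = np.zeros((n, spec.n_basis))
            Bm = _basis(z[mask], knots)
            center = Bm.mean(axis=0)
            B[mask] = Bm - center
            S, N = _penalties(spec.n_basis)
            sl = slice(pos, pos + spec.n_basis)
            terms.append(
                SmoothTerm(
                    feature=feat, sex=sname, sl=sl, knots=knots, center=center,
                    x_mean=mu, x_sd=sd, S=S, N=N,
                )
            )
            cols.append(B)
            names.extend(f"s({feat},{sname}).{i}" for i in range(spec.n_basis))
            pos += spec.n_basis

    caller_sl = None
    caller_ids: list = []
    if "caller_id" in table.columns:
        caller_ids = sorted(table["caller_id"].unique().tolist())
        idx = {c: i for i, c in enumerate(caller_ids)}
        Z = np.zeros((n, len(caller_ids)))
        Z[np.arange(n), [idx[c] for c in table["caller_id"]]] = 1.0
        caller_sl = slice(pos, pos + len(caller_ids))
        cols.append(Z)
        names.extend(f"caller[{c}]" for c in caller_ids)
        pos += len(caller_ids)

    X = np.concatenate(cols, axis=1)
    # robust-inference clusters: the segment is the unit that shares a label
    # and carries the serial feature correlation; caller-level confounding is
    # absorbed structurally by the caller-intercept block
    clusters = table["segment_id"].to_numpy() if "segment_id" in table.columns else None
    return GammDesign(
        X=X, terms=terms, intercept_idx=0, sex_idx=sex_idx, caller_sl=caller_sl,
        caller_ids=caller_ids, col_names=names, sex_values=sex,
        cluster_values=clusters, dropped_terms=dropped,
    )


@dataclass
class GammFit:
    design: GammDesign
    beta: np.ndarray
    cov: np.ndarray  # Bayesian covariance (X'WX + P)^-1
    cov_robust: np.ndarray | None  # segment-clustered sandwich, used for tests
    edf: dict[str, float]  # per-term and "caller", "total"
    lambdas: dict[str, float]  # {"smooth", "shrink", "caller"}
    deviance: float
    null_deviance: float
    deviance_explained: float
    fitted: np.ndarray
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)
    deviance_trace: list[float] = field(default_factory=list)

    @property
    def caller_effects(self) -> np.ndarray:
        sl = self.design.caller_sl
        return self.beta[sl] if sl is not None else np.empty(0)

    @property
    def caller_variance(self) -> float:
        # ridge weight lambda_c acts as 1/sigma_b^2 on the working scale
        return 1.0 / self.lambdas["caller"] if self.design.caller_sl is not None else 0.0


def _penalty_matrix(design: GammDesign, lam_s: float, lam_0: float, lam_c: float) -> np.ndarray:
    P = np.zeros((design.p, design.p))
    for t in design.terms:
        P[t.sl, t.sl] += lam_s * t.S + lam_0 * t.N
    if design.caller_sl is not None:
        idx = np.arange(design.caller_sl.start, design.caller_sl.stop)
        P[idx, idx] += lam_c
    return P


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    P: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    dev_prev = np.inf
    trace = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        C = XtW @ X
        b = XtW @ z
        try:
            cf = cho_factor(C + P + 1e-10 * np.eye(p))
        except np.linalg.LinAlgError:
            cf = cho_factor(C + P + 1e-6 * np.eye(p))
        beta = cho_solve(cf, b)
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        trace.append(dev)
        if abs(dev_prev - dev) < tol * (abs(dev) + 0.1):
            return beta, C, cf, w, z, dev, True, it, trace
        dev_prev = dev
    return beta, C, cf, w, z, dev, False, max_iter, trace


def _gcv_scan(C, b, design, grids, n, zWz):
    """Scan penalty grids on a fixed working model; return best lambdas by GCV."""
    p = C.shape[0]
    best = (np.inf, None)
    S_tot = np.zeros((p, p))
    N_tot = np.zeros((p, p))
    for t in design.terms:
        S_tot[t.sl, t.sl] += t.S
        N_tot[t.sl, t.sl] += t.N
    Ic = np.zeros((p, p))
    if design.caller_sl is not None:
        idx = np.arange(design.caller_sl.start, design.caller_sl.stop)
        Ic[idx, idx] = 1.0
    for ls in grids["smooth"]:
        for l0 in grids["shrink"]:
            for lc in grids["caller"]:
                H = C + ls * S_tot + l0 * N_tot + lc * Ic + 1e-10 * np.eye(p)
                try:
                    cf = cho_factor(H)
                except np.linalg.LinAlgError:
                    continue
                beta = cho_solve(cf, b)
                edf = float(np.trace(cho_solve(cf, C)))
                # working residual sum of squares: z'Wz - 2 b'beta + beta'C beta;
                # gamma > 1 charges extra per effective dof against overfitting
                gamma = 1.4
                rss = zWz + float(beta @ C @ beta - 2.0 * b @ beta)
                gcv = max(rss, 0.0) * n / max(n - gamma * edf, 1.0) ** 2
                if gcv < best[0]:
                    best = (gcv, (ls, l0, lc))
    return best[1]


def fit_pgamm(
    design: GammDesign,
    labels: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    fixed_lambdas: dict[str, float] | None = None,
    n_perf_iter: int = 2,
) -> GammFit:
    """Fit the penalized additive mixed model by IRLS with GCV-chosen penalties.

    lambda_grid covers the curvature penalty; shrinkage and caller-ridge
    grids are derived from it.  Passing fixed_lambdas skips GCV (used for
    oracle comparisons and penalty-monotonicity checks; a value of 0 for
    every penalty reduces the fit to unpenalized logistic IRLS).
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    X = design.X
    n = design.n

    if fixed_lambdas is not None:
        lam = {
            "smooth": fixed_lambdas.get("smooth", 0.0),
            "shrink": fixed_lambdas.get("shrink", 0.0),
            "caller": fixed_lambdas.get("caller", 0.0),
        }
    else:
        grid = np.asarray(lambda_grid) if lambda_grid is not None else np.logspace(-1, 4, 5)
        grids = {
            "smooth": grid,
            "shrink": np.logspace(-2, 3, 4),
            "caller": np.logspace(-2, 2, 3) if design.caller_sl is not None else [0.0],
        }
        lam = {"smooth": float(np.median(grid)), "shrink": 1.0, "caller": 1.0}
        beta = None
        for _ in range(n_perf_iter):
            P = _penalty_matrix(design, lam["smooth"], lam["shrink"], lam["caller"])
            beta, C, cf, w, z, dev, conv, nit, trace = _irls(X, y, P, beta0=beta)
            b = (X.T * w) @ z
            picked = _gcv_scan(C, b, design, grids, n, float(np.sum(w * z * z)))
            if picked is None:
                break
            new = {"smooth": picked[0], "shrink": picked[1], "caller": picked[2]}
            if new == lam:
                break
            lam = new

    P = _penalty_matrix(design, lam["smooth"], lam["shrink"], lam["caller"])
    beta, C, cf, w, z, dev, conv, nit, trace = _irls(X, y, P)
    flags = []
    if not conv:
        raise RuntimeError(f"IRLS failed to converge; deviance trace: {trace[-5:]}")
    if np.abs(beta).max() > 1e3:
        flags.append("possible complete separation: diverging coefficients")

    cov = cho_solve(cf, np.eye(design.p))
    # segment-clustered sandwich covariance: frames within a segment share
    # their label and are serially correlated, so model-based SEs overstate
    # the information.  Score contributions use leave-one-segment-out working
    # residuals (a CR3-style (I - H_gg)^-1 adjustment): in-sample residuals
    # of a high-edf penalized fit are deflated and would shrink the sandwich.
    cov_robust = None
    if design.cluster_values is not None:
        mu_fit = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w_fit = mu_fit * (1.0 - mu_fit)
        groups = pd.factorize(design.cluster_values)[0]
        XAinv = X @ cov
        M = np.zeros((design.p, design.p))
        for g in range(groups.max() + 1):
            ix = np.flatnonzero(groups == g)
            Xg, wg = X[ix], w_fit[ix]
            Tg = (y[ix] - mu_fit[ix]) / wg  # working residuals
            Hgg = (XAinv[ix] @ Xg.T) * wg[None, :]
            try:
                tg = np.linalg.solve(np.eye(len(ix)) - Hgg, Tg)
            except np.linalg.LinAlgError:
                tg = Tg
            sg = Xg.T @ (wg * tg)
            M += np.outer(sg, sg)
        cov_robust = cov @ M @ cov
    A_diag = np.einsum("ij,ji->i", cho_solve(cf, C), np.eye(design.p))
    edf: dict[str, float] = {}
    for t in design.terms:
        edf[f"s({t.feature},{t.sex})"] = float(A_diag[t.sl].sum())
    if design.caller_sl is not None:
        edf["caller"] = float(A_diag[design.caller_sl].sum())
    edf["total"] = float(A_diag.sum())

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    p0 = y.mean()
    null_dev = -2.0 * n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
    dev_expl = 1.0 - (dev / max(n - edf["total"], 1.0)) / (null_dev / (n - 1))
    return GammFit(
        design=design, beta=beta, cov=cov, cov_robust=cov_robust, edf=edf, lambdas=lam,
        deviance=dev, null_deviance=null_dev,
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        fitted=mu, converged=conv, n_iter=nit, flags=flags, deviance_trace=trace,
    )


def term_table(fit: GammFit, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-(feature, sex) report: beta, se, 95% CI, edf, F, dfs, p.

    beta is the slope of the least-squares linear component of the fitted
    smooth against the z-scored feature (smooths are not parametric, so the
    linear projection summarizes direction), with a delta-method SE.
    Includes a male-vs-female contrast row when sex moderation is present.
    """
    design = fit.design
    rows = []
    V = fit.cov_robust if fit.cov_robust is not None else fit.cov
    if fit.cov_robust is not None and design.cluster_values is not None:
        # clustered inference: the segment, not the frame, is the unit
        df_den = max(float(len(pd.unique(design.cluster_values)) - 1), 1.0)
    else:
        df_den = max(design.n - fit.edf["total"], 1.0)
    for t in design.terms:
        bj = fit.beta[t.sl]
        Vj = V[t.sl, t.sl]
        edf_j = fit.edf[f"s({t.feature},{t.sex})"]
        r = int(np.clip(np.ceil(edf_j - 1e-8), 1, bj.size))
        w, v = np.linalg.eigh(Vj)
        w = np.maximum(w[::-1], 1e-12)
        v = v[:, ::-1]
        inv_r = (v[:, :r] / w[:r]) @ v[:, :r].T
        F = float(bj @ inv_r @ bj) / r
        p = float(stats.f.sf(F, r, df_den))

        mask = design.sex_values == t.sex if t.sex != "all" else np.ones(design.n, bool)
        B = design.X[np.asarray(mask), t.sl]
        fvals = B @ bj
        # reconstruct z-scored x on the stratum via the basis' Greville-like grid:
        # use the linear projection against the basis-implied coordinate
        if table is not None:
            xz = ((table[t.feature].to_numpy(dtype=float) - t.x_mean) / t.x_sd)[np.asarray(mask)]
        else:
            # fall back: dominant direction of the centered basis
            xz = B @ np.linspace(-1, 1, bj.size)
        xc = xz - xz.mean()
        denom = float(xc @ xc)
        if denom <= 0:
            beta_lin, se_lin = 0.0, np.nan
        else:
            c = (xc @ B) / denom
            beta_lin = float(c @ bj)
            se_lin = float(np.sqrt(max(c @ Vj @ c, 0.0)))
        rows.append(
            {
                "feature": t.feature, "sex": t.sex, "beta": beta_lin, "se": se_lin,
                "ci_low": beta_lin - 1.96 * se_lin, "ci_high": beta_lin + 1.96 * se_lin,
                "edf": edf_j, "F": F, "df_num": r, "df_den": df_den, "p": p,
            }
        )
    if design.sex_idx is not None:
        b = float(fit.beta[design.sex_idx])
        se = float(np.sqrt(V[design.sex_idx, design.sex_idx]))
        rows.append(
            {
                "feature": "male_vs_female", "sex": "contrast", "beta": b, "se": se,
                "ci_low": b - 1.96 * se, "ci_high": b + 1.96 * se, "edf": 1.0,
                "F": (b / se) ** 2 if se > 0 else 0.0, "df_num": 1, "df_den": df_den,
                "p": float(stats.f.sf((b / se) ** 2, 1, df_den)) if se > 0 else 1.0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["deviance_explained"] = fit.deviance_explained
    return out


@dataclass
class SelectionResult:
    selected: list[tuple[str, str]]  # (feature, sex) with p < alpha
    features: list[str]  # union of selected features
    n_selected: int
    fallback: bool = False


def select_predictors(fit: GammFit, alpha: float = 0.05, table: pd.DataFrame | None = None) -> SelectionResult:
    """(feature, sex) pairs significant at alpha; union of features downstream.

    Falls back to the full feature set with a warning when nothing is
    selected, so the pipeline never runs on an empty predictor set.
    """
    tt = term_table(fit, table=table)
    tt = tt[tt["sex"].isin(["male", "female", "all"])]
    sel = [
        (r.feature, r.sex)
        for r in tt.itertuples()
        if r.p < alpha
    ]
    feats = sorted({f for f, _ in sel})
    fallback = False
    if not sel:
        warnings.warn("no predictor significant; falling back to full feature set", stacklevel=2)
        feats = sorted({t.feature for t in fit.design.terms})
        fallback = True
    return SelectionResult(selected=sel, features=feats, n_selected=len(sel), fallback=fallback)


def partial_effect_curves(
    fit: GammFit, feature: str, sex: str, grid: np.ndarray
) -> pd.DataFrame:
    """Predicted probability along one feature, others at their means.

    The grid is on the raw feature scale; other smooths contribute their
    value at the stratum mean (z = 0), the caller intercept is 0.
    """
    design = fit.design
    target = None
    base = float(fit.beta[design.intercept_idx])
    if design.sex_idx is not None:
        male_center = float(np.mean(design.sex_values == "male"))
        base += float(fit.beta[design.sex_idx]) * ((1.0 if sex == "male" else 0.0) - male_center)
    for t in design.terms:
        if t.feature == feature and t.sex == sex:
            target = t
            continue
        if t.sex not in (sex, "all"):
            continue
        Bm = _basis(np.array([0.0]), t.knots) - t.center
        base += float((Bm @ fit.beta[t.sl])[0])
    if target is None:
        raise KeyError(f"no smooth for ({feature}, {sex}) in the model")
    z = (np.asarray(grid, dtype=float) - target.x_mean) / target.x_sd
    B = _basis(z, target.knots) - target.center
    eta = base + B @ fit.beta[target.sl]
    return pd.DataFrame({"x": np.asarray(grid, dtype=float), "prob": 1.0 / (1.0 + np.exp(-eta))})
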