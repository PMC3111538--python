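"""OLS, PGLS and RegOU regression with comparable maximum likelihoods.

All three model families are generalized least squares with different
residual covariance structures:

* OLS      -- ``V = I`` (the star-phylogeny assumption);
* PGLS     -- ``V`` = the Brownian-motion tree covariance (numerically
  equivalent to regression on phylogenetically independent contrasts);
* RegOU    -- ``V = V(d)``, a one-parameter Ornstein-Uhlenbeck family with
  ``d`` estimated by REML; ``d = 1`` recovers PGLS and ``d = 0`` OLS.

For a fixed covariance ``V`` the estimates are

    beta_hat   = (X' V^-1 X)^-1 X' V^-1 y
    sigma2_ML  = e' V^-1 e / n,              e = y - X beta_hat
    lnL_ML     = -(n/2) [ln(2 pi) + ln sigma2_ML + 1] - (1/2) ln|V|

so log-likelihoods share one constant convention and are directly comparable
across model families (with identical species sets).  The OU parameter is
estimated by restricted maximum likelihood,

    lnL_R(d) = -1/2 [ (n-p) ln sigma2_R(d) + ln|V(d)| + ln|X'V(d)^-1 X|
                      + (n-p)(1 + ln 2 pi) ],   sigma2_R = e'V^-1 e/(n-p)

and the reported likelihood is the ML value evaluated at ``d_hat``.  Slope
inference uses a t distribution with ``n - p`` degrees of freedom.

``r^2`` for GLS fits is the GLS-metric proportion of variance; it is not
directly comparable between phylogenetic and ordinary models and fit reports
carry a per-model-metric footnote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .data_io import AlignedDataset
from .phylo_core import Phylogeny, TipCovariance, bm_covariance, ou_from_bm

logger = logging.getLogger(__name__)

__all__ = [
    "GLSFit",
    "BalanceReport",
    "FitError",
    "fit_gls",
    "fit_ols",
    "fit_regou",
    "ancova_fit",
]

R2_FOOTNOTE = (
    "r2 is computed in each model's own (GLS) metric and is not directly "
    "comparable across phylogenetic and nonphylogenetic models"
)


class FitError(RuntimeError):
    """Numerical failure during fitting (singularity, non-convergence)."""


@dataclass
class GLSFit:
    """A fitted regression with comparable ML log-likelihood.

    ``p_regression`` is the two-sided t-test p-value of the first
    non-intercept coefficient (the slope); ``d_hat`` is set for RegOU only.
    """

    model: str
    beta: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r2: float
    lnL_ML: float
    sigma2_hat: float
    residuals: np.ndarray
    n: int
    p: int
    tips: list[str] | None = None
    coef_names: list[str] = field(default_factory=list)
    d_hat: float | None = None
    d_boundary: bool = False
    lnL_REML: float | None = None

    @property
    def slope(self) -> float | None:
        return float(self.beta[1]) if self.p >= 2 else None

    @property
    def t(self) -> float | None:
        return float(self.t_stats[1]) if self.p >= 2 else None

    @property
    def p_regression(self) -> float | None:
        return float(self.p_values[1]) if self.p >= 2 else None

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "coef_names": list(self.coef_names),
            "beta": list(map(float, self.beta)),
            "se": list(map(float, self.se)),
            "lnL_ML": self.lnL_ML,
            "n": self.n,
            "b": self.slope,
            "r2": self.r2,
            "d": self.d_hat,
            "p_regression": self.p_regression,
            "sigma2_hat": self.sigma2_hat,
            "r2_note": R2_FOOTNOTE,
        }


def _gls_core(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    model: str,
    tips: list[str] | None,
    coef_names: Sequence[str],
) -> GLSFit:
    n, p = X.shape
    if n <= p:
        raise FitError(f"need n > p (n={n}, p={p})")
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError("residual covariance is not positive definite") from exc
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Vinv_X = cho_solve(cho, X)
    Vinv_y = cho_solve(cho, y)
    XtVX = X.T @ Vinv_X
    try:
        beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
        XtVX_inv = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError as exc:
        raise FitError("X'V^-1X is singular (collinear design?)") from exc
    e = y - X @ beta
    sse = float(e @ cho_solve(cho, e))
    sigma2_ml = sse / n
    if sigma2_ml <= 0:
        sigma2_ml = np.finfo(float).tiny
    lnL = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2_ml) + 1.0) - 0.5 * logdetV
    sigma2_unb = sse / (n - p)
    se = np.sqrt(sigma2_unb * np.diag(XtVX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = beta / se
    p_values = 2.0 * t_dist.sf(np.abs(t_stats), df=n - p)
    # GLS-metric r2 around the GLS phylogenetic mean
    ones = np.ones(n)
    Vinv_1 = cho_solve(cho, ones)
    ybar = float(Vinv_1 @ y) / float(ones @ Vinv_1)
    dy = y - ybar
    tss = float(dy @ cho_solve(cho, dy))
    r2 = 0.0 if tss <= 0 else max(0.0, min(1.0, 1.0 - sse / tss))
    return GLSFit(
        model=model,
        beta=beta,
        se=se,
        t_stats=t_stats,
        p_values=p_values,
        r2=r2,
        lnL_ML=float(lnL),
        sigma2_hat=sigma2_ml,
        residuals=e,
        n=n,
        p=p,
        tips=list(tips) if tips is not None else None,
        coef_names=list(coef_names),
    )


def fit_gls(
    dataset: AlignedDataset,
    V: TipCovariance | None = None,
    model: str = "PGLS",
) -> GLSFit:
    """Generalized least squares under a fixed covariance.

    ``V`` defaults to the dataset's own covariance; pass an identity-valued
    covariance (or use :func:`fit_ols`) for ordinary least squares.
    """
    cov = dataset.V if V is None else V.reorder(dataset.tips)
    return _gls_core(
        dataset.y, dataset.X, cov.matrix, model, dataset.tips, dataset.var_names
    )


def fit_ols(dataset: AlignedDataset) -> GLSFit:
    """Ordinary least squares: GLS under the identity (star-phylogeny) covariance."""
    n = dataset.n
    return _gls_core(
        dataset.y,
        dataset.X,
        np.eye(n),
        "OLS",
        dataset.tips,
        dataset.var_names,
    )


# ---------------------------------------------------------------------------
# RegOU


def _reml_loglik(d: float, y, X, S, depths) -> float:
    n, p = X.shape
    V = ou_from_bm(S, depths, d)
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Vinv_X = cho_solve(cho, X)
    XtVX = X.T @ Vinv_X
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    try:
        beta = np.linalg.solve(XtVX, X.T @ cho_solve(cho, y))
    except np.linalg.LinAlgError:
        return -np.inf
    e = y - X @ beta
    sse = float(e @ cho_solve(cho, e))
    if sse <= 0:
        return -np.inf
    sigma2_r = sse / (n - p)
    return -0.5 * (
        (n - p) * np.log(sigma2_r)
        + logdetV
        + logdetXtVX
        + (n - p) * (1.0 + np.log(2 * np.pi))
    )


_REGOU_RESTARTS = (0.01, 1.0, 3.0)
_REGOU_TOL = 1e-6
_REGOU_GRID = 41


def fit_regou(
    dataset: AlignedDataset,
    tree: Phylogeny | None = None,
    d_bounds: tuple[float, float] = (0.0, 5.0),
    reml: bool = True,
    d_fixed: float | None = None,
) -> GLSFit:
    """GLS with the residual covariance an OU family, ``d`` estimated by REML.

    The profile (restricted) likelihood is maximized over ``d`` in
    ``d_bounds`` by a coarse grid plus bounded scalar refinement with
    restarts; ties resolve toward smaller ``d`` (parsimony toward OLS).  The
    reported ``lnL_ML`` is the ML log-likelihood evaluated at ``d_hat``, so
    it is directly comparable with OLS and PGLS fits.  Boundary solutions
    are flagged via ``d_boundary``.
    """
    lo, hi = d_bounds
    if d_fixed is None and (lo < 0 or hi <= lo):
        raise ValueError(f"invalid d_bounds {d_bounds}")
    if tree is not None:
        bm = bm_covariance(tree).reorder(dataset.tips)
        S, depths = bm.matrix, bm.depth
    else:
        # the dataset's covariance is taken as the BM base of the OU family
        S, depths = dataset.V.matrix, np.diag(dataset.V.matrix).copy()
    y, X = dataset.y, dataset.X

    objective = _reml_loglik if reml else (
        lambda d, y, X, S, depths: _gls_core(
            y, X, ou_from_bm(S, depths, d), "tmp", None, []
        ).lnL_ML
    )

    def f(d: float) -> float:
        val = float(objective(float(d), y, X, S, depths))
        # large finite penalty keeps the bounded optimizer's arithmetic clean
        return val if np.isfinite(val) else -1e300

    if d_fixed is not None:
        if d_fixed < 0:
            raise ValueError("d_fixed must be >= 0")
        V_fixed = ou_from_bm(S, depths, float(d_fixed))
        fit = _gls_core(y, X, V_fixed, "RegOU", dataset.tips, dataset.var_names)
        fit.d_hat = float(d_fixed)
        fit.d_boundary = d_fixed in (lo, hi)
        fit.lnL_REML = f(float(d_fixed)) if reml else None
        return fit

    candidates: list[tuple[float, float]] = []  # (d, lnL)
    grid = np.linspace(lo, hi, _REGOU_GRID)
    grid_vals = np.array([f(d) for d in grid])
    if not (grid_vals > -1e299).any():
        raise FitError("restricted likelihood not finite anywhere on the d grid")
    candidates.extend(zip(grid, grid_vals))

    # local refinement around the grid max and from fixed restarts
    starts = {float(grid[int(np.nanargmax(grid_vals))])}
    starts.update(s for s in _REGOU_RESTARTS if lo <= s <= hi)
    step = (hi - lo) / (_REGOU_GRID - 1)
    for s in starts:
        a, b = max(lo, s - 2 * step), min(hi, s + 2 * step)
        if b - a < 1e-12:
            continue
        res = minimize_scalar(
            lambda d: -f(d), bounds=(a, b), method="bounded",
            options={"xatol": _REGOU_TOL},
        )
        if res is not None and np.isfinite(res.fun):
            candidates.append((float(res.x), float(-res.fun)))
    candidates.append((lo, f(lo)))
    candidates.append((hi, f(hi)))

    best_lnl = max(v for _, v in candidates if v > -1e299)
    # ties resolved toward smaller d
    d_hat = min(d for d, v in candidates if v >= best_lnl - 1e-9)
    boundary = d_hat <= lo + 1e-6 or d_hat >= hi - 1e-6
    if boundary:
        logger.info("RegOU d_hat=%g at a bound of %s", d_hat, d_bounds)

    V_hat = ou_from_bm(S, depths, d_hat)
    fit = _gls_core(y, X, V_hat, "RegOU", dataset.tips, dataset.var_names)
    fit.d_hat = float(d_hat)
    fit.d_boundary = bool(boundary)
    fit.lnL_REML = f(d_hat) if reml else None
    return fit


# ---------------------------------------------------------------------------
# Phylogenetic ANCOVA


@dataclass
class BalanceReport:
    """Per-group counts for a two-group ANCOVA, with an imbalance warning."""

    counts: dict[str, int]
    imbalanced: bool
    fitted: bool
    note: str = ""

    @classmethod
    def from_groups(cls, groups: np.ndarray, fitted: bool) -> "BalanceReport":
        labels, counts = np.unique(groups, return_counts=True)
        mapping = {str(l): int(c) for l, c in zip(labels, counts)}
        imbalanced = min(mapping.values()) < 5
        note = ""
        if imbalanced:
            note = (
                f"highly unbalanced design (group sizes {mapping}); "
                "group contrasts are not trustworthy"
            )
        return cls(counts=mapping, imbalanced=imbalanced, fitted=fitted, note=note)


class AncovaDesignError(ValueError):
    """The grouping cannot support an ANCOVA fit (too few groups/members)."""

    def __init__(self, msg: str, report: BalanceReport | None = None):
        super().__init__(msg)
        self.report = report


def ancova_fit(
    dataset: AlignedDataset,
    V: TipCovariance | None = None,
    interaction: bool = False,
) -> tuple[GLSFit, BalanceReport]:
    """Two-group (phylogenetic) ANCOVA: intercept + x + group (+ x:group).

    The dataset must carry exactly two group labels and a single predictor
    column.  Groups with fewer than 2 members refuse to fit (counts are
    still reported via the raised error); group sizes below 5 trigger an
    imbalance warning in the returned :class:`BalanceReport`.
    """
    if dataset.group is None:
        raise AncovaDesignError("dataset has no group labels")
    labels = np.unique(dataset.group)
    if len(labels) != 2:
        raise AncovaDesignError(f"ANCOVA needs exactly 2 groups, got {list(labels)}")
    counts = {str(l): int(np.sum(dataset.group == l)) for l in labels}
    if min(counts.values()) < 2:
        report = BalanceReport(counts=counts, imbalanced=True, fitted=False,
                               note="a group has < 2 members; refusing to fit")
        raise AncovaDesignError(
            f"group with < 2 members (sizes {counts}); refusing to fit", report
        )
    if dataset.X.shape[1] != 2:
        raise AncovaDesignError("ANCOVA expects exactly one predictor column")
    x = dataset.X[:, 1]
    indicator = (dataset.group == labels[1]).astype(float)
    cols = [np.ones(dataset.n), x, indicator]
    names = ["intercept", dataset.var_names[1], f"group[{labels[1]}]"]
    if interaction:
        cols.append(x * indicator)
        names.append(f"{dataset.var_names[1]}:group[{labels[1]}]")
    X = np.column_stack(cols)
    cov = dataset.V if V is None else V.reorder(dataset.tips)
    fit = _gls_core(dataset.y, X, cov.matrix, "ANCOVA", dataset.tips, names)
    report = BalanceReport.from_groups(dataset.group, fitted=True)
    if report.imbalanced:
        logger.warning("%s", report.note)
    return fit, report
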