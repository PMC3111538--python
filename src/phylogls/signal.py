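"""Blomberg's K statistic and the MSE randomization test of phylogenetic signal.

K compares the observed ratio of the mean squared error of tip values around
the phylogenetic (GLS) mean in the ordinary metric (``MSE0``) versus the
phylogenetic metric (``MSE``) to the ratio expected under Brownian motion on
the candidate tree:

    K = (MSE0 / MSE) / E[MSE0 / MSE]_BM,
    E[MSE0 / MSE]_BM = [tr(V) - n / (1'V^-1 1)] / (n - 1).

K = 1 means relatives resemble each other exactly as much as Brownian motion
on the tree predicts; K near 0 means no signal; K > 1 stronger-than-BM
similarity.  Significance comes from a one-sided randomization test: tip
values are permuted across the tips and the observed phylogenetic-metric MSE
is compared with the permutation distribution (smaller MSE = stronger
signal).

The same machinery applies to regression residuals, which is the model-choice
criterion for phylogenetic versus ordinary regression: residual signal means
the phylogeny still matters after conditioning on the predictors.  Residuals
here are response-scale residuals ``y - X @ beta`` -- whitened residuals
would have their signal destroyed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data_io import AlignedDataset
from .phylo_core import Phylogeny, bm_covariance

if TYPE_CHECKING:  # pragma: no cover
    from .gls import GLSFit

__all__ = [
    "SignalResult",
    "DegenerateTraitError",
    "blomberg_k",
    "signal_test",
    "residual_signal",
]


class DegenerateTraitError(ValueError):
    """Trait is (numerically) constant: signal statistics are undefined."""


@dataclass
class SignalResult:
    """Blomberg's K with its ingredients and (optionally) a randomization P.

    Invariant: ``K == (mse0 / mse) / expected_ratio`` and, when a test was
    run, ``p_value >= 1 / (n_perm + 1)``.
    """

    K: float
    mse0: float
    mse: float
    expected_ratio: float
    p_value: float | None = None
    n_perm: int = 0

    def as_dict(self) -> dict:
        return {
            "K": self.K,
            "mse0": self.mse0,
            "mse": self.mse,
            "expected_ratio": self.expected_ratio,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
        }


def _signal_pieces(y: np.ndarray, V: np.ndarray):
    """GLS phylogenetic mean and the two MSE metrics for one trait vector."""
    n = len(y)
    cho = cho_factor(V, lower=True)
    ones = np.ones(n)
    Vinv_1 = cho_solve(cho, ones)
    denom = float(ones @ Vinv_1)
    a_hat = float(Vinv_1 @ y) / denom
    e = y - a_hat
    mse0 = float(e @ e) / (n - 1)
    mse = float(e @ cho_solve(cho, e)) / (n - 1)
    expected = (float(np.trace(V)) - n / denom) / (n - 1)
    return a_hat, mse0, mse, expected, cho, Vinv_1, denom


def blomberg_k(dataset: AlignedDataset) -> SignalResult:
    """Blomberg's K for a single trait against the dataset's covariance.

    The dataset must be intercept-only (the trait is ``y``; ``X`` is the
    all-ones column).  Constant traits are rejected.
    """
    if dataset.X.shape[1] != 1 or not np.allclose(dataset.X[:, 0], 1.0):
        raise ValueError("blomberg_k expects an intercept-only design")
    return _k_from_vector(dataset.y, dataset.V.matrix)


def _k_from_vector(y: np.ndarray, V: np.ndarray) -> SignalResult:
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0 or np.var(y) == 0:
        raise DegenerateTraitError("trait is constant; K is undefined")
    _, mse0, mse, expected, _, _, _ = _signal_pieces(y, V)
    if mse <= 0:
        raise DegenerateTraitError("phylogenetic-metric MSE is zero")
    return SignalResult(K=(mse0 / mse) / expected, mse0=mse0, mse=mse, expected_ratio=expected)


def _perm_mse(Y: np.ndarray, cho, Vinv_1: np.ndarray, denom: float) -> np.ndarray:
    """Phylogenetic-metric MSE for each column of ``Y`` (vectorized)."""
    n, m = Y.shape
    a_hat = (Vinv_1 @ Y) / denom            # (m,)
    E = Y - a_hat[None, :]
    M = cho_solve(cho, E)
    return np.einsum("ij,ij->j", E, M) / (n - 1)


def signal_test(
    dataset: AlignedDataset,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Randomization test of phylogenetic signal via the GLS-metric MSE.

    Tip values are permuted ``n_perm`` times; the one-sided add-one P is
    ``(1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1)``, so P is never zero and
    its smallest attainable value is ``1 / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful test")
    res = blomberg_k(dataset)
    y = dataset.y
    V = dataset.V.matrix
    n = len(y)
    _, _, mse_obs, _, cho, Vinv_1, denom = _signal_pieces(y, V)
    rng = np.random.default_rng(seed)
    # one permutation per column; argsort of uniforms is a uniform permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = y[order].T                           # (n, n_perm)
    mse_perm = _perm_mse(Y, cho, Vinv_1, denom)
    count = int(np.sum(mse_perm <= mse_obs))
    res.p_value = (1 + count) / (n_perm + 1)
    res.n_perm = n_perm
    return res


def residual_signal(
    fit: "GLSFit",
    tree: Phylogeny,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Signal test of a fit's response-scale residuals against a tree's BM covariance."""
    V = bm_covariance(tree)
    resid = np.asarray(fit.residuals, dtype=float)
    if fit.tips is not None:
        V = V.reorder(list(fit.tips))
    elif V.n != len(resid):
        raise ValueError("tree size does not match residual vector")
    ds = AlignedDataset(
        y=resid,
        X=np.ones((V.n, 1)),
        V=V,
        tips=list(V.tip_order),
        var_names=["intercept"],
    )
    return signal_test(ds, n_perm=n_perm, seed=seed)
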