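"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use explicit matrix inversion and textbook formulas
(never the package's solve paths) so they stay independent of the code they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

import phylogls as pg
from phylogls.data_io import AlignedDataset


@pytest.fixture
def three_tip() -> pg.Phylogeny:
    return pg.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced8() -> pg.Phylogeny:
    return pg.balanced_tree(8)


@pytest.fixture
def balanced64() -> pg.Phylogeny:
    return pg.balanced_tree(64)


def intercept_dataset(tree: pg.Phylogeny, y: np.ndarray) -> AlignedDataset:
    """Intercept-only dataset for signal statistics on a BM covariance."""
    V = pg.bm_covariance(tree)
    y = np.asarray(y, dtype=float)
    return AlignedDataset(
        y=y, X=np.ones((V.n, 1)), V=V, tips=list(V.tip_order),
        var_names=["intercept"],
    )


def regression_dataset(tree: pg.Phylogeny, x: np.ndarray, y: np.ndarray) -> AlignedDataset:
    V = pg.bm_covariance(tree)
    return AlignedDataset(
        y=np.asarray(y, float),
        X=np.column_stack([np.ones(V.n), np.asarray(x, float)]),
        V=V,
        tips=list(V.tip_order),
        var_names=["intercept", "x"],
    )


# ---------------------------------------------------------------------------
# independent oracles


def gls_oracle(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Textbook GLS by explicit inversion: beta, sigma2_ML, lnL_ML."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Vinv = np.linalg.inv(V)
    beta = np.linalg.inv(X.T @ Vinv @ X) @ (X.T @ Vinv @ y)
    e = y - X @ beta
    n = len(y)
    s2 = float(e @ Vinv @ e) / n
    lnL = -n / 2 * (np.log(2 * np.pi) + np.log(s2) + 1) - 0.5 * np.log(
        np.linalg.det(V)
    )
    return beta, s2, float(lnL)


def k_oracle(y: np.ndarray, V: np.ndarray) -> float:
    """Blomberg's K by explicit inversion of the four defining formulas."""
    y = np.asarray(y, float)
    n = len(y)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    a = (ones @ Vinv @ y) / (ones @ Vinv @ ones)
    e = y - a
    mse0 = (e @ e) / (n - 1)
    mse = (e @ Vinv @ e) / (n - 1)
    expected = (np.trace(V) - n / (ones @ Vinv @ ones)) / (n - 1)
    return float((mse0 / mse) / expected)


def pic_contrasts(tree: pg.Phylogeny, values: dict[str, float]) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts (binary trees)."""
    vals: dict[int, float] = {}
    bl: dict[int, float] = {}
    out = []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            vals[id(node)] = values[node.taxon.label]
            bl[id(node)] = float(node.edge.length)
            continue
        ch = node.child_nodes()
        assert len(ch) == 2, "PIC oracle needs a binary tree"
        v1, v2 = vals[id(ch[0])], vals[id(ch[1])]
        b1, b2 = bl[id(ch[0])], bl[id(ch[1])]
        out.append((v1 - v2) / np.sqrt(b1 + b2))
        vals[id(node)] = (v1 / b1 + v2 / b2) / (1 / b1 + 1 / b2)
        edge = 0.0
        if node is not tree.tree.seed_node and node.edge.length is not None:
            edge = float(node.edge.length)
        bl[id(node)] = edge + b1 * b2 / (b1 + b2)
    return np.asarray(out)


def pic_slope(tree: pg.Phylogeny, x: dict[str, float], y: dict[str, float]) -> float:
    """Regression-through-origin slope of y-contrasts on x-contrasts."""
    cx = pic_contrasts(tree, x)
    cy = pic_contrasts(tree, y)
    return float((cx @ cy) / (cx @ cx))
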