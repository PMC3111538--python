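"""Model comparison across the topology x branch-length x model grid.

A comparative regression is only as good as its assumed tree, so the fits are
repeated over alternative topologies and branch-length schemes and ranked by
their ML log-likelihoods (computed under one shared constant convention, so
they are comparable across OLS / PGLS / RegOU on the same species set).

RegOU nests OLS at ``d = 0`` and is compared to it with a likelihood-ratio
test on 1 df.  The plain chi-square reference is conservative when the true
``d`` sits on the boundary at zero; that convention is documented and kept.
PGLS and OLS are non-nested (different fixed covariances) and are compared by
raw log-likelihood only, without a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .data_io import AlignedDataset, TraitTable, align
from .gls import GLSFit, fit_gls, fit_ols, fit_regou
from .phylo_core import Phylogeny

__all__ = ["ComparisonGrid", "GridRow", "lr_test", "run_grid", "select_best"]

#: parameters estimated beyond the coefficients: sigma^2 (all), d (RegOU)
_EXTRA_PARAMS = {"OLS": 1, "PGLS": 1, "RegOU": 2}
_MODEL_PREF = {"OLS": 0, "PGLS": 1, "RegOU": 2}  # tie-break: simpler first


def lr_test(lnL_full: float, lnL_null: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value for 2*(lnL_full - lnL_null) on ``df``.

    The models must be nested: a full-model likelihood more than slightly
    below the null signals a fitting bug and raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if lnL_full < lnL_null - 1e-8:
        raise ValueError(
            f"nesting violated: lnL_full={lnL_full} < lnL_null={lnL_null}"
        )
    stat = max(0.0, 2.0 * (lnL_full - lnL_null))
    return float(chi2.sf(stat, df))


@dataclass
class GridRow:
    topology: str
    scheme: str
    model: str
    fit: GLSFit | None
    error: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def lnL(self) -> float:
        return -np.inf if self.fit is None else self.fit.lnL_ML

    def as_dict(self) -> dict:
        base = {
            "topology": self.topology,
            "scheme": self.scheme,
            "model": self.model,
            "flags": list(self.flags),
            "error": self.error,
        }
        if self.fit is not None:
            base.update(
                {
                    "lnL_ML": self.fit.lnL_ML,
                    "N": self.fit.n,
                    "b": self.fit.slope,
                    "r2": self.fit.r2,
                    "d": self.fit.d_hat,
                    "p_regression": self.fit.p_regression,
                }
            )
        return base


@dataclass
class ComparisonGrid:
    """All fitted cells on one species set, ranked by ML log-likelihood."""

    rows: list[GridRow]
    species: list[str]
    alpha: float = 0.05

    def ranking(self) -> list[GridRow]:
        return sorted(
            self.rows,
            key=lambda r: (
                -r.lnL,
                _EXTRA_PARAMS.get(r.model, 9),
                _MODEL_PREF.get(r.model, 9),
                r.topology,
                r.scheme,
            ),
        )

    def to_records(self) -> list[dict]:
        return [r.as_dict() for r in self.ranking()]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.to_records())


def run_grid(
    table: TraitTable,
    response: str,
    predictor: str,
    trees: Mapping[tuple[str, str], Phylogeny],
    models: Sequence[str] = ("ols", "pgls", "regou"),
    log10: Sequence[str] = (),
    d_bounds: tuple[float, float] = (0.0, 5.0),
    alpha: float = 0.05,
) -> ComparisonGrid:
    """Fit every (topology, scheme) x model cell on one shared species set.

    ``trees`` maps ``(topology_id, scheme_id)`` to an already-lengthed
    phylogeny; all trees must cover the dataset's species.  OLS is fitted
    once (it is topology-independent).  Cell failures are recorded in the
    grid rather than aborting it.  RegOU rows get a ``*`` flag when the LR
    test against OLS is significant at ``alpha``, and a ``d_boundary`` flag
    when ``d_hat`` sits at a bound.
    """
    if not trees:
        raise ValueError("need at least one (topology, scheme) tree")
    models = [m.lower() for m in models]

    # shared complete-case species set across all trees
    datasets: dict[tuple[str, str], AlignedDataset] = {}
    common: set[str] | None = None
    for key, tree in trees.items():
        ds = align(tree, table, response, [predictor], log10=log10)
        datasets[key] = ds
        common = set(ds.tips) if common is None else common & set(ds.tips)
    assert common is not None
    for key, tree in trees.items():
        if set(datasets[key].tips) != common:
            datasets[key] = align(
                tree.prune_to(common), table, response, [predictor], log10=log10
            )

    rows: list[GridRow] = []
    any_ds = next(iter(datasets.values()))
    ols_fit: GLSFit | None = None
    if "ols" in models:
        try:
            ols_fit = fit_ols(any_ds)
            rows.append(GridRow("--", "--", "OLS", ols_fit))
        except Exception as exc:  # keep the grid even if a cell fails
            rows.append(GridRow("--", "--", "OLS", None, error=str(exc)))
    elif "regou" in models:
        # LR reference is still OLS even when its row is not requested
        ols_fit = fit_ols(any_ds)

    for (topo, scheme), ds in datasets.items():
        if "pgls" in models:
            try:
                rows.append(GridRow(topo, scheme, "PGLS", fit_gls(ds)))
            except Exception as exc:
                rows.append(GridRow(topo, scheme, "PGLS", None, error=str(exc)))
        if "regou" in models:
            try:
                fit = fit_regou(ds, tree=trees[(topo, scheme)], d_bounds=d_bounds)
                flags = []
                if ols_fit is not None and fit.lnL_ML >= ols_fit.lnL_ML - 1e-8:
                    if lr_test(fit.lnL_ML, ols_fit.lnL_ML, df=1) < alpha:
                        flags.append("*")
                if fit.d_boundary:
                    flags.append("d_boundary")
                rows.append(GridRow(topo, scheme, "RegOU", fit, flags=flags))
            except Exception as exc:
                rows.append(GridRow(topo, scheme, "RegOU", None, error=str(exc)))

    return ComparisonGrid(rows=rows, species=sorted(common), alpha=alpha)


def select_best(grid: ComparisonGrid) -> tuple[GridRow, dict]:
    """Highest-lnL row plus a rationale record.

    Ties break toward fewer estimated parameters, then toward PGLS over
    RegOU (the ranking key encodes both), deterministically.
    """
    ranked = [r for r in grid.ranking() if r.fit is not None]
    if not ranked:
        raise ValueError("grid has no successful fits")
    best = ranked[0]
    runner = ranked[1] if len(ranked) > 1 else None
    rationale = {
        "selected": {
            "topology": best.topology,
            "scheme": best.scheme,
            "model": best.model,
            "lnL_ML": best.lnL,
        },
        "margin_lnL": None if runner is None else best.lnL - runner.lnL,
        "tie_break": (
            runner is not None and abs(best.lnL - runner.lnL) <= 1e-9
        ),
        "rule": "max lnL; ties -> fewer parameters, then PGLS over RegOU",
    }
    return best, rationale
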