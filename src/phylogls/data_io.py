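"""Trait-table reading, tree/table alignment, and population-genetic utilities.

Cross-species analyses need the trait table and the phylogeny reduced to a
common, complete-case species set before a covariance matrix is built.  The
:func:`align` routine does that reduction explicitly (never imputing), applies
the conventional log10 transforms, and returns an analysis-ready dataset whose
row order matches the covariance's tip order exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phylo_core import (
    OUParameter,
    Phylogeny,
    TipCovariance,
    bm_covariance,
    ou_covariance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "AlignedDataset",
    "AlignmentSummary",
    "DataValidationError",
    "AlignmentError",
    "read_trait_table",
    "align",
    "ne_from_heterozygosity",
    "export_dataset",
]

#: canonical trait columns of the genome-architecture dataset this package
#: was built around; arbitrary numeric columns are equally accepted
CANONICAL_TRAITS = (
    "ne_u",                 # N_e * u, dimensionless (often estimated by pi_s)
    "genome_size_mb",       # megabases
    "gene_number",          # count
    "duplicate_half_life",  # time units
    "intron_size",          # bp
    "intron_number",        # count
    "transposon_number",    # count
    "transposon_fraction",  # fraction of genome, in [0, 1]
)


class DataValidationError(ValueError):
    """A trait table violates an invariant (duplicates, ranges, columns)."""


class AlignmentError(ValueError):
    """Tree/table alignment cannot produce a usable dataset."""


@dataclass
class TraitTable:
    """A species x trait table with an explicit species column.

    Species labels are unique (after trimming outer whitespace); missing
    values are explicit NaN; any transposon-fraction column is bounded to
    [0, 1].
    """

    df: pd.DataFrame
    species_col: str = "species"
    group_col: str | None = None

    def __post_init__(self) -> None:
        if self.species_col not in self.df.columns:
            raise DataValidationError(
                f"species column {self.species_col!r} not in table "
                f"(columns: {list(self.df.columns)})"
            )
        self.df = self.df.copy()
        self.df[self.species_col] = self.df[self.species_col].astype(str).str.strip()
        dupes = self.df[self.species_col][self.df[self.species_col].duplicated()]
        if len(dupes):
            raise DataValidationError(
                f"duplicate species in table: {sorted(set(dupes))}"
            )
        if "transposon_fraction" in self.df.columns:
            frac = pd.to_numeric(self.df["transposon_fraction"], errors="coerce")
            bad = self.df[self.species_col][(frac < 0) | (frac > 1)]
            if len(bad):
                raise DataValidationError(
                    f"transposon_fraction outside [0, 1] for: {list(bad)}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.df[self.species_col])

    @property
    def trait_names(self) -> list[str]:
        skip = {self.species_col, self.group_col}
        return [
            c
            for c in self.df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.df[c])
        ]

    def subset(self, query: str) -> "TraitTable":
        """Row subset via a pandas query expression (e.g. ``group == 'bacteria'``)."""
        return TraitTable(
            self.df.query(query), species_col=self.species_col, group_col=self.group_col
        )


@dataclass
class AlignmentSummary:
    """Species bookkeeping from an alignment: nothing is dropped silently."""

    used: list[str]
    tree_only: list[str]
    table_only: list[str]
    incomplete: list[str]

    def __str__(self) -> str:
        return (
            f"{len(self.used)} species used; "
            f"{len(self.tree_only)} tree-only, {len(self.table_only)} table-only, "
            f"{len(self.incomplete)} dropped for missing values"
        )


@dataclass
class AlignedDataset:
    """Response, design matrix, covariance and tips, jointly complete-case.

    ``X`` always carries an intercept column first; ``V.tip_order``, ``tips``
    and the row order of ``y``/``X`` coincide.
    """

    y: np.ndarray
    X: np.ndarray
    V: TipCovariance
    tips: list[str]
    var_names: list[str] = field(default_factory=list)
    group: np.ndarray | None = None
    summary: AlignmentSummary | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.tips)
        if self.y.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("y/X row count does not match tips")
        if self.V.tip_order != list(self.tips):
            raise ValueError("covariance tip_order does not match dataset tips")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("aligned dataset must be complete-case")
        if n < 3:
            raise AlignmentError(f"need >= 3 complete cases, have {n}")

    @property
    def n(self) -> int:
        return len(self.tips)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def with_covariance(self, V: TipCovariance) -> "AlignedDataset":
        """Same data under a different covariance (tip orders must agree)."""
        return AlignedDataset(
            y=self.y,
            X=self.X,
            V=V.reorder(self.tips),
            tips=list(self.tips),
            var_names=list(self.var_names),
            group=None if self.group is None else self.group.copy(),
            summary=self.summary,
        )


def read_trait_table(
    path,
    dialect: str | None = None,
    species_col: str = "species",
    group_col: str | None = None,
) -> TraitTable:
    """Read a delimited species x trait table.

    ``dialect`` is ``"csv"``, ``"tsv"`` or None (sniffed).  Non-numeric cells
    in trait columns become explicit missing values with a logged warning.
    """
    sep = {"csv": ",", "tsv": "\t", None: None}[dialect]
    df = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    for col in df.columns:
        if col in (species_col, group_col):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            logger.warning(
                "column %r: %d unparseable value(s) set to missing", col, int(bad.sum())
            )
        df[col] = coerced
    return TraitTable(df, species_col=species_col, group_col=group_col)


def align(
    tree: Phylogeny,
    table: TraitTable,
    response: str,
    predictors: Sequence[str] = (),
    log10: Iterable[str] = (),
    cov_model: "str | tuple[str, float] | OUParameter" = "bm",
    group: str | None = None,
) -> AlignedDataset:
    """Join a tree and trait table into an analysis-ready dataset.

    Species present in both inputs with complete cases for the chosen
    variables are kept; the tree is pruned to them before covariance
    construction.  ``log10`` names the variables to log10-transform (values
    must be strictly positive).  ``cov_model`` is ``"bm"`` or ``("ou", d)``.
    """
    variables = [response, *predictors]
    for v in variables:
        if v not in table.df.columns:
            raise DataValidationError(f"variable {v!r} not in trait table")
    log10 = set(log10)
    unknown = log10 - set(variables)
    if unknown:
        raise DataValidationError(f"log10 flag for unknown variable(s): {sorted(unknown)}")

    df = table.df.set_index(table.species_col)
    tree_tips = set(tree.tip_labels)
    table_species = set(df.index)
    common = tree_tips & table_species
    needed = list(variables) + ([group] if group else [])
    sub = df.loc[sorted(common), needed]
    complete = sub.dropna()
    summary = AlignmentSummary(
        used=list(complete.index),
        tree_only=sorted(tree_tips - table_species),
        table_only=sorted(table_species - tree_tips),
        incomplete=sorted(common - set(complete.index)),
    )
    logger.info("alignment: %s", summary)
    if len(complete) < 3:
        raise AlignmentError(
            f"only {len(complete)} complete cases for {variables}; need >= 3 "
            f"({summary})"
        )

    for v in log10:
        nonpos = complete.index[complete[v] <= 0]
        if len(nonpos):
            raise DataValidationError(
                f"log10 of non-positive {v!r} for species: {list(nonpos)}"
            )

    pruned = tree.prune_to(complete.index)
    if isinstance(cov_model, OUParameter):
        cov_model = ("ou", cov_model.d)
    if cov_model == "bm":
        V = bm_covariance(pruned)
    elif isinstance(cov_model, tuple) and cov_model[0] == "ou":
        V = ou_covariance(pruned, float(cov_model[1]))
    else:
        raise ValueError(f"unknown covariance model {cov_model!r}")

    ordered = complete.loc[V.tip_order]

    def column(v: str) -> np.ndarray:
        x = ordered[v].to_numpy(dtype=float)
        return np.log10(x) if v in log10 else x

    y = column(response)
    Xcols = [np.ones(len(ordered))] + [column(v) for v in predictors]
    X = np.column_stack(Xcols)
    return AlignedDataset(
        y=y,
        X=X,
        V=V,
        tips=list(V.tip_order),
        var_names=["intercept", *predictors],
        group=ordered[group].to_numpy() if group else None,
        summary=summary,
    )


def ne_from_heterozygosity(H, u: float = 1e-5):
    """Effective population size from expected heterozygosity.

    Under mutation-drift equilibrium at a locus with stepwise-like dynamics,
    ``N_e = ((1 - H)^-2 - 1) / (8 u)``.  Strictly increasing in ``H`` on
    [0, 1); with constant ``u`` the ranking of species by ``N_e`` equals the
    ranking by ``N_e * u``.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0) or np.any(H >= 1):
        raise ValueError("heterozygosity H must lie in [0, 1)")
    if u <= 0:
        raise ValueError("mutation rate u must be positive")
    out = ((1.0 - H) ** -2 - 1.0) / (8.0 * u)
    return float(out) if out.ndim == 0 else out


def export_dataset(dataset: AlignedDataset, tree: Phylogeny, out_dir, stem: str = "dataset") -> dict:
    """Write a dataset as a CSV + Newick pair (the same pair :func:`align` consumes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = {"species": dataset.tips, "response": dataset.y}
    for j, name in enumerate(dataset.var_names):
        if name == "intercept":
            continue
        cols[name] = dataset.X[:, j]
    if dataset.group is not None:
        cols["group"] = dataset.group
    csv_path = out_dir / f"{stem}.csv"
    nwk_path = out_dir / f"{stem}.nwk"
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    nwk_path.write_text(tree.to_newick() + "\n")
    return {"csv": str(csv_path), "newick": str(nwk_path)}
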