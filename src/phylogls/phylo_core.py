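"""Tree representation, Newick I/O, branch-length schemes, and tip covariance matrices.

A rooted phylogeny with branch lengths implies a variance-covariance matrix
among tip states under Brownian-motion (BM) trait evolution: the covariance of
two tips equals the root-to-MRCA path length they share, and each tip's
variance equals its root-to-tip depth.  A star phylogeny (one polytomy, equal
depths) yields a matrix proportional to the identity -- the structure that
ordinary least squares implicitly assumes.

The one-parameter Ornstein-Uhlenbeck (OU) family interpolates between those
two extremes.  With tip depths ``t_i`` and shared depths ``s_ij`` the
covariance is parameterized by ``d = exp(-2*alpha)``::

    V_ij(d) = d ** ((t_i + t_j)/2 - s_ij) * (1 - d**s_ij) / (1 - d)

with analytic limits ``V(1) = BM covariance`` and ``V(0) = identity``.  Values
``d > 1`` make relatives *more* similar than BM predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TipCovariance",
    "OUParameter",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "apply_branch_scheme",
    "bm_covariance",
    "ou_covariance",
    "star_tree",
]

#: additive diagonal jitter allowed when repairing near-PSD matrices,
#: as a fraction of mean(diag)
_PSD_JITTER_FRAC = 1e-10
_SYM_TOL = 1e-10


class NewickError(ValueError):
    """Malformed Newick input (syntax, duplicate labels, negative lengths)."""


class TreeValidationError(ValueError):
    """A tree violates a structural invariant (lengths, labels, schemes)."""


@dataclass(frozen=True)
class OUParameter:
    """Dimensionless OU restraining-force parameter ``d = exp(-2*alpha)``.

    ``d = 1`` recovers Brownian motion, ``d = 0`` the star-phylogeny
    (identity) structure; ``d > 1`` means relatives are more similar than
    under BM.
    """

    d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.d) or self.d < 0:
            raise ValueError(f"OU parameter d must be finite and >= 0, got {self.d}")


class Phylogeny:
    """A rooted phylogeny with labelled tips, backed by a dendropy tree.

    Tip order is the stable left-to-right leaf order of the underlying tree
    and is the canonical row/column order for covariance matrices built from
    it.  Polytomies are allowed; branch lengths may be absent until a
    branch-length scheme is applied.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_labels()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- basic accessors ---------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def _validate_labels(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not (leaf.taxon.label or "").strip():
                raise NewickError("tree contains an unlabelled tip")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")

    def has_lengths(self) -> bool:
        return all(
            node.edge.length is not None
            for node in self._tree.preorder_node_iter()
            if node is not self._tree.seed_node
        )

    def _require_lengths(self) -> None:
        missing = [
            _clade_id(node)
            for node in self._tree.preorder_node_iter()
            if node is not self._tree.seed_node and node.edge.length is None
        ]
        if missing:
            raise TreeValidationError(
                f"tree has edges without branch lengths: {missing[:5]}"
            )
        bad = [
            (_clade_id(node), node.edge.length)
            for node in self._tree.preorder_node_iter()
            if node is not self._tree.seed_node and node.edge.length <= 0
        ]
        if bad:
            raise TreeValidationError(f"non-positive branch lengths: {bad[:5]}")

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, aligned to :attr:`tip_labels`."""
        self._require_lengths()
        depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        out = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        for leaf in self._tree.leaf_node_iter():
            out.append(depth[id(leaf)])
        return np.asarray(out, dtype=float)

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        depths = self.tip_depths()
        scale = max(depths.max(), 1.0)
        return bool(np.ptp(depths) <= rel_tol * scale)

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a copy restricted to the given tip labels (order-free)."""
        keep = set(labels)
        have = set(self.tip_labels)
        missing = keep - have
        if missing:
            raise TreeValidationError(f"labels not in tree: {sorted(missing)}")
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        return Phylogeny(sub)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Phylogeny(n_tips={self.n_tips})"


@dataclass
class TipCovariance:
    """An ``n x n`` phylogenetic variance-covariance matrix with explicit tip order.

    ``depth`` carries the per-tip root-to-tip path length of the generating
    tree (equal to the diagonal for BM, but not for OU transforms).
    """

    matrix: np.ndarray
    tip_order: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = len(self.tip_order)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} tips"
            )
        asym = np.abs(self.matrix - self.matrix.T).max() if n else 0.0
        scale = max(float(np.abs(self.matrix).max()), 1.0)
        if asym > _SYM_TOL * scale:
            raise ValueError(f"covariance not symmetric (max asymmetry {asym:g})")
        self.matrix = (self.matrix + self.matrix.T) / 2.0
        self._repair_psd()

    def _repair_psd(self) -> None:
        n = len(self.tip_order)
        if n == 0:
            return
        min_eig = float(np.linalg.eigvalsh(self.matrix)[0])
        if min_eig >= 0:
            return
        jitter = _PSD_JITTER_FRAC * float(np.mean(np.diag(self.matrix)))
        if -min_eig <= jitter:
            logger.info("adding diagonal jitter %g to repair PSD", -min_eig)
            self.matrix = self.matrix + (-min_eig) * np.eye(n)
        else:
            raise ValueError(
                f"covariance matrix not positive semi-definite (min eig {min_eig:g})"
            )

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def reorder(self, new_order: Sequence[str]) -> "TipCovariance":
        """Return a copy with rows/columns permuted to ``new_order``."""
        if sorted(new_order) != sorted(self.tip_order):
            raise ValueError("new_order must be a permutation of tip_order")
        idx = [self.tip_order.index(label) for label in new_order]
        return TipCovariance(
            matrix=self.matrix[np.ix_(idx, idx)],
            tip_order=list(new_order),
            depth=self.depth[idx],
        )


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are optional (a scheme may fill them later).  Duplicate or
    empty tip labels and negative branch lengths are rejected.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is not None and node.edge.length < 0:
            raise NewickError(
                f"negative branch length {node.edge.length} on edge to "
                f"{_clade_id(node)!r}"
            )
    phy = Phylogeny(tree)
    if phy.n_tips < 2:
        raise NewickError("tree must have at least 2 tips")
    return phy


def write_newick(tree: Phylogeny) -> str:
    """Serialize to strict Newick (labels, ':'-lengths where set, ';')."""
    s = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip() + ("" if s.strip().endswith(";") else ";")


# ---------------------------------------------------------------------------
# Branch-length schemes


def _clade_id(node: dendropy.Node) -> str:
    """Stable identifier for the edge above ``node``: sorted tips of its clade."""
    if node.is_leaf():
        return node.taxon.label
    return ",".join(sorted(l.taxon.label for l in node.leaf_iter()))


def apply_branch_scheme(
    tree: Phylogeny,
    scheme: str,
    lengths: "Mapping[str, float] | Phylogeny | None" = None,
) -> Phylogeny:
    """Return a copy of ``tree`` with branch lengths set by a scheme.

    Parameters
    ----------
    scheme
        ``"all_one"`` sets every edge length to exactly 1 (the arbitrary
        "all = 1" convention).  ``"from_file"`` takes lengths from
        ``lengths``: either a mapping of clade identifier (comma-joined
        sorted tip labels; a bare tip label for terminal edges) to length,
        or a fully lengthed :class:`Phylogeny` of identical topology.
    """
    out = tree.copy()
    nodes = [
        n for n in out.tree.preorder_node_iter() if n is not out.tree.seed_node
    ]
    if scheme == "all_one":
        for node in nodes:
            node.edge.length = 1.0
    elif scheme == "from_file":
        if lengths is None:
            raise TreeValidationError("scheme 'from_file' requires a length source")
        if isinstance(lengths, Phylogeny):
            lengths._require_lengths()
            table = {
                _clade_id(n): n.edge.length
                for n in lengths.tree.preorder_node_iter()
                if n is not lengths.tree.seed_node
            }
        else:
            table = dict(lengths)
        for node in nodes:
            cid = _clade_id(node)
            if cid not in table:
                raise TreeValidationError(
                    f"length table missing edge for clade {cid!r}"
                )
            val = float(table[cid])
            if not np.isfinite(val) or val <= 0:
                raise TreeValidationError(
                    f"non-positive length {val} supplied for clade {cid!r}"
                )
            node.edge.length = val
    else:
        raise ValueError(f"unknown branch-length scheme {scheme!r}")
    out._require_lengths()
    return out


def read_edge_length_table(path) -> dict[str, float]:
    """Read a two-column delimited file (clade identifier, length)."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) != 2:
                raise TreeValidationError(
                    f"{path}:{lineno}: expected 'clade length', got {line!r}"
                )
            table[parts[0]] = float(parts[1])
    return table


# ---------------------------------------------------------------------------
# Covariance construction


def bm_covariance(tree: Phylogeny) -> TipCovariance:
    """Brownian-motion tip covariance: V_ij = shared root-to-MRCA path length."""
    tree._require_lengths()
    labels = tree.tip_labels
    n = len(labels)
    index = {id(leaf): i for i, leaf in enumerate(tree.tree.leaf_node_iter())}

    depth: dict[int, float] = {id(tree.tree.seed_node): 0.0}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    V = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        h = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                V[np.ix_(ia, ib)] = h
                V[np.ix_(ib, ia)] = h
        tipsets[id(node)] = [i for s in child_sets for i in s]
    depths = np.array([depth[id(leaf)] for leaf in tree.tree.leaf_node_iter()])
    return TipCovariance(matrix=V, tip_order=labels, depth=depths)


def ou_from_bm(S: np.ndarray, depths: np.ndarray, d: float) -> np.ndarray:
    """OU-family covariance from a BM covariance ``S`` and tip depths.

    ``S`` must be the BM matrix (``S_ij`` = shared depth, ``S_ii`` = tip
    depth).  Uses expm1/log for numerical stability near ``d = 1``.
    """
    if d < 0:
        raise ValueError(f"OU parameter d must be >= 0, got {d}")
    if d == 0.0:
        return np.eye(S.shape[0])
    if abs(d - 1.0) < 1e-12:
        return S.copy()
    t_half = np.add.outer(depths, depths) / 2.0
    logd = np.log(d)
    # (1 - d**s) / (1 - d), stable for d near 1
    ratio = np.expm1(S * logd) / np.expm1(logd)
    return np.exp((t_half - S) * logd) * ratio


def ou_covariance(tree: Phylogeny, d: "float | OUParameter") -> TipCovariance:
    """One-parameter OU tip covariance; d=1 gives BM, d=0 the identity."""
    if isinstance(d, OUParameter):
        d = d.d
    if d < 0:
        raise ValueError(f"OU parameter d must be >= 0, got {d}")
    bm = bm_covariance(tree)
    if not tree.is_ultrametric():
        logger.warning(
            "OU covariance on a non-ultrametric tree: the d=0 limit is only "
            "identity-structured up to diagonal scale"
        )
    V = ou_from_bm(bm.matrix, bm.depth, float(d))
    return TipCovariance(matrix=V, tip_order=bm.tip_order, depth=bm.depth)


def star_tree(labels: Sequence[str], depth: float = 1.0) -> Phylogeny:
    """Single polytomy with all tips at the same depth.

    Its BM covariance is ``depth * I`` -- the structure ordinary least
    squares assumes.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("star tree needs at least 2 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in star tree")
    if depth <= 0:
        raise ValueError("depth must be positive")
    newick = "(" + ",".join(f"{l}:{depth!r}" for l in labels) + ");"
    return parse_newick(newick)
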