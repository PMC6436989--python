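"""Neighbor-joining trees and Robinson-Foulds comparisons.

Neighbor joining is implemented in the classic Saitou-Nei form with the
Studier-Keppler Q-criterion; on an additive distance matrix it recovers the
generating tree exactly, branch lengths included.  Trees are handled as
unrooted (serialized with a trifurcating root).  Tree comparison uses the
Robinson-Foulds symmetric difference of non-trivial bipartitions; for two
binary trees on n shared leaves the maximum is 2n - 6, which normalizes RF
to the *relative* RF in [0, 1].
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .distances import DistanceMatrix

__all__ = [
    "PhyloTree",
    "TreeComparison",
    "neighbor_joining",
    "parse_newick",
    "rf_distance",
    "relative_rf",
    "round_half_up",
]


@dataclass
class PhyloTree:
    """An unrooted phylogenetic tree with branch lengths (wraps dendropy)."""

    tree: dendropy.Tree

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def __str__(self) -> str:
        return self.newick()


def parse_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick tree from a string or file path."""
    if isinstance(source, Path):
        text = source.read_text()
    elif "(" in source:  # newick data, possibly with a [&U]/[&R] prefix
        text = source
    else:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises reader-specific error types
        raise ValueError(f"malformed Newick input: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in Newick tree")
    tree.is_rooted = False
    return PhyloTree(tree)


class _NJNode:
    __slots__ = ("newick", "tag")

    def __init__(self, newick: str, tag: str) -> None:
        self.newick = newick  # subtree serialization without trailing length
        self.tag = tag  # smallest leaf label, for deterministic tie-breaks


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; ties are broken
    by the lexicographically smallest joined pair (each cluster keyed by its
    smallest leaf label).  Negative branch lengths are kept unless
    ``clamp_negative``; NJ can produce them on non-additive input.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes = [_NJNode(name, name) for name in dm.names]

    def edge(child: _NJNode, length: float) -> str:
        if clamp_negative:
            length = max(length, 0.0)
        return f"{child.newick}:{_fmt_len(length)}"

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i, j in zip(*np.nonzero(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))):
            if i >= j:
                continue
            tag = tuple(sorted((nodes[i].tag, nodes[j].tag)))
            if best is None or tag < best:
                best, bi, bj = tag, int(i), int(j)
        i, j = bi, bj
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        merged = _NJNode(
            f"({edge(nodes[i], li)},{edge(nodes[j], lj)})",
            min(nodes[i].tag, nodes[j].tag),
        )
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [merged]

    # final trifurcation
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    newick = f"({edge(a, la)},{edge(b, lb)},{edge(c, lc)});"
    return parse_newick(newick)


@dataclass(frozen=True)
class TreeComparison:
    """Robinson-Foulds comparison of two trees on the same leaf set."""

    n: int
    rf: int
    max_rf: int
    relative_rf: float


def relative_rf(rf: float, n: int) -> float:
    """Relative RF distance: rf / (2n - 6)."""
    if n < 4:
        raise ValueError("relative RF needs at least 4 taxa")
    return rf / (2 * n - 6)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the usual table-rendering convention,
    unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> TreeComparison:
    """Robinson-Foulds distance between two trees with identical leaf sets.

    ``rf`` counts the symmetric difference of non-trivial bipartitions;
    polytomies are compared as-is, without resolving them.
    """
    if t1.leaf_names != t2.leaf_names:
        raise ValueError("trees must share an identical leaf set")
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=ns, preserve_underscores=True)
    b = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=ns, preserve_underscores=True)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(a, b))
    n = len(t1.leaf_names)
    max_rf = 2 * n - 6
    return TreeComparison(n=n, rf=rf, max_rf=max_rf, relative_rf=rf / max_rf if max_rf > 0 else 0.0)
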