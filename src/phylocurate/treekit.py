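"""Newick handling, bipartition algebra and congruence/convergence diagnostics.

Trees are ``dendropy.Tree`` objects throughout.  All split operations treat
trees as unrooted: the root edge is collapsed, and a bipartition is
canonicalized as the side *not* containing a fixed reference terminal (the
lexicographically smallest label), so a split and its complement compare and
hash equal.

Support values are read from internal-node labels (the common IQ-TREE /
RAxML dialect) or, failing that, from a bare number or ``support=x`` token in
a branch comment.  Values greater than 1 are taken to be percentages and
divided by 100, so bootstrap percents and posterior proportions land on a
common [0, 1] scale.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

Tree = dendropy.Tree

#: Marker used in split-support TSV output for splits absent from an analysis.
ABSENT = "NA"

_SUPPORT_COMMENT = re.compile(r"(?:support\s*=\s*)?([0-9]*\.?[0-9]+)\s*$")


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree; underscores in labels are preserved."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate terminal labels: {dupes}")
    return tree


def write_newick(tree: Tree) -> str:
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"


def read_tree(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def read_tree_list(path: str | Path) -> list[Tree]:
    """Read a multi-tree Newick file, one tree per line (MCMC treelist style)."""
    trees = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            trees.append(parse_newick(line))
    return trees


def write_tree_list(trees: Iterable[Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t))


def terminal_labels(tree: Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Bipartitions


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of the taxon set, canonicalized for hashing.

    ``side`` is whichever of the two complementary sets does not contain the
    reference terminal (the smallest label), so constructing a bipartition
    from either side yields an equal object.
    """

    side: frozenset[str]
    taxa: frozenset[str]

    def __init__(self, side: Iterable[str], taxa: Iterable[str]):
        side = frozenset(side)
        taxa = frozenset(taxa)
        if not side <= taxa:
            raise ValueError("side must be a subset of the taxon set")
        ref = min(taxa)
        if ref in side:
            side = taxa - side
        object.__setattr__(self, "side", side)
        object.__setattr__(self, "taxa", taxa)

    @property
    def is_trivial(self) -> bool:
        return len(self.side) < 2 or len(self.side) > len(self.taxa) - 2

    def __str__(self) -> str:
        other = self.taxa - self.side
        return ",".join(sorted(self.side)) + "|" + ",".join(sorted(other))


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial splits induced by the internal edges of an unrooted tree.

    Rooted input is treated as unrooted (the root edge is collapsed); for a
    binary unrooted tree on n taxa this returns exactly n - 3 splits.
    """
    taxa = terminal_labels(tree)
    splits: set[Bipartition] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = s
            bp = Bipartition(s, taxa)
            if not bp.is_trivial:
                splits.add(bp)
    return splits


def split_supports(tree: Tree) -> dict[Bipartition, float | None]:
    """Map each non-trivial split to its support value (or None if unlabelled)."""
    taxa = terminal_labels(tree)
    root = tree.seed_node
    out: dict[Bipartition, float | None] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = s
        if node is root:
            continue
        bp = Bipartition(s, taxa)
        if bp.is_trivial:
            continue
        sup = _node_support(node)
        # a bifurcating root shows the same split twice; keep a labelled value
        if bp not in out or out[bp] is None:
            out[bp] = sup
    return out


def _node_support(node: dendropy.Node) -> float | None:
    raw: str | None = node.label
    if raw is None:
        comments = list(node.comments) + list(node.edge.comments or [])
        for c in comments:
            m = _SUPPORT_COMMENT.search(c.strip("&"))
            if m:
                raw = m.group(1)
                break
    if raw is None:
        return None
    try:
        val = float(raw)
    except ValueError:
        return None
    return val / 100.0 if val > 1.0 else val


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: |symmetric difference of split sets|."""
    tax1, tax2 = terminal_labels(t1), terminal_labels(t2)
    if tax1 != tax2:
        raise ValueError(
            "terminal sets differ: only in first "
            f"{sorted(tax1 - tax2)}, only in second {sorted(tax2 - tax1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> Tree:
    """Neighbour-joining tree from a symmetric distance matrix.

    Negative estimated branch lengths are truncated to zero.  Delegates the
    agglomeration to scikit-bio's saitou-nei implementation.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("need at least 3 taxa for neighbour joining")
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    dm = DistanceMatrix(d, list(labels))
    sk = _skbio_nj(dm, neg_as_zero=True)
    buf = io.StringIO()
    sk.write(buf, format="newick")
    return parse_newick(buf.getvalue())


# ---------------------------------------------------------------------------
# Congruence table


@dataclass
class SplitSupportTable:
    """Reference-tree splits x analyses support matrix (NaN = split absent)."""

    table: pd.DataFrame  # index: canonical split strings; columns: analyses

    @property
    def all_full_support(self) -> pd.Series:
        """True for splits recovered with support 1.0 in every analysis."""
        return (self.table == 1.0).all(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["all_full_support"] = self.all_full_support
        out.to_csv(path, sep="\t", na_rep=ABSENT, index_label="split")


def split_support_table(
    reference: Tree, analyses: Sequence[tuple[str, Tree]]
) -> SplitSupportTable:
    """Tabulate, per internal split of the reference, each analysis' support.

    Every analysis tree must cover exactly the reference terminal set; a cell
    is NaN when the analysis does not contain the reference split at all.
    A split present in an analysis but carrying no support label is recorded
    as 1.0 (fully resolved trees without annotations assert their splits).
    """
    ref_taxa = terminal_labels(reference)
    ref_splits = sorted(bipartitions(reference), key=str)
    data: dict[str, list[float]] = {}
    for name, tree in analyses:
        taxa = terminal_labels(tree)
        if taxa != ref_taxa:
            raise ValueError(
                f"analysis {name!r}: terminal set mismatch with reference "
                f"(missing {sorted(ref_taxa - taxa)}, extra {sorted(taxa - ref_taxa)})"
            )
        sup = split_supports(tree)
        col = []
        for bp in ref_splits:
            if bp in sup:
                col.append(1.0 if sup[bp] is None else sup[bp])
            else:
                col.append(np.nan)
        data[name] = col
    frame = pd.DataFrame(data, index=[str(bp) for bp in ref_splits])
    return SplitSupportTable(frame)


# ---------------------------------------------------------------------------
# Posterior tree-list diagnostics


def bipartition_frequencies(treelist: Sequence[Tree]) -> dict[Bipartition, float]:
    """Frequency of every split observed in at least one tree of the list."""
    if not treelist:
        raise ValueError("empty tree list")
    taxa = terminal_labels(treelist[0])
    counts: dict[Bipartition, int] = {}
    for i, t in enumerate(treelist):
        if terminal_labels(t) != taxa:
            raise ValueError(f"tree {i}: terminal set differs from tree 0")
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(treelist)
    return {bp: c / n for bp, c in counts.items()}


def maxdiff(
    chain_a: Sequence[Tree],
    chain_b: Sequence[Tree],
    burnin_fraction: float = 0.0,
) -> float:
    """Maximum between-chain discrepancy in bipartition frequencies.

    The PhyloBayes-style topological convergence diagnostic: over the union
    of splits observed in either chain (absent = frequency 0), the largest
    absolute frequency difference.  1.0 signals chains stuck on conflicting
    resolutions; values near 0 indicate topological convergence.
    """
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    chain_a = _discard_burnin(chain_a, burnin_fraction)
    chain_b = _discard_burnin(chain_b, burnin_fraction)
    if terminal_labels(chain_a[0]) != terminal_labels(chain_b[0]):
        raise ValueError("chains have different terminal sets")
    fa = bipartition_frequencies(chain_a)
    fb = bipartition_frequencies(chain_b)
    diffs = [abs(fa.get(bp, 0.0) - fb.get(bp, 0.0)) for bp in set(fa) | set(fb)]
    return max(diffs, default=0.0)


def _discard_burnin(chain: Sequence[Tree], fraction: float) -> Sequence[Tree]:
    if not chain:
        raise ValueError("empty chain")
    start = int(len(chain) * fraction)
    kept = chain[start:]
    if not kept:
        raise ValueError("burn-in discards the whole chain")
    return kept


def prune_terminal(treelist: Sequence[Tree], taxon: str) -> list[Tree]:
    """Remove one terminal from every tree of a list (rogue-taxon cleanup).

    Degree-2 nodes left behind are suppressed and the lengths of the merged
    edges are summed, so path lengths among remaining terminals are preserved.
    """
    out = []
    for i, t in enumerate(treelist):
        if taxon not in terminal_labels(t):
            raise ValueError(f"tree {i} lacks terminal {taxon!r}")
        c = t.clone(depth=1)
        c.prune_taxa_with_labels([taxon])
        out.append(c)
    return out
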