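"""Compositional-homogeneity testing and Dayhoff recoding.

The homogeneity test is a per-gene parametric bootstrap: the observed
taxon-by-residue chi-square statistic is compared against its null
distribution obtained by re-simulating the gene on a neighbour-joining guide
tree under a frequency-driven replacement process with the gene's pooled
empirical frequencies.  Comparing against simulated rather than theoretical
quantiles is essential because shared ancestry correlates taxon compositions
and inflates the statistic far beyond its nominal chi-square distribution.

Genes failing the test at a conservative alpha (default 0.1) are flagged as
compositionally heterogeneous; Dayhoff recoding collapses the 20 amino acids
into 6 biochemically coherent categories to dampen exactly this kind of
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GeneAlignment, MISSING_CHARS, OrthologSet
from .curation import p_distance_matrix
from .simulate import _simulate_leaf_states, _TreeArrays
from .treekit import Tree, nj_tree

logger = logging.getLogger(__name__)

#: The six Dayhoff categories: small/neutral, sulfhydryl, acid/amide,
#: aromatic, basic, hydrophobic.
DAYHOFF_CATEGORIES: dict[str, str] = {
    "1": "AGPST",
    "2": "C",
    "3": "DENQ",
    "4": "FWY",
    "5": "HKR",
    "6": "ILMV",
}

_DAYHOFF_MAP = {aa: cat for cat, members in DAYHOFF_CATEGORIES.items() for aa in members}
_DAYHOFF_TABLE = str.maketrans({**_DAYHOFF_MAP, "-": "-", "X": "X"})

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Composition tables and the chi-square statistic


@dataclass
class CompositionTable:
    """Taxon x residue counts (gaps and 'X' excluded)."""

    taxa: list[str]
    counts: np.ndarray  # shape (n_taxa, 20), integer

    @property
    def frequencies(self) -> np.ndarray:
        """Pooled empirical residue frequencies (column totals / grand total)."""
        col = self.counts.sum(axis=0).astype(float)
        return col / col.sum()


def composition_counts(gene: GeneAlignment) -> CompositionTable:
    """Count residues per taxon; taxa with zero residues are excluded (logged)."""
    taxa, rows = [], []
    for tid, seq in gene.rows.items():
        counts = np.zeros(20, dtype=np.int64)
        for ch in seq:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        if counts.sum() == 0:
            logger.info(
                "gene %s: taxon %s has no residues; excluded from composition",
                gene.gene_id, tid,
            )
            continue
        taxa.append(tid)
        rows.append(counts)
    if len(taxa) < 2:
        raise ValueError(
            f"gene {gene.gene_id}: composition needs >= 2 taxa with residues"
        )
    return CompositionTable(taxa, np.vstack(rows))


def _x2_from_counts(counts: np.ndarray) -> np.ndarray:
    """Chi-square statistic per table for a (..., n_taxa, 20) counts array.

    Residue columns with zero total contribute nothing.
    """
    counts = counts.astype(float)
    row = counts.sum(axis=-1, keepdims=True)
    col = counts.sum(axis=-2, keepdims=True)
    grand = counts.sum(axis=(-1, -2), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = row * col / grand
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=(-1, -2))


def x2_statistic(table: CompositionTable) -> float:
    """Taxon-by-residue homogeneity chi-square: sum (O - E)^2 / E."""
    if len(table.taxa) < 2:
        raise ValueError("chi-square needs at least 2 taxa")
    if table.counts.sum() == 0:
        raise ValueError("empty composition table")
    return float(_x2_from_counts(table.counts))


# ---------------------------------------------------------------------------
# The simulation-based test


@dataclass
class CompositionTestResult:
    """Outcome of the per-gene homogeneity bootstrap."""

    gene_id: str
    x2_observed: float
    n_simulations: int
    n_ge: int  # null replicates with X^2 >= observed
    p_value: float  # add-one estimator (n_ge + 1) / (n_simulations + 1)
    alpha: float
    homogeneous: bool  # p_value >= alpha


def _f81_corrected_distances(
    gene: GeneAlignment, frequencies: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Pairwise distances in expected-replacements units.

    p-distances are inverted through the frequency-driven model,
    d = -pmax * ln(1 - p / pmax) with pmax = 1 - sum(pi^2), so the guide tree
    carries branch lengths on the same scale the simulator expects.
    Saturated or incomparable pairs are capped at the distance of
    p = 0.999 * pmax.
    """
    p, labels = p_distance_matrix(gene)
    pmax = max(1.0 - float(frequencies @ frequencies), 1e-9)
    cap = -pmax * np.log(1.0 - 0.999)
    p = np.where(np.isnan(p), pmax, p)
    ratio = np.clip(1.0 - p / pmax, 0.001, None)
    d = -pmax * np.log(ratio)
    d = np.minimum(d, cap)
    np.fill_diagonal(d, 0.0)
    return d, labels


def _guide_tree(gene: GeneAlignment, taxa: list[str], frequencies: np.ndarray) -> Tree:
    sub = GeneAlignment(
        gene.gene_id, {t: gene.rows[t] for t in taxa}, recoded=gene.recoded
    )
    d, labels = _f81_corrected_distances(sub, frequencies)
    if len(taxa) < 3:
        logger.info("gene %s: < 3 usable taxa, star-tree null", gene.gene_id)
        return _star_tree(labels, float(d[np.triu_indices(len(labels), 1)].mean()))
    return nj_tree(d, labels)


def _star_tree(labels: list[str], mean_distance: float) -> Tree:
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    for lab in labels:
        tree.seed_node.new_child(
            taxon=tns.get_taxon(lab), edge_length=mean_distance / 2.0
        )
    return tree


def composition_homogeneity_test(
    gene: GeneAlignment,
    n_simulations: int = 499,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.1,
) -> CompositionTestResult:
    """Parametric-bootstrap test of amino-acid compositional homogeneity.

    Procedure: (1) observed chi-square from the taxon x residue table;
    (2) neighbour-joining guide tree on model-corrected p-distances;
    (3) ``n_simulations`` replicate alignments of the gene's length evolved
    on the guide tree under the frequency-driven process with the gene's
    pooled frequencies; (4) replicate chi-squares; (5) add-one Monte-Carlo
    p-value.  The gene is called homogeneous when ``p >= alpha``.
    """
    if n_simulations < 99:
        raise ValueError("n_simulations must be at least 99")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    table = (
        composition_counts_recoded(gene) if gene.recoded else composition_counts(gene)
    )
    observed = x2_statistic(table)
    frequencies = table.frequencies
    tree = _guide_tree(gene, table.taxa, frequencies)
    masks = _missing_masks(gene, table.taxa)
    null = _null_x2(tree, gene.length, frequencies, n_simulations, rng, masks)
    n_ge = int((null >= observed).sum())
    p = (n_ge + 1) / (n_simulations + 1)
    return CompositionTestResult(
        gene_id=gene.gene_id,
        x2_observed=observed,
        n_simulations=n_simulations,
        n_ge=n_ge,
        p_value=p,
        alpha=alpha,
        homogeneous=p >= alpha,
    )


def _missing_masks(gene: GeneAlignment, taxa: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-taxon boolean mask of missing ('-'/'X') alignment positions."""
    out = {}
    for t in taxa:
        arr = np.frombuffer(gene.rows[t].encode("ascii"), dtype="S1")
        out[t] = (arr == b"-") | (arr == b"X")
    return out


def _null_x2(
    tree: Tree,
    length: int,
    frequencies: np.ndarray,
    n_simulations: int,
    rng: np.random.Generator,
    masks: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Chi-square statistics of replicate alignments simulated on ``tree``.

    All replicates are evolved in one vectorized pass (columns are i.i.d.),
    then counted per replicate.  When ``masks`` is given, each replicate
    inherits the observed per-taxon coverage pattern: positions missing in a
    taxon's real row are excluded from that taxon's replicate counts.  This
    matters because with ragged coverage the taxa no longer share the same
    column set, so among-column compositional variation stops cancelling out
    of the among-taxon statistic; a null that ignores the coverage pattern
    is badly miscalibrated on end-ragged genes.
    """
    arrays = _TreeArrays(tree)
    k = len(frequencies)
    n_cols = n_simulations * length
    leaf_states = _simulate_leaf_states(arrays, n_cols, frequencies, rng)
    counts = np.empty((n_simulations, len(leaf_states), k), dtype=np.int64)
    rep_offsets = (np.arange(n_cols) // length) * k
    for j, (label, states) in enumerate(leaf_states.items()):
        if masks is not None and masks[label].any():
            keep = ~np.tile(masks[label], n_simulations)
            binned = np.bincount(
                rep_offsets[keep] + states[keep], minlength=n_simulations * k
            )
        else:
            binned = np.bincount(rep_offsets + states, minlength=n_simulations * k)
        counts[:, j, :] = binned.reshape(n_simulations, k)
    return _x2_from_counts(counts)


def run_homogeneity_tests(
    ortholog_set: OrthologSet,
    n_simulations: int = 499,
    seed: int = 0,
    alpha: float = 0.1,
) -> list[CompositionTestResult]:
    """Run the homogeneity test on every gene with per-gene derived seeds."""
    children = np.random.SeedSequence(seed).spawn(len(ortholog_set))
    return [
        composition_homogeneity_test(
            g, n_simulations, np.random.default_rng(child), alpha
        )
        for g, child in zip(ortholog_set, children)
    ]


def filter_homogeneous(
    ortholog_set: OrthologSet,
    alpha: float = 0.1,
    n_simulations: int = 499,
    seed: int = 0,
    results: Sequence[CompositionTestResult] | None = None,
) -> tuple[OrthologSet, OrthologSet]:
    """Partition genes into (homogeneous, heterogeneous) at ``alpha``.

    Precomputed ``results`` may be supplied to re-partition at a different
    alpha without re-simulating.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if results is None:
        results = run_homogeneity_tests(ortholog_set, n_simulations, seed, alpha)
    by_gene = {r.gene_id: r for r in results}
    kept, flagged = [], []
    for g in ortholog_set:
        (kept if by_gene[g.gene_id].p_value >= alpha else flagged).append(g)
    return ortholog_set.replace_genes(kept), ortholog_set.replace_genes(flagged)


def results_to_tsv(
    results: Sequence[CompositionTestResult], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "x2": [r.x2_observed for r in results],
            "n_simulations": [r.n_simulations for r in results],
            "p_value": [r.p_value for r in results],
            "homogeneous": [r.homogeneous for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dayhoff recoding


def dayhoff_recode(gene: GeneAlignment) -> GeneAlignment:
    """Recode the 20 amino acids into the six Dayhoff categories (digits 1-6).

    Gap and 'X' characters pass through unchanged.  Digit symbols keep the
    six states unambiguous and distinct from residue letters.
    """
    rows = {}
    for tid, seq in gene.rows.items():
        for pos, ch in enumerate(seq):
            if ch not in _DAYHOFF_MAP and ch not in MISSING_CHARS:
                raise ValueError(
                    f"gene {gene.gene_id}, row {tid}: cannot recode "
                    f"{ch!r} at column {pos + 1}"
                )
        rows[tid] = seq.translate(_DAYHOFF_TABLE)
    return GeneAlignment(gene.gene_id, rows, recoded=True)


def recode_set(ortholog_set: OrthologSet) -> OrthologSet:
    return ortholog_set.replace_genes(dayhoff_recode(g) for g in ortholog_set)


def composition_counts_recoded(gene: GeneAlignment) -> CompositionTable:
    """Taxon x category counts for a Dayhoff-recoded alignment."""
    taxa, rows = [], []
    symbols = list(DAYHOFF_CATEGORIES)
    for tid, seq in gene.rows.items():
        counts = np.array([seq.count(s) for s in symbols], dtype=np.int64)
        if counts.sum() == 0:
            continue
        taxa.append(tid)
        rows.append(counts)
    if len(taxa) < 2:
        raise ValueError(f"gene {gene.gene_id}: needs >= 2 taxa with residues")
    return CompositionTable(taxa, np.vstack(rows))
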