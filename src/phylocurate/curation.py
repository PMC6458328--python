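"""Supermatrix curation: occupancy slicing, end trimming, rate-tail removal,
concatenation, outgroup subsetting and isoform selection.

These are the matrix-construction steps of a phylogenomic pipeline: starting
from per-gene amino-acid alignments over a shared taxon manifest, build the
nested family of matrices that probes matrix completeness (occupancy
thresholds), extreme evolutionary rates (removal of the slowest and fastest
gene tails) and outgroup composition.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import GeneAlignment, OrthologSet, TaxonManifest

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    """Thresholds of the four-matrix construction protocol.

    Defaults follow the standard protocol: matrix 1 at 50% taxon occupancy,
    matrix 2 removing the 20% slowest and 20% fastest genes, matrix 3 keeping
    genes homogeneous in composition at alpha = 0.1, matrix 4 at 70%
    occupancy, with alignment ends trimmed of columns over 80% missing.
    """

    occupancy_fraction_m1: float = 0.5
    occupancy_fraction_m4: float = 0.7
    rate_tail_fraction: float = 0.2
    end_trim_max_missing: float = 0.8
    composition_alpha: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "occupancy_fraction_m1",
            "occupancy_fraction_m4",
            "rate_tail_fraction",
            "end_trim_max_missing",
            "composition_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Occupancy


@dataclass
class OccupancyMatrix:
    """Boolean gene x taxon presence table."""

    table: pd.DataFrame  # index: gene_ids, columns: terminal_ids, dtype bool

    @property
    def gene_counts(self) -> pd.Series:
        """Number of taxa present per gene."""
        return self.table.sum(axis=1)

    @property
    def taxon_counts(self) -> pd.Series:
        """Number of genes present per taxon."""
        return self.table.sum(axis=0)

    def sorted(self) -> "OccupancyMatrix":
        """Best-sampled genes and taxa in the upper-left corner."""
        t = self.table
        t = t.loc[
            t.sum(axis=1).sort_values(ascending=False, kind="stable").index,
            t.sum(axis=0).sort_values(ascending=False, kind="stable").index,
        ]
        return OccupancyMatrix(t)

    def to_tsv(self, path: str | Path) -> None:
        self.table.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def compute_occupancy(ortholog_set: OrthologSet) -> OccupancyMatrix:
    """Presence of each terminal in each gene (all-gap rows count as absent)."""
    if not len(ortholog_set):
        raise ValueError("empty ortholog set")
    taxa = ortholog_set.manifest.terminal_ids
    data = {
        g.gene_id: [g.is_present(t) for t in taxa] for g in ortholog_set
    }
    table = pd.DataFrame.from_dict(
        data, orient="index", columns=list(taxa), dtype=bool
    )
    return OccupancyMatrix(table)


def occupancy_threshold(fraction: float, n_taxa: int) -> int:
    """Minimum present-taxon count at a fractional occupancy threshold.

    ``ceil(fraction * n_taxa)`` with an epsilon guard against float error;
    "at least half" of 74 is 37, and 70% of 74 forces ceil(51.8) = 52.
    """
    return int(math.ceil(fraction * n_taxa - 1e-9))


def slice_by_occupancy(ortholog_set: OrthologSet, fraction: float) -> OrthologSet:
    """Keep genes represented in at least ``fraction`` of manifest terminals."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_taxa = ortholog_set.manifest.n_taxa
    minimum = occupancy_threshold(fraction, n_taxa)
    kept = [
        g
        for g in ortholog_set
        if sum(g.is_present(t) for t in g.rows) >= minimum
    ]
    logger.info(
        "occupancy slice at %.2f (>= %d/%d taxa): %d of %d genes kept",
        fraction, minimum, n_taxa, len(kept), len(ortholog_set),
    )
    return ortholog_set.replace_genes(kept)


# ---------------------------------------------------------------------------
# End trimming


def trim_ends(gene: GeneAlignment, max_missing: float) -> GeneAlignment:
    """Trim alignment ends of columns exceeding the missingness threshold.

    Columns are removed from the left end while the fraction of missing
    characters ('-' or 'X', over the taxa present in the gene) exceeds
    ``max_missing``, and likewise from the right end; interior columns are
    never touched.  The result may be empty.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    if not gene.rows or gene.length == 0:
        return gene
    frac = column_missingness(gene)
    lo, hi = 0, gene.length
    while lo < hi and frac[lo] > max_missing:
        lo += 1
    while hi > lo and frac[hi - 1] > max_missing:
        hi -= 1
    if lo == 0 and hi == gene.length:
        return gene
    rows = {t: s[lo:hi] for t, s in gene.rows.items()}
    return GeneAlignment(gene.gene_id, rows, recoded=gene.recoded)


def column_missingness(gene: GeneAlignment) -> np.ndarray:
    """Per-column fraction of '-'/'X' characters over the gene's rows."""
    arr = _char_matrix(gene)
    missing = (arr == b"-") | (arr == b"X")
    return missing.mean(axis=0)


def _char_matrix(gene: GeneAlignment) -> np.ndarray:
    return np.frombuffer(
        "".join(gene.rows.values()).encode("ascii"), dtype="S1"
    ).reshape(gene.n_taxa, gene.length)


# ---------------------------------------------------------------------------
# Evolutionary-rate proxy and rate tails


def p_distance_matrix(gene: GeneAlignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances over mutually ungapped columns.

    Entries are NaN for pairs with no comparable column.
    """
    labels = list(gene.rows)
    arr = _char_matrix(gene)
    ok = ~((arr == b"-") | (arr == b"X"))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        comparable = both.sum(axis=1).astype(float)
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(comparable > 0, mism / comparable, np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d, labels


def gene_rate(gene: GeneAlignment) -> float:
    """Rate proxy: mean pairwise p-distance across sequence pairs.

    Pairs with zero comparable columns are skipped; gaps and 'X' never count
    as matches or mismatches.
    """
    if gene.n_taxa < 2:
        raise ValueError(f"gene {gene.gene_id}: need >= 2 sequences for a rate")
    d, _ = p_distance_matrix(gene)
    iu = np.triu_indices(gene.n_taxa, k=1)
    vals = d[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"gene {gene.gene_id}: rate undefined (no comparable pair)")
    return float(vals.mean())


@dataclass
class RateTable:
    """gene_id -> mean pairwise p-distance."""

    rates: dict[str, float]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\trate\n")
            for gid, r in self.rates.items():
                fh.write(f"{gid}\t{r:.6f}\n")


def rate_table(ortholog_set: OrthologSet) -> RateTable:
    return RateTable({g.gene_id: gene_rate(g) for g in ortholog_set})


def remove_rate_tails(
    ortholog_set: OrthologSet,
    lower_fraction: float,
    upper_fraction: float,
    rates: RateTable | None = None,
) -> OrthologSet:
    """Drop the slowest and fastest genes by rate rank.

    Genes are ranked by rate ascending with ties broken by gene_id;
    ``ceil(lower_fraction * n)`` genes are removed from the slow end and
    ``ceil(upper_fraction * n)`` from the fast end.  Survivors keep their
    original order.  At the standard 20%/20% setting, 1059 genes reduce to
    635 (212 removed per tail).
    """
    if not (0.0 <= lower_fraction <= 1.0 and 0.0 <= upper_fraction <= 1.0):
        raise ValueError("tail fractions must be in [0, 1]")
    if lower_fraction + upper_fraction >= 1.0:
        raise ValueError("tail fractions must sum to less than 1")
    n = len(ortholog_set)
    if n == 0:
        return ortholog_set
    if rates is None:
        rates = rate_table(ortholog_set)
    ranked = sorted(
        ortholog_set.gene_ids, key=lambda gid: (rates.rates[gid], gid)
    )
    n_low = math.ceil(lower_fraction * n - 1e-9)
    n_high = math.ceil(upper_fraction * n - 1e-9)
    removed = set(ranked[:n_low]) | set(ranked[n - n_high :] if n_high else [])
    kept = [g for g in ortholog_set if g.gene_id not in removed]
    logger.info(
        "rate tails removed (%d slow, %d fast): %d of %d genes kept",
        n_low, n_high, len(kept), n,
    )
    return ortholog_set.replace_genes(kept)


# ---------------------------------------------------------------------------
# Concatenation


@dataclass
class Supermatrix:
    """Concatenated alignment with 1-based inclusive partition coordinates."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid, seq in self.rows.items():
                fh.write(f">{tid}\n{seq}\n")

    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP: name, two spaces, full sequence."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.rows)} {self.length}\n")
            for tid, seq in self.rows.items():
                fh.write(f"{tid}  {seq}\n")

    def write_partitions(self, path: str | Path, model: str = "LG") -> None:
        """RAxML-style partition file: ``MODEL, gene = start-end``."""
        with open(path, "w") as fh:
            for gid, start, end in self.partitions:
                fh.write(f"{model}, {gid} = {start}-{end}\n")


def concatenate(ortholog_set: OrthologSet) -> Supermatrix:
    """Concatenate genes into a supermatrix over the full manifest.

    Terminals missing a gene are filled with '?' for that gene's columns;
    partitions tile [1, total_length] in input gene order.
    """
    if not len(ortholog_set):
        raise ValueError("cannot concatenate an empty ortholog set")
    taxa = ortholog_set.manifest.terminal_ids
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for g in ortholog_set:
        partitions.append((g.gene_id, pos, pos + g.length - 1))
        pos += g.length
        filler = "?" * g.length
        for t in taxa:
            chunks[t].append(g.rows.get(t, filler))
    return Supermatrix(
        rows={t: "".join(parts) for t, parts in chunks.items()},
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# Outgroup subsetting


def subset_outgroups(ortholog_set: OrthologSet, keep_group: str) -> OrthologSet:
    """Restrict to all ingroup terminals plus one outgroup lineage.

    The gene list is left untouched (no re-slicing against occupancy); only
    rows of excluded terminals are dropped, matching the construction of
    outgroup-test datasets from the largest matrix.
    """
    manifest = ortholog_set.manifest
    outgroup_labels = sorted(
        {e.group_label for e in manifest.entries if e.source_class == "outgroup"}
    )
    if keep_group not in {e.group_label for e in manifest.entries}:
        raise ValueError(
            f"unknown group {keep_group!r}; available outgroup labels: "
            f"{outgroup_labels}"
        )
    keep_ids = {
        e.terminal_id
        for e in manifest.entries
        if e.source_class != "outgroup" or e.group_label == keep_group
    }
    new_manifest = TaxonManifest(
        tuple(e for e in manifest.entries if e.terminal_id in keep_ids)
    )
    genes = [
        GeneAlignment(
            g.gene_id,
            {t: s for t, s in g.rows.items() if t in keep_ids},
            recoded=g.recoded,
        )
        for g in ortholog_set
    ]
    return OrthologSet(new_manifest, genes)


# ---------------------------------------------------------------------------
# Isoform selection


_ISOFORM_PATTERN = re.compile(r"^(?P<gene>.+?)(?:\.(?:\d+)|_i\d+)$")


def select_longest_isoform(
    peptides: Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Keep the longest isoform per gene key.

    The gene key is everything before a trailing isoform token of the form
    ``.N`` or ``_iN`` (Trinity-style); ids without such a token are passed
    through as their own gene key (logged).  Length ties are broken by the
    lexicographically smallest sequence id.  Output order follows the first
    appearance of each gene key.
    """
    best: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for seq_id, seq in peptides:
        m = _ISOFORM_PATTERN.match(seq_id)
        if m:
            key = m.group("gene")
        else:
            key = seq_id
            logger.info("no isoform token in %r; treated as its own gene", seq_id)
        if key not in best:
            best[key] = (seq_id, seq)
            order.append(key)
        else:
            cur_id, cur_seq = best[key]
            if len(seq) > len(cur_seq) or (
                len(seq) == len(cur_seq) and seq_id < cur_id
            ):
                best[key] = (seq_id, seq)
    return [best[k] for k in order]
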