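"""Core containers: taxon manifests, per-gene alignments, ortholog sets.

A *gene alignment* is one orthogroup's aligned amino-acid sequences keyed by
terminal id.  An *ortholog set* is an ordered collection of gene alignments
sharing a taxon manifest; terminals absent from a gene simply have no row
(they are not gap-padded), mirroring how orthology pipelines emit
partially-occupied orthogroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet (one-letter codes, alphabetical order).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Characters treated as missing data in occupancy, rate and composition work.
MISSING_CHARS = frozenset("-X")

_ALLOWED = frozenset(AMINO_ACIDS) | MISSING_CHARS
# recoded alignments use digit states; accepted so curation ops work post-recode
_ALLOWED_RECODED = frozenset("123456") | MISSING_CHARS

SOURCE_CLASSES = ("new", "published_ingroup", "outgroup")


@dataclass(frozen=True)
class ManifestEntry:
    terminal_id: str
    group_label: str
    source_class: str

    def __post_init__(self) -> None:
        if not self.terminal_id:
            raise ValueError("terminal_id must be non-empty")
        if not self.group_label:
            raise ValueError("group_label must be non-empty")
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"source_class must be one of {SOURCE_CLASSES}, "
                f"got {self.source_class!r}"
            )


@dataclass(frozen=True)
class TaxonManifest:
    """Ordered roster of terminals with clade labels and sampling provenance."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.terminal_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate terminal ids: {dupes}")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "TaxonManifest":
        return cls(tuple(ManifestEntry(*r) for r in rows))

    @property
    def terminal_ids(self) -> tuple[str, ...]:
        return tuple(e.terminal_id for e in self.entries)

    @property
    def n_taxa(self) -> int:
        return len(self.entries)

    def ingroup_ids(self) -> tuple[str, ...]:
        return tuple(
            e.terminal_id for e in self.entries if e.source_class != "outgroup"
        )

    def group_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.group_label, None)
        return tuple(seen)

    def counts_by_source(self) -> dict[str, int]:
        out = {c: 0 for c in SOURCE_CLASSES}
        for e in self.entries:
            out[e.source_class] += 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("terminal_id\tgroup_label\tsource_class\n")
            for e in self.entries:
                fh.write(f"{e.terminal_id}\t{e.group_label}\t{e.source_class}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonManifest":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["terminal_id", "group_label", "source_class"]:
                raise ValueError(f"unexpected manifest header: {header}")
            for line in fh:
                if line.strip():
                    rows.append(tuple(line.rstrip("\n").split("\t")[:3]))
        return cls.from_rows(rows)


@dataclass
class GeneAlignment:
    """One orthogroup's aligned sequences, keyed by terminal id.

    Rows are strings over the 20 amino acids plus ``-`` (indel) and ``X``
    (unknown residue); Dayhoff-recoded alignments use the digit states 1-6.
    """

    gene_id: str
    rows: dict[str, str]
    recoded: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"gene {self.gene_id}: unequal row lengths {sorted(lengths)}"
            )
        allowed = _ALLOWED_RECODED if self.recoded else _ALLOWED
        for tid, seq in self.rows.items():
            bad = set(seq) - allowed
            if bad:
                pos = min(seq.index(c) for c in bad)
                raise ValueError(
                    f"gene {self.gene_id}, row {tid}: illegal character "
                    f"{seq[pos]!r} at column {pos + 1}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def terminal_ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    def is_present(self, terminal_id: str) -> bool:
        """Presence per the all-gap-rows-count-as-absent convention."""
        seq = self.rows.get(terminal_id)
        if seq is None:
            return False
        return any(c not in MISSING_CHARS for c in seq)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=tid, description="")
            for tid, seq in self.rows.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(
        cls, path: str | Path, gene_id: str | None = None, recoded: bool = False
    ) -> "GeneAlignment":
        gid = gene_id if gene_id is not None else Path(path).stem
        rows: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in rows:
                raise ValueError(f"duplicate terminal {rec.id!r} in {path}")
            rows[rec.id] = str(rec.seq).upper()
        return cls(gid, rows, recoded=recoded)


@dataclass
class OrthologSet:
    """Ordered gene alignments over a shared taxon manifest."""

    manifest: TaxonManifest
    genes: list[GeneAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        known = set(self.manifest.terminal_ids)
        for g in self.genes:
            extra = set(g.rows) - known
            if extra:
                raise ValueError(
                    f"gene {g.gene_id}: terminals not in manifest: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneAlignment]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def replace_genes(self, genes: Iterable[GeneAlignment]) -> "OrthologSet":
        return OrthologSet(self.manifest, list(genes))

    def write_fasta_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for g in self.genes:
            g.to_fasta(directory / f"{g.gene_id}.fasta")

    @classmethod
    def from_fasta_dir(
        cls, directory: str | Path, manifest: TaxonManifest
    ) -> "OrthologSet":
        paths = sorted(Path(directory).glob("*.fasta")) + sorted(
            Path(directory).glob("*.fa")
        )
        return cls(manifest, [GeneAlignment.from_fasta(p) for p in paths])
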