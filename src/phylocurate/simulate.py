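"""Synthetic phylogenomic data: trees, alignments, heterogeneity, missingness.

The generator emulates the structure of a deep-phylogeny transcriptomic
dataset: a species tree over labelled terminals, gene trees that may disagree
with it, amino-acid alignments evolved under a frequency-driven replacement
process, lineage-restricted compositional shifts, ragged alignment ends and
patterned taxon missingness.

The replacement process is F81-like over the 20 amino acids: replacement
events occur at rate beta along a branch and the new residue is drawn from
the stationary frequencies pi, giving the closed-form transition probability

    P(i -> j | t) = pi_j * (1 - exp(-beta * t)) + [i == j] * exp(-beta * t)

with beta = 1 / (1 - sum(pi^2)) so that branch lengths are expected
replacements per site.  This is deliberately the simplest process that can
induce and detect compositional heterogeneity; no attempt is made to mimic
empirical exchangeability matrices or site-heterogeneous mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .alignment import (
    AMINO_ACIDS,
    GeneAlignment,
    ManifestEntry,
    OrthologSet,
    TaxonManifest,
)
from .treekit import Tree

_AMINO_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

#: Average amino-acid composition of well-curated protein databases,
#: normalized to sum to 1; the default stationary distribution.
DEFAULT_FREQUENCIES = np.array(
    [
        0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
        0.024, 0.041, 0.047, 0.039, 0.055, 0.066, 0.054, 0.069, 0.011, 0.029,
    ]
)
DEFAULT_FREQUENCIES = DEFAULT_FREQUENCIES / DEFAULT_FREQUENCIES.sum()

#: Disturbed stationary distribution used for compositional shifts: all mass
#: on glycine, a caricature of the GC-pressure-driven drift toward small
#: residues (G/A/P) seen in compositionally deviant lineages.  Concentrating
#: the mass makes the induced heterogeneity unambiguous at moderate branch
#: lengths.
DISTURBED_FREQUENCIES = np.zeros(20)
DISTURBED_FREQUENCIES[AMINO_ACIDS.index("G")] = 1.0

#: Default mean of the exponential branch-length distribution (expected
#: amino-acid replacements per site).
DEFAULT_MEAN_BRANCH_LENGTH = 0.1


def _check_frequencies(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (20,):
        raise ValueError("frequencies must be a 20-vector")
    if (freqs < 0).any():
        raise ValueError("frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError(f"frequencies not normalized (sum={freqs.sum()!r})")
    return freqs


@dataclass
class SimulationConfig:
    """Parameters of a generic multi-gene simulation."""

    n_taxa: int
    n_genes: int
    gene_length: int
    seed: int
    rate_multipliers: Sequence[float] | None = None
    base_frequencies: np.ndarray = field(
        default_factory=lambda: DEFAULT_FREQUENCIES.copy()
    )
    shifted_taxa: tuple[str, ...] = ()
    shift_strength: float = 0.0
    shifted_gene_fraction: float = 0.0
    discordance_prob: float = 0.0
    occupancy_targets: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("too few taxa")
        if self.n_genes < 1 or self.gene_length < 1:
            raise ValueError("n_genes and gene_length must be positive")
        self.base_frequencies = _check_frequencies(self.base_frequencies)
        if self.rate_multipliers is not None:
            r = np.asarray(self.rate_multipliers, dtype=float)
            if len(r) != self.n_genes or (r <= 0).any():
                raise ValueError("rate_multipliers must be positive, one per gene")
        if not 0.0 <= self.shift_strength <= 1.0:
            raise ValueError("shift_strength must be in [0, 1]")
        if self.occupancy_targets is not None:
            t = np.asarray(self.occupancy_targets, dtype=int)
            if len(t) != self.n_genes:
                raise ValueError("one occupancy target per gene required")
            if (t > self.n_taxa).any():
                raise ValueError("occupancy target exceeds n_taxa")


# ---------------------------------------------------------------------------
# Trees


def simulate_species_tree(
    n_taxa: int,
    seed: int,
    labels: Sequence[str] | None = None,
    mean_branch_length: float = DEFAULT_MEAN_BRANCH_LENGTH,
) -> Tree:
    """Random binary unrooted species tree with exponential branch lengths.

    Topology is built by sequential random edge attachment (each new terminal
    subdivides a uniformly chosen edge); branch lengths are drawn from an
    exponential with the given mean.  Deterministic for a fixed seed.
    """
    if n_taxa < 3:
        raise ValueError("too few taxa")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"T{i + 1:03d}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("label count does not match n_taxa")
    order = [labels[i] for i in rng.permutation(n_taxa)]

    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    draw = lambda: float(rng.exponential(mean_branch_length)) + 1e-9
    for lab in order[:3]:
        tree.seed_node.new_child(taxon=tns.get_taxon(lab), edge_length=draw())
    for lab in order[3:]:
        edges = [
            e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        ]
        edge = edges[int(rng.integers(len(edges)))]
        parent, child = edge.tail_node, edge.head_node
        u = float(rng.random())
        total = edge.length
        mid = parent.new_child(edge_length=total * u)
        parent.remove_child(child)
        mid.add_child(child)
        child.edge.length = total * (1.0 - u)
        mid.new_child(taxon=tns.get_taxon(lab), edge_length=draw())
    return tree


def random_nni(tree: Tree, rng: np.random.Generator) -> Tree:
    """Apply one random nearest-neighbour-interchange move in place.

    Exactly one internal bipartition is replaced, so the result is at
    Robinson-Foulds distance 2 from the input.
    """
    candidates = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node or node.parent_node is None:
            continue
        siblings = [c for c in node.parent_node.child_nodes() if c is not node]
        if siblings and node.child_nodes():
            candidates.append((node, siblings))
    if not candidates:
        raise ValueError("tree has no internal edge eligible for NNI")
    node, siblings = candidates[int(rng.integers(len(candidates)))]
    sib = siblings[int(rng.integers(len(siblings)))]
    children = node.child_nodes()
    child = children[int(rng.integers(len(children)))]
    parent = node.parent_node
    len_child, len_sib = child.edge.length, sib.edge.length
    node.remove_child(child)
    parent.remove_child(sib)
    node.add_child(sib)
    sib.edge.length = len_sib
    parent.add_child(child)
    child.edge.length = len_child
    return tree


def simulate_gene_trees(
    species_tree: Tree,
    n_genes: int,
    discordance_prob: float,
    seed: int,
    rate_multipliers: Sequence[float] | None = None,
) -> list[Tree]:
    """Per-gene trees: the species tree, NNI-perturbed with given probability.

    Each gene tree equals the species tree with probability
    ``1 - discordance_prob``; otherwise one random NNI move is applied.  If
    ``rate_multipliers`` is given, each gene's branch lengths are scaled by
    its multiplier (rate heterogeneity among genes).
    """
    if not 0.0 <= discordance_prob <= 1.0:
        raise ValueError("discordance_prob must be in [0, 1]")
    if not any(species_tree.leaf_node_iter()):
        raise ValueError("empty species tree")
    if rate_multipliers is not None and len(rate_multipliers) != n_genes:
        raise ValueError("one rate multiplier per gene required")
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_genes):
        gt = species_tree.clone(depth=1)
        if rng.random() < discordance_prob:
            random_nni(gt, rng)
        if rate_multipliers is not None:
            r = float(rate_multipliers[g])
            if r <= 0:
                raise ValueError("rate multipliers must be positive")
            for edge in gt.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = edge.length * r
        out.append(gt)
    return out


# ---------------------------------------------------------------------------
# Sequence evolution


class _TreeArrays:
    """Flat preorder representation of a tree for vectorized simulation."""

    def __init__(self, tree: Tree):
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.blen = np.zeros(self.n_nodes)
        self.leaf_labels: list[str] = []
        self.leaf_index: list[int] = []
        self.is_terminal_edge = np.zeros(self.n_nodes, dtype=bool)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                self.parent[i] = index[id(n.parent_node)]
                t = n.edge.length
                if t is None:
                    t = 0.0
                if t < 0:
                    raise ValueError(f"negative branch length {t}")
                self.blen[i] = t
            if n.is_leaf():
                if n.taxon is None:
                    raise ValueError("leaf without a taxon label")
                self.leaf_labels.append(n.taxon.label)
                self.leaf_index.append(i)
                self.is_terminal_edge[i] = True


def _draw(cum: np.ndarray, rng: np.random.Generator, size: int) -> np.ndarray:
    return np.searchsorted(cum, rng.random(size)).astype(np.int8)


def _simulate_leaf_states(
    arrays: _TreeArrays,
    n_cols: int,
    frequencies: np.ndarray,
    rng: np.random.Generator,
    shifted_leaves: frozenset[str] = frozenset(),
    mixed_frequencies: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evolve ``n_cols`` i.i.d. columns down the tree; returns leaf states."""
    # beta so that branch length = expected replacements; the max() guards the
    # degenerate single-residue composition where no replacement is visible
    beta = 1.0 / max(1.0 - float(frequencies @ frequencies), 1e-12)
    cum_base = np.cumsum(frequencies)
    cum_mix = None if mixed_frequencies is None else np.cumsum(mixed_frequencies)
    states = np.empty((arrays.n_nodes, n_cols), dtype=np.int8)
    states[0] = _draw(cum_base, rng, n_cols)
    shifted_node_ids = {
        arrays.leaf_index[i]
        for i, lab in enumerate(arrays.leaf_labels)
        if lab in shifted_leaves
    }
    for i in range(1, arrays.n_nodes):
        parent_state = states[arrays.parent[i]]
        q = 1.0 - np.exp(-beta * arrays.blen[i])
        mask = rng.random(n_cols) < q
        state = parent_state.copy()
        k = int(mask.sum())
        if k:
            cum = cum_mix if (cum_mix is not None and i in shifted_node_ids) else cum_base
            state[mask] = _draw(cum, rng, k)
        states[i] = state
    return {
        lab: states[idx]
        for lab, idx in zip(arrays.leaf_labels, arrays.leaf_index)
    }


def _states_to_row(states: np.ndarray) -> str:
    return _AMINO_BYTES[states].tobytes().decode("ascii")


def simulate_alignment(
    tree: Tree,
    length: int,
    frequencies: np.ndarray = DEFAULT_FREQUENCIES,
    seed: int | np.random.Generator = 0,
    gene_id: str = "gene",
    shifted_taxa: Sequence[str] = (),
    shift_strength: float = 0.0,
    disturbed_frequencies: np.ndarray | None = None,
) -> GeneAlignment:
    """Evolve an amino-acid alignment of ``length`` columns down ``tree``.

    Root states are drawn from ``frequencies``; each column then evolves
    independently under the frequency-driven replacement process.  If
    ``shifted_taxa`` is non-empty, replacement draws on those terminals'
    subtending branches use the mixture
    ``(1 - s) * pi + s * pi_disturbed`` instead of ``pi``.
    """
    frequencies = _check_frequencies(frequencies)
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= shift_strength <= 1.0:
        raise ValueError("shift_strength must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arrays = _TreeArrays(tree)
    mixed = None
    shifted = frozenset(shifted_taxa)
    if shifted:
        unknown = shifted - set(arrays.leaf_labels)
        if unknown:
            raise ValueError(f"unknown shifted taxa: {sorted(unknown)}")
        if disturbed_frequencies is None:
            disturbed_frequencies = DISTURBED_FREQUENCIES
        disturbed_frequencies = _check_frequencies(disturbed_frequencies)
        mixed = (1.0 - shift_strength) * frequencies + (
            shift_strength * disturbed_frequencies
        )
    leaf_states = _simulate_leaf_states(
        arrays, length, frequencies, rng, shifted, mixed
    )
    rows = {lab: _states_to_row(s) for lab, s in leaf_states.items()}
    return GeneAlignment(gene_id, rows)


def apply_compositional_shift(
    tree: Tree,
    length: int,
    frequencies: np.ndarray,
    seed: int,
    shifted_taxa: Sequence[str],
    shift_strength: float,
    disturbed_frequencies: np.ndarray | None = None,
    gene_id: str = "gene",
) -> GeneAlignment:
    """Simulate an alignment whose ``shifted_taxa`` evolve toward a disturbed
    composition on their terminal branches (see :func:`simulate_alignment`)."""
    return simulate_alignment(
        tree,
        length,
        frequencies,
        seed,
        gene_id=gene_id,
        shifted_taxa=shifted_taxa,
        shift_strength=shift_strength,
        disturbed_frequencies=disturbed_frequencies,
    )


def within_category_disturbance(
    frequencies: np.ndarray = DEFAULT_FREQUENCIES,
) -> np.ndarray:
    """A disturbed frequency vector that preserves Dayhoff-category totals.

    Within each of the six Dayhoff groups the category's total mass is
    concentrated on one representative residue, so a shift toward this vector
    changes residue usage without changing category usage — the kind of
    heterogeneity Dayhoff recoding is meant to erase.
    """
    from .composition import DAYHOFF_CATEGORIES

    frequencies = _check_frequencies(frequencies)
    out = np.zeros(20)
    for members in DAYHOFF_CATEGORIES.values():
        idx = [AMINO_ACIDS.index(a) for a in members]
        out[AMINO_ACIDS.index(members[0])] = frequencies[idx].sum()
    return out


# ---------------------------------------------------------------------------
# Missingness and ragged ends


def apply_missingness(
    genes: OrthologSet, occupancy_targets: Sequence[int], seed: int
) -> OrthologSet:
    """Subsample each gene's rows to exactly its occupancy target.

    Removed taxa become absent records (no gap-padded rows), matching how
    orthology output presents partial occupancy.  Deterministic per seed.
    """
    if len(occupancy_targets) != len(genes):
        raise ValueError("one occupancy target per gene required")
    n_taxa = genes.manifest.n_taxa
    children = np.random.SeedSequence(seed).spawn(len(genes))
    out = []
    for gene, target, child in zip(genes, occupancy_targets, children):
        target = int(target)
        if target < 1:
            raise ValueError(f"gene {gene.gene_id}: occupancy target < 1")
        if target > n_taxa:
            raise ValueError(f"gene {gene.gene_id}: occupancy target > n_taxa")
        if target > gene.n_taxa:
            raise ValueError(
                f"gene {gene.gene_id}: target {target} exceeds available rows"
            )
        rng = np.random.default_rng(child)
        ids = list(gene.rows)
        keep = set(
            ids[i] for i in rng.choice(len(ids), size=target, replace=False)
        )
        rows = {t: s for t, s in gene.rows.items() if t in keep}
        out.append(GeneAlignment(gene.gene_id, rows, recoded=gene.recoded))
    return genes.replace_genes(out)


def add_ragged_ends(
    gene: GeneAlignment,
    seed: int | np.random.Generator,
    row_fraction: float = 0.5,
    max_run_fraction: float = 0.2,
) -> GeneAlignment:
    """Gap out leading/trailing runs of some rows (partial-transcript ends).

    Each row is made ragged with probability ``row_fraction``; a ragged row
    loses a uniform-length run of up to ``max_run_fraction * length`` columns
    at each end, capped so at least one residue survives.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    length = gene.length
    max_run = int(max_run_fraction * length)
    rows = {}
    for tid, s in gene.rows.items():
        if rng.random() < row_fraction and length > 2:
            lead = int(rng.integers(0, max_run + 1))
            trail = int(rng.integers(0, max_run + 1))
            trail = min(trail, length - lead - 1)
            s = "-" * lead + s[lead : length - trail] + "-" * trail
        rows[tid] = s
    return GeneAlignment(gene.gene_id, rows, recoded=gene.recoded)


# ---------------------------------------------------------------------------
# The gastropod-shaped benchmark fixture


@dataclass
class GastropodFixture:
    """A synthetic dataset shaped like a deep-gastropod transcriptomic study.

    Unpacks as ``manifest, ortholog_set = fixture``; the remaining attributes
    expose the generating parameters for parameter-recovery checks.
    """

    manifest: TaxonManifest
    ortholog_set: OrthologSet
    species_tree: Tree
    rate_multipliers: dict[str, float]
    shifted_gene_ids: frozenset[str]
    shifted_taxa: tuple[str, ...]
    occupancy_targets: dict[str, int]

    def __iter__(self) -> Iterator:
        return iter((self.manifest, self.ortholog_set))


#: (group_label, source_class, count) blocks of the fixture manifest:
#: 17 newly sequenced gastropods, 39 published gastropods, 18 outgroups.
FIXTURE_MANIFEST_BLOCKS = (
    ("Patellogastropoda", "new", 9),
    ("Neritimorpha", "new", 8),
    ("Patellogastropoda", "published_ingroup", 4),
    ("Neritimorpha", "published_ingroup", 4),
    ("Vetigastropoda", "published_ingroup", 8),
    ("Caenogastropoda", "published_ingroup", 12),
    ("Heterobranchia", "published_ingroup", 11),
    ("Bivalvia", "outgroup", 9),
    ("Scaphopoda", "outgroup", 4),
    ("Cephalopoda", "outgroup", 4),
    ("Polyplacophora", "outgroup", 1),
)

_SOURCE_TAG = {"new": "n", "published_ingroup": "p", "outgroup": "o"}

FIXTURE_N_GENES = 1059
FIXTURE_N_HIGH_OCCUPANCY = 149  # genes at >= 70% occupancy (52 of 74 taxa)
FIXTURE_N_SHIFTED = 97  # genes carrying a strong compositional shift
FIXTURE_GENE_LENGTH = 500
FIXTURE_SHIFT_STRENGTH = 0.8
FIXTURE_N_SHIFTED_TAXA = 18  # a quarter of the 74 terminals
FIXTURE_DISCORDANCE_PROB = 0.25


def fixture_manifest() -> TaxonManifest:
    entries = []
    for group, source, count in FIXTURE_MANIFEST_BLOCKS:
        for i in range(count):
            tid = f"{group[:4]}_{_SOURCE_TAG[source]}{i + 1:02d}"
            entries.append(ManifestEntry(tid, group, source))
    return TaxonManifest(tuple(entries))


def _occupancy_draw(
    rng: np.random.Generator, low: int, high: int, n: int, decay: float = 0.85
) -> np.ndarray:
    """Draw occupancies in [low, high] with geometrically decaying weights,
    mimicking the many-genes-barely-pass shape of occupancy histograms."""
    k = np.arange(low, high + 1)
    w = decay ** (k - low)
    w /= w.sum()
    return rng.choice(k, size=n, p=w)


def make_gastropod_fixture(seed: int) -> GastropodFixture:
    """Generate the study-shaped benchmark dataset.

    74 terminals (17 new + 39 published gastropods + 18 outgroups);
    1059 genes, all at >= 50% taxon occupancy (>= 37 of 74), of which exactly
    149 reach 70% occupancy (>= 52), with genes placed at exactly 51 and 52
    present taxa to probe the threshold boundary; per-gene rate multipliers
    spanning an order of magnitude; 97 designated genes carrying a strong
    compositional shift (strength 0.8 toward a glycine-concentrated
    composition on 18 terminals); ragged alignment ends.
    """
    ss = np.random.SeedSequence(seed)
    (
        tree_seed,
        occ_seed,
        rate_seed,
        assign_seed,
        genes_seed,
        miss_seed,
    ) = ss.spawn(6)
    manifest = fixture_manifest()
    n_taxa = manifest.n_taxa

    rng_tree = np.random.default_rng(tree_seed)
    species_tree = simulate_species_tree(
        n_taxa, int(rng_tree.integers(2**31)), labels=manifest.terminal_ids
    )

    # occupancy histogram: a low block in [37, 51] and a high block in
    # [52, 74], with the boundary values forced to appear
    rng_occ = np.random.default_rng(occ_seed)
    n_low = FIXTURE_N_GENES - FIXTURE_N_HIGH_OCCUPANCY
    low = np.concatenate(
        [[37, 51], _occupancy_draw(rng_occ, 37, 51, n_low - 2)]
    )
    high = np.concatenate(
        [[52, 74], _occupancy_draw(rng_occ, 52, 74, FIXTURE_N_HIGH_OCCUPANCY - 2)]
    )
    occupancy = np.concatenate([low, high])
    rng_occ.shuffle(occupancy)

    rng_assign = np.random.default_rng(assign_seed)
    shifted_gene_idx = set(
        int(i)
        for i in rng_assign.choice(
            FIXTURE_N_GENES, size=FIXTURE_N_SHIFTED, replace=False
        )
    )
    shifted_taxa = tuple(
        manifest.terminal_ids[int(i)]
        for i in rng_assign.choice(
            n_taxa, size=FIXTURE_N_SHIFTED_TAXA, replace=False
        )
    )

    # rate multipliers: log-uniform over an order of magnitude; shifted genes
    # draw from the upper part of the range, reflecting the empirical
    # association between compositional deviation and fast evolution
    rng_rate = np.random.default_rng(rate_seed)
    rates = np.exp(rng_rate.uniform(np.log(0.2), np.log(2.5), FIXTURE_N_GENES))
    fast = np.exp(rng_rate.uniform(np.log(0.9), np.log(2.5), FIXTURE_N_GENES))
    for i in shifted_gene_idx:
        rates[i] = fast[i]

    gene_children = genes_seed.spawn(FIXTURE_N_GENES)
    genes = []
    for i in range(FIXTURE_N_GENES):
        gid = f"g{i + 1:04d}"
        rng_g = np.random.default_rng(gene_children[i])
        gt = species_tree.clone(depth=1)
        if rng_g.random() < FIXTURE_DISCORDANCE_PROB:
            random_nni(gt, rng_g)
        r = float(rates[i])
        for edge in gt.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * r
        if i in shifted_gene_idx:
            aln = simulate_alignment(
                gt,
                FIXTURE_GENE_LENGTH,
                DEFAULT_FREQUENCIES,
                rng_g,
                gene_id=gid,
                shifted_taxa=shifted_taxa,
                shift_strength=FIXTURE_SHIFT_STRENGTH,
                disturbed_frequencies=DISTURBED_FREQUENCIES,
            )
        else:
            aln = simulate_alignment(
                gt, FIXTURE_GENE_LENGTH, DEFAULT_FREQUENCIES, rng_g, gene_id=gid
            )
        genes.append(add_ragged_ends(aln, rng_g))

    full = OrthologSet(manifest, genes)
    miss_rng = np.random.default_rng(miss_seed)
    sliced = apply_missingness(
        full, occupancy.tolist(), int(miss_rng.integers(2**31))
    )
    return GastropodFixture(
        manifest=manifest,
        ortholog_set=sliced,
        species_tree=species_tree,
        rate_multipliers={f"g{i + 1:04d}": float(rates[i]) for i in range(FIXTURE_N_GENES)},
        shifted_gene_ids=frozenset(
            f"g{i + 1:04d}" for i in shifted_gene_idx
        ),
        shifted_taxa=shifted_taxa,
        occupancy_targets={
            f"g{i + 1:04d}": int(occupancy[i]) for i in range(FIXTURE_N_GENES)
        },
    )
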