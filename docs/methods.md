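# Methods

This note documents the models, default parameters and design choices behind
`phylocurate`, and what the synthetic benchmarks do and do not demonstrate
about real data.

## The replacement process

Sequences are simulated under the simplest process that can induce and
detect compositional heterogeneity: a frequency-driven (F81-like) model over
the 20 amino acids. Replacement events occur at rate β along a branch; the
new residue is drawn from the stationary frequencies π, giving

    P(i → j | t) = π_j (1 − e^{−βt}) + [i = j] e^{−βt},
    β = 1 / (1 − Σ_k π_k²),

so that branch lengths are expected replacements per site. The closed form
makes the process exactly simulable column-by-column (all columns i.i.d.),
and the choice of β calibrates distances and branch lengths to a common
scale. Deliberately out of scope: empirical exchangeabilities (LG etc.),
site-heterogeneous mixtures (CAT, C10–C60), rate variation across sites, and
heterotachy. These matter for tree inference, which this package does not
do; they are not needed to exercise occupancy, rate and composition
filtering.

Default stationary frequencies are the average composition of well-curated
protein databases (normalised; see `simulate.DEFAULT_FREQUENCIES`).

## Compositional shifts

A shifted terminal evolves, on its subtending branch only, with replacement
draws from the mixture (1 − s)·π + s·π_disturbed, s ∈ [0, 1]. The default
disturbed vector is a point mass on glycine — a deliberate caricature of the
GARP-ward compositional drift of GC-biased lineages, concentrated so that a
"strong" shift (s = 0.8) is unambiguous at realistic terminal branch lengths
(the shift a terminal actually expresses is damped by 1 − e^{−βt}, so a
terminal branch of length 0.1 moves composition only ~10% of the way toward
the mixture). `within_category_disturbance()` builds an alternative
disturbed vector that preserves Dayhoff-category totals, used to verify that
recoding erases exactly within-category heterogeneity.

## Trees, discordance, branch lengths

Species trees are random binary unrooted topologies (sequential random edge
attachment) with branch lengths drawn from an exponential with mean 0.1
replacements/site — arbitrary but fixed, and typical of the internal-branch
scale in deep-phylogeny datasets. Gene-tree discordance is modelled by a
single random NNI move applied with a per-gene probability; one NNI changes
exactly one bipartition (RF = 2), which is sufficient to exercise
congruence tooling. No coalescent machinery is implied: the generator makes
no claim about the *process* of discordance, only its presence.

## The homogeneity test

Per gene: (1) observed X² = Σᵢⱼ (Oᵢⱼ − Eᵢⱼ)²/Eᵢⱼ on the taxon × residue
count table (gaps and X excluded; taxa with zero residues dropped with a log
record; residue columns with zero total contribute 0); (2) a neighbour-
joining guide tree on model-corrected p-distances,
d = −p_max · ln(1 − p/p_max) with p_max = 1 − Σπ², capped at the distance of
p = 0.999·p_max (saturated or incomparable pairs); (3) N replicate
alignments of the gene's length evolved on the guide tree with the gene's
pooled empirical frequencies; (4) the add-one Monte-Carlo p-value
(n≥ + 1)/(N + 1), which can never be 0; (5) homogeneous ⇔ p ≥ α. A gene
with fewer than three usable taxa falls back to a star-tree null (logged).

Two design points deserve emphasis:

**Distance correction.** Using raw p-distances for the guide tree
systematically compresses its branch lengths (p saturates below p_max), so
the simulated null is under-dispersed and the test over-rejects. The
correction puts guide-tree branch lengths on the same
expected-replacements scale the simulator uses; measured null rejection at
α = 0.1 is then 0.10 (500 null genes, 16 taxa, length 500).

**Coverage-matched null.** When rows are end-ragged, taxa no longer share
the same column set, and among-column compositional variation stops
cancelling out of the among-taxon statistic — real coverage differences
masquerade as compositional heterogeneity. Simulating complete replicate
matrices therefore miscalibrates the test badly on ragged genes (measured
null rejection 0.77 at 74 taxa with ~10% end-raggedness). Each replicate
here instead inherits the observed per-taxon missing-position mask before
counting, which restores calibration (measured 0.10 under the same
conditions) while leaving replicate length equal to the gene length. This
is a stricter null than tools that simulate complete matrices, and is the
package's deliberate choice.

Defaults: N = 499 simulations (p-resolution 0.002), α = 0.1 ("conservative"
in the sense that it flags more genes than the conventional 0.05). A gene
at exactly p = α counts as homogeneous (the rejection region is p < α).

## Curation conventions

- Occupancy threshold: keep genes with present-count ≥ ⌈f·n⌉ (ε-guarded
  ceiling); "at least half" of 74 is 37, and f = 0.7 forces ⌈51.8⌉ = 52.
  All-gap rows count as absent.
- Rate proxy: mean pairwise p-distance over mutually ungapped columns;
  pairs with no comparable column are skipped; a gene with no comparable
  pair has no rate (error). This transparent proxy recovers simulated rate
  rankings with Spearman ρ ≈ 0.99 over multipliers spanning 0.1–10.
- Rate tails: ⌈f·n⌉ genes removed per tail, ties in the rate ranking broken
  by gene id so the pipeline is deterministic; 1059 genes at 20%/20% leave
  635 (212 per tail).
- End trimming counts both `-` and `X` as missing (neither is informative
  for composition or rate); the rule is strictly "> threshold", applied
  from each end only.
- Concatenation fills absent terminals with `?` (conventional for absent
  data, distinct from `-` for indels); partitions are 1-based inclusive in
  input gene order.
- Outgroup subsetting keeps all ingroup terminals plus one outgroup lineage
  and does not re-slice the gene list.
- Isoform selection parses a trailing `.N` or `_iN` token; ids without one
  are their own gene key (logged); length ties break to the smallest id.

## Tree diagnostics

Bipartitions are canonicalized as the side not containing the smallest
taxon label, so a split and its complement hash equal; rooted inputs are
treated as unrooted. Supports are read from internal-node labels (or a
branch-comment number), with values > 1 interpreted as percentages —
bootstrap percents and posterior proportions land on one [0, 1] scale.
maxdiff is taken over the union of splits observed in either chain (absent
= frequency 0), which yields exactly 1.0 for a terminal fixed at different
positions in two chains; an optional leading-fraction burn-in discard
defaults to 0. Pruning a terminal sums the lengths of merged edges, so
remaining path lengths are preserved. Neighbour joining truncates negative
estimated branch lengths to 0.

## The benchmark fixture

`make_gastropod_fixture` emulates the shape of a deep-gastropod
transcriptomic study: 74 terminals (17 newly sequenced + 39 published
gastropods + 18 outgroups split 9/4/4/1 across bivalves, scaphopods,
cephalopods and one polyplacophoran); 1059 genes of length 500 at ≥ 50%
occupancy, exactly 149 at ≥ 70%, with genes placed at exactly 51 and 52
present taxa to probe the ⌈0.7·74⌉ = 52 boundary; occupancy histogram with
geometric decay toward the threshold (most genes barely pass, as in real
occupancy plots); per-gene rate multipliers log-uniform on [0.2, 2.5];
gene-tree discordance probability 0.25; ragged ends on ~50% of rows (up to
20% of columns per side); and 97 designated genes with a strong shift
(s = 0.8, glycine-concentrated disturbance) on a fixed set of 18 terminals.
Shifted genes draw their rate multipliers from the upper part of the rate
range ([0.9, 2.5]): compositionally deviant genes are empirically fast
evolvers, and a near-zero-rate gene cannot express a terminal-branch shift
at all.

On this fixture the homogeneity filter (499 simulations, α = 0.1) flags all
97 shifted genes and, as a calibrated test must, also flags ≈ 7% of the 962
unshifted genes, leaving a homogeneous set of ≈ 890–900 genes. A designed
split can only be recovered exactly by a test with near-zero type-I error,
which would contradict calibration at α = 0.1; the package reports the
honestly computed partition.

What passing the suite does **not** show about real data: real orthogroups
have correlated missingness (whole libraries drop out), alignment error,
site-rate variation, saturated and misaligned regions, and compositional
heterogeneity that is continuous rather than a designed two-class mixture.
The fixture probes the *arithmetic and calibration* of the curation
pipeline, not the biological adequacy of any inference model.

## Problem sizes and runtime

The test suite simulates at the scales the checks need: the full 74 × 1059
fixture for matrix arithmetic and the homogeneity partition (499 null
simulations per gene, vectorized over replicates; a few minutes), 500 null
genes for calibration, 200 genes per setting for power monotonicity and
rate recovery, and 500–1000 randomized instances for oracle-equivalence
checks. `scripts/acceptance.py` re-runs the headline quantities from
scratch with seeds derived from a single `--seed`.
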