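# Methods

## Intron sites and coordinates

All genomic intervals are 0-based half-open internally; GFF3 I/O
converts to and from the 1-based inclusive convention. A gene model is
the CDS chain of one representative transcript — the mRNA with the
longest total CDS, ties broken lexicographically by transcript ID
(annotation releases rarely state an isoform policy; this one is
deterministic and reproducible). Introns located in UTRs are ignored:
the analysis is defined on coding gene architecture only.

An intron site is located by the cumulative coding length `c` upstream
of its junction in transcription order:

    protein_index = floor(c / 3)        phase = c mod 3

Phase follows the GFF3 convention (0 = between codons; 1/2 = after the
first/second nucleotide of a codon). "Intron phase" has two conventions
in the literature, so this one is stated explicitly and used
everywhere, including the simulator's slot indexing (boundary index
`b` in `1..L−1`, `c = 3b + p`; a boundary with zero upstream coding
sequence cannot be observed by any parser and is not a slot).

Strict parsing rejects genes with coding length not divisible by 3,
overlapping CDS segments, or mixed strands, naming the gene; lenient
mode skips and tallies them. No support for trans-splicing,
selenoproteins or programmed frameshifts.

## Well-aligned mask

The homology of intron positions is only assessed inside well-aligned
alignment regions. Column `k` is kept iff

* the fraction of rows without a gap at `k` is ≥ `f` (default 0.75), and
* the mean pairwise identity within the length-`w` window centred on
  `k` (default `w` = 10, clipped at the alignment ends) is ≥ `c`
  (default 0.5).

Pair identity within a window counts only columns where both rows are
ungapped; pairs with no comparable column are ignored, and a window
with no comparable pair scores 0. The criterion is a package policy —
"well-aligned" has no universal definition — so it is configurable and
echoed into every report; with `f = c = 0` the filter is disabled. The
mask is a deterministic function of the alignment and parameters and is
invariant to row order.

## Position homology

A site with `protein_index = i` maps to the alignment column of
residue `i` of its species' row. It is admitted when that column and,
where residue `i+1` exists, the column of residue `i+1` are both
mask-true (a site before the row's last residue is flanked on both
sides; one after it uses only the upstream column). Two admitted sites
are the same position iff they fall at the same boundary column with
the same phase. Requiring phase identity is standard practice for
intron-position homology and is assumed here.

Exact-position matching (tolerance 0) is the default and the
reproducible null. An opt-in tolerance `t > 0` merges same-phase
boundaries within `t` columns by single-linkage clustering per
(group, phase), with the smallest column as the deterministic cluster
representative — a sensitivity knob for intron sliding or alignment
jitter, not a default behaviour.

Only groups containing every configured species ("universal
single-copy" groups) are analyzed by default; a flag admits partial
groups, in which case distances restrict each species pair to their
shared groups.

## Sharing classes and proportions

Relative to a focal species, a position present in the focal is:

* `UNIQUE` — present in no other species;
* `EXCLUSIVE:<X>` — the set of other clades containing it is exactly
  {X};
* `WIDESPREAD` — two or more other clades contain it.

The focal's own clade minus the focal counts as "another clade" when
non-empty (a position shared between the tick and another chelicerate
would not be exclusive-with-outgroups; with a single-species focal
clade this is moot). The classes are exhaustive and mutually exclusive
for any vector containing the focal. The proportion denominator is the
number of focal-present positions in analyzed groups; fractions sum to
one.

Ancient introns are positions present in the focal AND the comparator
AND at least one outgroup species AND at least one ingroup (insect)
species. Their length summaries report n, quartiles by linear
interpolation (the type-7 convention, stated in output metadata),
log10 of the median, and the focal/species median ratio. An empty
subset yields an explicit `n = 0` row with null statistics, never NaN
arithmetic.

## Intron tree and Dollo losses

Species are compared by the Jaccard distance between their
intron-position sets (Dice available); Jaccard satisfies the metric
axioms, which the test suite verifies on random matrices. The tree is
built with canonical Saitou–Nei neighbor-joining implemented
in-package because its determinism contract matters here: Q-criterion
agglomeration with ties broken on the lexicographically smallest taxon
pair (internal nodes keyed by their smallest descendant leaf), negative
branch lengths clamped to zero with a warning, and output invariant to
input row permutation. On additive matrices NJ recovers the generating
tree exactly (RF = 0, branch lengths to 1e-9), which the suite checks
against random trees and cross-checks against scikit-bio's
implementation. NJ output is unrooted; for display it is rooted on the
configured outgroup clade.

Under Dollo parsimony each position is gained once, at the MRCA of the
species carrying it, and its absences are explained by the minimal set
of loss edges — the maximal all-absent subtrees below the MRCA, counted
in one post-order pass (bitmask-accelerated when summed over a whole
matrix). Topologies are compared by the unrooted Robinson–Foulds
bipartition distance.

No likelihood or Bayesian binary-character inference, and no bootstrap
support, are provided.

## Simulator

The generator emulates the statistical structure of a multi-genome
intron-architecture study: `n_groups` universal single-copy ortholog
groups, a root protein of `L` residues whose codon boundaries are
intron slots, evolution down a rooted species tree with branch lengths
in expected-substitution units.

* Root state: each boundary carries an intron with probability `p0`,
  phase uniform on {0,1,2}.
* Along a branch of length `t` with rate multiplier `m`, each present
  intron is lost with probability `1 − exp(−μ·m·t)` and each empty slot
  gains one with probability `1 − exp(−λ·m·t)`. One event per slot per
  branch — an approximation to the full jump process, accurate for
  small rate·t, chosen for simplicity and determinism under a single
  RNG stream.
* Rate multipliers attach to the MRCA of a configured species set and
  apply to its stem edge and every edge below — e.g. elevated intron
  loss across Pancrustacea.
* Amino acids mutate independently with probability `1 − exp(−s·t)` to
  a uniformly random other residue; no site-rate heterogeneity.
* Intron lengths are drawn per species from a log-normal (minimum 4 nt
  to fit the `GT..AG` bounds); CDS is back-translated with one fixed
  codon per amino acid (codon usage is out of scope); intron and flank
  sequence is uniform random, introns bounded by `GT..AG`.
* No insertions by default, so the true alignment is the ungapped leaf
  proteins. An optional deletion mode removes residue windows on
  terminal branches, putting gaps in the corresponding alignment rows
  and deleting introns whose flanking residues are lost — enough to
  exercise the mask and gap handling.

The emitted bundle (GFF3 + genome FASTA + protein FASTA per species,
aligned FASTA per group, ortholog TSV, Newick, truth tables, a ready
`run.yaml`, and a checksummed manifest) is byte-identical for equal
config + seed.

### Default study condition

The defaults encode a nine-species condition mirroring the
chelicerate-versus-pancrustacea contrast: focal "tick", comparator
"daphnia", three insects, four outgroups (two cnidarian-like, two
vertebrate-like); 500 groups, L = 300, p0 = 0.4, λ = 0, μ = 0.12 per
intron per unit branch length with an 8× multiplier on the
pancrustacean clade, substitution rate s = 0.05. The base loss rate was
chosen by forward analysis of the default tree so that lineage-specific
loss, not gain, dominates and the focal's exclusive-with-outgroups
fraction (~20%) exceeds the comparator's (~0.7%) by far more than an
order of magnitude — a clean, desk-scale analogue of the asymmetry such
studies report. Length models are log-normal with medians exactly one
decade apart (400 nt for tick + outgroups, 40 nt for pancrustaceans,
sdlog 0.6), so the designed ancient-intron log10 median ratio is 1.0.
These sizes keep the full simulate → emit → parse → analyze cycle
around a minute while leaving tens of thousands of positions, enough
for tight recovery checks.

### What the simulator does not emulate

Real annotation noise (wrong gene models, missing exons), paralogy and
gene duplication, intron sliding, insertion-driven alignment columns,
codon usage and GC structure, and rate heterogeneity across sites or
genes. Passing the recovery tests therefore shows the pipeline is
correct and internally consistent under the stated model; it does not
certify robustness to mis-annotation or alignment error in real
genomes, which the mask parameters and the tolerance knob exist to
probe.

## Numerical conventions and degenerate inputs

* Quartiles: linear interpolation (type 7), stated in output metadata.
* Jaccard on two empty position sets is defined as 0.
* NJ requires ≥3 taxa and a symmetric matrix; near-ties in Q (within
  1e-15) resolve to the lexicographically smallest pair.
* Empty ortholog tables, ragged alignments, duplicate species in a
  group, and degapped-row/protein mismatches are hard errors naming the
  group and species; an empty presence matrix (no admitted sites) is a
  valid object, but classification of a focal with zero sites is an
  error.
* Pipeline reports contain no timestamps; reruns with identical config
  and inputs are byte-identical.

## Known limitations

The single-event-per-branch approximation biases gain/loss dynamics at
large rate·t (no within-branch reversal). The well-aligned criterion is
a policy, not an inference; its defaults are conservative but
arbitrary, and results should be read with the mask parameters in view.
Dollo counting ignores the possibility of parallel gains, which for
intron positions at phase-matched boundaries is rare but not
impossible.
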