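# Methods

## Signature-indel detection

The detector operates on a protein multiple sequence alignment (≥ 2 rows,
uppercase residues, `-` gaps) and a taxon-group label per sequence.

**Gap-block segmentation.** Each column is reduced to its gap/non-gap
presence bitmask over rows; maximal runs of adjacent columns with identical
bitmasks form candidate blocks, kept when the pattern mixes gapped and
non-gapped rows. Within a block, a row counts as insert-bearing when it is
non-gap in at least `ragged_membership_fraction` (default 0.5) of the block
columns — with exact bitmask merging blocks are rectangular, but the ragged
rule keeps membership well defined if a caller relaxes the merging.

**Flank conservation.** "Conserved" has no canonical numeric definition for
this kind of analysis; we call a column conserved when the modal residue
frequency among its non-gap rows is ≥ `conservation_threshold` (default
0.90). Strict identity fails at realistic divergence, and 0.90 reproduces the
visual flank structure of published signature figures. The flank window walks
outward from the block edge on each side until `flank_window` (default 35,
the midpoint of the customary 30–40 residue neighbourhood) eligible columns
have been examined; columns gapped in more than `1 − conservation_threshold`
of rows are skipped *without consuming a window slot*, so a neighbouring
indel cannot deflate the count. The window truncates at the alignment edge.
A candidate needs ≥ `min_flank_conserved` (default 5) conserved columns on
*both* sides.

**Specificity.** A block is specific to a target label set when the fraction
of target members bearing the insert is ≥ `min_target_presence` (default 1.0)
and the fraction of non-target bearers is ≤ `max_other_presence` (default
0.0). Violating sequences are listed as exceptions. Polarity (insertion vs.
deletion) is reported as an insertion in the bearer set; outgroup-based
polarity inference is out of scope.

**Consensus length** is the mode of the bearers' ungapped residue counts in
the block, tie-broken to the smallest mode so output is deterministic.
`min_insert_length` defaults to 2 — no minimum CSI length is established in
the literature, so this only suppresses single-residue alignment noise.
Records are ordered by start column; the detector is invariant to row order.

## Composition and charge enrichment

Insert residues from all bearers are pooled; the background is the pooled
remainder of the protein. With background charged fraction `p0` (charged set
default {D, E, K, R}; H or N can be added by the caller) and `k` of `n`
insert residues charged, the two-sided exact binomial p-value follows the
minimum-likelihood rule: `p = Σ pmf(i; n, p0)` over all `i` with
`pmf(i) ≤ pmf(k)·(1 + 1e-9)`; the relative tolerance absorbs floating-point
ties (exact symmetric ties occur at `p0 = 0.5`). A binomial test was chosen
over Fisher's because the comparison is one pooled segment against a fixed
background fraction — there is no 2×2 structure. A background fraction of 0
or 1 makes the two-sided construction degenerate; the report is flagged and
the boundary one-sided tail is returned instead. No claim is made that this
test reflects an established convention for indel composition; it is this
package's formalization of the "inserts are charged-residue-rich"
observation.

## Phylogenetic congruence

The question is whether an indel shared by two distantly related groups
arose once (and moved by horizontal gene transfer) or independently in each
lineage. The test is topological: a single origin is consistent exactly when
the presence tips are monophyletic on the *unrooted* gene tree (the argument
concerns clustering, not root placement), equivalently when the minimum
number of 0↔1 changes is ≤ 1. The minimum-change count is a Sankoff dynamic
programme with unit substitution costs, which equals Fitch counting on
binary trees and the Hartigan generalization on multifurcations —
multifurcations are therefore handled exactly rather than by arbitrary
resolution, which could change the count. With symmetric costs the score is
invariant under rerooting and under complementing the character. No gain/loss
asymmetry (Dollo) is assumed.

## Trajectory hydration

Snapshots are consumed as multi-model PDB (fixed-column ATOM/HETATM parsing
with line-numbered errors; binary MD formats are out of scope — conversion is
the user's concern). Frame times are MODEL ordinal × a caller-supplied
interval, or an explicit `REMARK TIME` override. The snapshot grid
`extract_snapshots` places frames at `interval, 2·interval, …` and excludes
t = 0, so a 100 ns trajectory at 100 ps yields exactly 1000 frames.

Waters are identified by residue name ({HOH, SOL, WAT}, configurable) and
represented by their oxygen. All cutoffs are inclusive (≤). Shell counts:
number of distinct water oxygens within the radius (default 9 Å) of *any*
ligand atom, computed with a k-d tree. Site occupancy: fraction of frames
with ≥ 1 water oxygen within `match_radius` (default 1.5 Å — published
snapshot figures show crystallographic-water superpositions without stating
a radius, so this is a package choice at roughly half a hydrogen-bond
length) of each reference coordinate; the longest consecutive occupied run
is reported as a residence summary. Hydrogen bonds: the geometric criterion
defaults to heavy-atom donor–acceptor distance ≤ 3.5 Å within a 4 Å search
shell, the common hydrogen-free MD-analysis convention; when waters carry
hydrogens an optional H–donor–acceptor angle ≤ 30° mode is available.
Periodic boundary conditions are **not** applied: frames are assumed whole
and clustered around the solute. RMSD superposition is the optimal
least-squares rigid-body fit (Kabsch, via SVD); atoms are matched by order
within the selection.

Window means for hydration series use half-open time intervals `[t0, t1)`;
whether published shell-water averages are per-frame or block averages is
ambiguous, so explicit window means are exposed and the overall mean is the
plain per-frame average.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

**Alignment generator.** An ancestral core sequence (default 400 residues,
uniform over the 20 amino acids) is mutated per sequence at a per-site
substitution probability (default 0.05, a moderate within-family divergence;
0 gives the noise-free regime). Substitution replaces a residue uniformly
among the other 19 — detection tests need conservation *structure*, not
evolutionary realism, so no rate matrix is used. Bearer groups receive an
identical insert (default 50 residues at core position 180) — signature
indels are strongly conserved — and non-bearers are gapped over its columns;
within `flank_span` (40) columns of the insert the substitution rate is
overridden by `1 − flank_conservation` (default 0: fully conserved flanks).
The default group layout (Thermotogales 6 + Aquificales 5 bearing;
Petrotogales 4, Kosmotogales 4, Desulfurobacteriales 4 lacking) mirrors the
10–15-sequences-per-group design typical of such studies. Ground truth
records the planted span, bearer set and length.

**Tree generator.** Random sequential-join binary trees per group;
monophyletic mode joins the presence-group subtrees into one clade, the
non-monophyletic mode builds `((P1,A1),(P2,A2))` so the presence tips are
split across two clades each adjacent to absence tips, forcing ≥ 2 parsimony
changes. The alignment and tree generators are deliberately independent
(no sequence evolution along the tree).

**Trajectory generator.** Per frame: each conserved water site is occupied
independently with its probability (water at site + isotropic Gaussian
jitter, sd 0.4 Å, truncated to the match radius so planted occupancy is
exact); a Poisson(λ = 10) number of shell waters is placed within 9 Å of a
ligand atom; a contact water is placed 2.6–3.2 Å from the target acceptor
with probability 0.9 (emulating a persistently bridging water); 50 bulk
waters fill the box (60 Å) but are rejected from the shell, the sites and
the target neighbourhood so every planted statistic stays exact. The fixed
default geometry (27-heavy-atom ligand cluster, sites 15 Å out, target 25 Å
out) keeps the three statistics independent. What this does *not* emulate:
water dynamics and exchange kinetics, protein flexibility, periodic images,
or force-field physics — passing tests show the *measurement* operations are
correct and calibrated, not that any MD-derived number is reproduced.
All generators draw from `numpy.random.default_rng(seed)` only, so outputs
are byte-identical per seed.

## Problem sizes and numerical choices

Validation uses 100 noise-free and 50 noisy alignment replicates (23 rows,
~400–480 columns, insert lengths 10–80), 500-tree oracle comparisons at ≤ 8
tips (exhaustive internal labelings) and ≤ 10 tips (bipartition encoding),
200 geometry frames of 500 waters × 30 ligand atoms against an all-pairs
oracle, and 20 × 1000-frame occupancy recoveries — sizes at which the
independent oracles are exact and the full suite completes in about a
minute. Floating-point policy: superposition RMSD of rigid-motion copies is
asserted to 1e-6 Å; binomial p-values match the direct-summation oracle to
1e-12; occupancy and rate recoveries are judged inside 3-SD binomial /
Poisson sampling bands.

## Known limitations

- The detector assumes a trustworthy alignment; badly misaligned regions can
  create spurious gap blocks (upstream alignment masking is the user's job).
- Specificity is relative to the sequences supplied; it does not substitute
  for a database-wide screen of the indel region.
- Monophyly is a yes/no topological statement; branch support is not
  consulted.
- Hydration analyses trust the snapshot coordinates as given: no PBC
  unwrapping, no solvent equilibration checks.
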