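# Methods

This note documents the models and procedures implemented in `ssfe`, the
defaults they use, the design choices that were genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Alignment model

Pairwise and profile alignment use a substitution matrix **S** with
affine gap costs: a gap of length *L* costs `gap_open + (L−1)·gap_extend`
and terminal gaps are penalized (true global alignment). Defaults are
BLOSUM62 (from Biopython's bundled tables) with `gap_open = 11`,
`gap_extend = 1` — the community-standard protein defaults; no attempt
is made to tune them per family. The dynamic program is the three-state
Gotoh recursion with a fixed traceback tie order (diagonal > up > left)
so alignments are bit-reproducible. The same kernel aligns profiles:
column *i* of profile A scores against column *j* of profile B as
`cᵢᵀ S cⱼ` over residue count vectors (gaps contribute nothing), with
gap penalties scaled by the product of the profile sizes, i.e. plain
sum-of-pairs scoring.

The multiple alignment is progressive: pairwise p-distances from global
alignments feed a neighbor-joining guide tree (midpoint-rooted,
children canonically ordered), and profiles are merged leaves-to-root.
Known limitation: progressive alignment is greedy — "once a gap, always
a gap". Near long insertions it occasionally slips a short terminal
segment of one sequence into the insertion columns even when the
pairwise alignments are all correct; iterative refinement is
deliberately out of scope. The practical effect on the benchmark is
discussed below.

## Distances and phylogeny

From an alignment, pairwise distances are computed over columns where
both rows are non-gap: the raw mismatch proportion *p* (`model="p"`) or
the Poisson multiple-hit correction `d = −ln(1−p)` (`model="poisson"`,
the default). Pairs with no shared columns, or with *p* = 1 under the
correction, are hard errors rather than silently capped.

Trees are built with neighbor joining (Q-matrix minimization, standard
branch-length formulas). Two behaviours that libraries leave unspecified
are pinned down: ties in Q are broken by the lexicographically smallest
label pair, and negative branch lengths are clamped to zero with the
deficit moved to the sibling (the pair's total is preserved), because
downstream depth logic requires non-negative lengths. On additive
matrices the algorithm is exact (verified to 1e-9 in the tests).
Neighbor joining on corrected distances was chosen over likelihood
methods deliberately: it is deterministic and desk-scale, and the
downstream stages consume only the clade structure, not branch-length
fidelity.

Bootstrap supports resample alignment columns with replacement
(default 100 replicates, seeded NumPy generator), rebuild the tree per
replicate, and annotate each internal edge with the percentage of
replicates containing the same leaf bipartition.

Clades are extracted from the midpoint-rooted tree by a depth-fraction
cut (default 0.5 of the maximum leaf depth): each leaf joins its
shallowest ancestor at or below the cut, leaves whose whole path stays
above the cut form singletons. Published family subdivisions are
typically drawn by eye; the fraction is exposed as a parameter rather
than reverse-engineered.

## Reference numbering, fingerprints, disruption

All pocket analysis is phrased in reference numbering: walking the
alignment columns where the reference row is non-gap yields, per
homolog, a strictly increasing map from reference positions to homolog
positions (or "unaligned"). A homolog's **pocket fingerprint** is the
string of its residues at the annotated pocket positions ('-' where
unaligned). Fingerprints are compared with the premetric

    d(f, g) = Σ_slots [s(a,a) + s(b,b)]/2 − s(a,b)

with a flat `gap_penalty = 8` when exactly one side is '-' and 0 when
both are (absence of evidence should not count as divergence twice).
The premetric is symmetric, zero on identical fingerprints, and
non-negative whenever `s(a,a)+s(b,b) ≥ 2 s(a,b)`, which BLOSUM62
satisfies.

**Domain disruption** models the replacement of ordered
secondary-structure regions by long flexible loops. Per annotated domain
span it measures (a) the largest run of homolog residues inserted
between consecutive mapped reference positions, and (b) the number of
reference positions with no homolog counterpart. Defaults: disrupted if
an insertion exceeds 10 residues or the unaligned count exceeds 25 % of
the span length. The thresholds are order-of-magnitude choices for
"loop-sized" restructuring, not fitted quantities.

The bundled CHI-like profile annotates 21 pocket positions
{12, 14, 29, 33, 37, 40, 41, 47, 48, 50, 69, 71, 73, 75, 79, 87, 91,
101, 122, 125, 135} with A-ring/B-ring/catalytic roles, catalytic
positions 33 (His, Michael-addition base) and 48 (Tyr, carbonyl
stabilization), and two domain spans (catalytic 1–140, solvent-exposed
141–170). Position 47 is flagged provisional: it is implicated only
through a beneficial D47E exchange, not through ligand contact. The
bundled reference *sequence* is synthetic filler around those planted
residues (a real CHI sequence is database-derived and is not shipped);
users supply their own annotation for real studies. When a structure
with a bound ligand is available, the pocket can instead be derived as
all residues with ≥1 heavy atom within 4.5 Å (inclusive) of a ligand
heavy atom — the count criterion behind a "21-residue pocket" is not
standardized, so the cutoff is exposed.

## Activity, pocket types, substrate rules

Activity prediction is categorical by design — the underlying inference
("the catalytic base is conserved, hence activity is expected") is
categorical, and pretending to probabilities would be false precision.
`likely_active` ⇔ every catalytic residue conserved at its mapped
position ∧ no domain disrupted. This is monotone: breaking a residue or
adding a disruption can never reactivate a member.

Pocket types are single-linkage clusters under the fingerprint
premetric, merging until the minimum inter-cluster distance exceeds the
threshold (default 0: exact-identity grouping). Single linkage was
chosen because families group by connectivity (branches), not by
compactness. The scipy hierarchical-clustering routines perform the
agglomeration.

Substrate rules translate qualitative pocket/substrate observations
into config: per substrate, alternative condition groups of
(position, allowed symbols, weight), an optional disallowed list, and a
threshold. A fingerprint is `incompatible` if any disallowed symbol is
present, `compatible` if some group is fully satisfied with weight sum
≥ threshold, `unknown` otherwise; the reported score is the best weight
sum over groups. The shipped table covers five chalcone substrates
(unmodified, meta/para-hydroxylated and methoxylated B-rings) with the
known hints: D/E79+N122 for the unmodified para-OH network, K87R+D47E
as the shifted hydrogen-bonding mode, small-79 or E79+G125 for
para-methoxy room. Weights and thresholds are engineering choices — no
numeric compatibility score exists to calibrate against — and the table
is data, not code.

## Representative selection and transplant design

The panel selector is greedy maximin: seed with the member whose
fingerprint is nearest the reference pocket, then repeatedly add the
member maximizing its minimum distance to the chosen set, restricted to
uncovered pocket-type clusters until every coverable cluster is
represented; distance ties prefer uncovered clades, then the smallest
id. The default panel size is the number of pocket-type clusters. The
published panels this emulates were chosen by expert judgment; maximin
coverage is the stated algorithmic substitute. Candidates are
restricted to `likely_active` members with gap-free fingerprints, so
the panel is always synthesizable and scoreable.

Pocket transplants list one substitution per slot where scaffold and
target fingerprints differ, named in reference numbering (`D79P`)
regardless of the scaffold's private numbering — the convention used
when mutant names must be comparable across homologs. Slots where the
target is '-' are reported unresolvable rather than guessed.
`apply_mutations` round-trips every proposal; the mutation count equals
the Hamming distance on resolvable slots.

## Synthetic benchmark

`ssfe.synth.simulate_family` plants: a reference (emitted unchanged);
per clade, a pocket variant written at annotated positions plus
background substitutions at non-pocket sites (per-site rate, uniform
over the 19 alternatives); and out-group members that keep the
reference pocket but carry a contiguous random insertion strictly
inside the second domain span. Background noise never touches pocket or
catalytic positions unless `noise_at_pocket` is set, separating
partition-recovery tests from robustness tests. Insertions-only
disruption mirrors loop-insertion restructuring; deletions are a
flagged option left off by default. Everything is driven by one seeded
generator: the same seed reproduces the FASTA byte-for-byte.

Default study conditions (also used by `scripts/acceptance.py` and the
end-to-end tests): 4 clade variants — reference pocket; {79P, 125G};
{47E, 79I, 87R}; {40L, 91Q, 122S} — × 15 members, background rate 0.02,
5 out-group members with 15-residue insertions. These sizes keep a full
pipeline run (alignment of 66 × ~170-residue sequences, 100 bootstrap
replicates) around two seconds on one core while leaving each recovery
task non-trivial.

What passing shows: position mapping, fingerprint extraction,
disruption detection, categorical classification, clustering, selection
and transplant design compose correctly end-to-end, and the pipeline is
byte-deterministic. What it does not show: performance on real
families, where indel structure is richer than star-within-clade
evolution, pocket positions are not noise-free, and homologs differ in
length and domain architecture. One observed artifact at some seeds:
the greedy aligner can slip a short C-terminal segment of a clade
member into out-group insertion columns, tripping the unaligned-count
criterion for that member (a false disruption positive at a rate of a
few members per hundred); the planted pocket partition itself has been
recovered exactly at every seed examined.

## Numerical and degenerate-input choices

- Newick output is canonical (children ordered by smallest descendant
  leaf label, branch lengths at 6 decimals) so serialization is
  bit-stable; parsing reports the character offset of structural
  errors.
- NJ tie detection uses only the upper triangle of Q: the two float
  evaluations of a symmetric entry can differ in the last ulp.
- Midpoint rooting breaks path-length ties by the lexicographically
  smallest leaf pair; an all-zero-length tree roots on the edge
  adjacent to the smallest leaf. Re-rooting an already midpoint-rooted
  tree preserves depths and topology.
- A clade cut at fraction 1.0 yields singleton clades; fractions must
  lie in (0, 1].
- PDB parsing is fixed-column, first model only, first alternate
  location only; contact detection compares squared distances so the
  inclusive 4.5 Å boundary is exact.
- Distance models refuse saturated pairs (p = 1) and pairs with no
  shared columns instead of emitting infinities.
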