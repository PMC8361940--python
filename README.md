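# ssfe — Sequence-Structure-Function-Evolution enzyme-family mining

`ssfe` turns a reference enzyme with an annotated substrate-binding pocket
plus a pool of candidate homolog sequences into an actionable mining
report: a phylogeny of the family, per-homolog active-pocket fingerprints
in reference numbering, categorical activity predictions, pocket-type
clusters, a diversity-maximizing panel of representatives to synthesize,
and pocket-transplant mutation proposals for a chosen scaffold.

It is written for enzyme-discovery work of the kind done on bacterial
chalcone isomerases (CHIs) — the enzymes that cyclize chalcones to
(S)-flavanones via an intramolecular Michael addition — and ships a
CHI-like reference profile: catalytic base His33 and carbonyl-stabilizing
Tyr48, an A-ring binding shell (I12, V14, I29, F50, E69, T71, Q101, F135),
a B-ring shell (S37, Q40, F41, H73, W75, D79, K87, E91, N122, R125) and
the provisional position 47. The reference *sequence* bundled with this
profile is a synthetic scaffold carrying those residues at those
positions; real studies supply their own reference FASTA/annotation.

## Method

The pipeline runs four stages:

1. **Sequence** — progressive multiple alignment (BLOSUM62, affine gaps
   `open=11`, `extend=1`, sum-of-pairs profile merges over a
   neighbor-joining guide tree), Poisson-corrected distances
   `d = -ln(1 - p)`, a neighbor-joining tree with bootstrap supports,
   midpoint rooting, and a depth-fraction clade cut.
2. **Structure** — reference positions are mapped through the alignment
   onto every homolog (reference numbering); each homolog's pocket
   fingerprint is extracted, and domain disruption is detected as long
   insertions (> 10 residues) or unalignable stretches (> 25 % of a
   domain span) inside an annotated domain. Optionally the pocket can be
   derived from a structure as all residues with a heavy atom within
   4.5 Å of a bound ligand.
3. **Function** — a homolog is `likely_active` iff every catalytic
   residue is conserved at its mapped position and no domain is
   disrupted; fingerprints are grouped into pocket types by
   single-linkage clustering under a substitution-matrix premetric
   `d = Σ [s(a,a)+s(b,b)]/2 − s(a,b)`; editable substrate rules score
   compatibility hints (e.g. a small residue at 79 admits a para-methoxy
   B-ring).
4. **Evolution** — a greedy maximin panel (seeded at the member nearest
   the reference pocket, every pocket type covered before any is
   repeated) and pocket-transplant mutation sets (`D79P`, `K87R`, ...)
   that convert the scaffold fingerprint into each pocket type.

A synthetic-family generator (`ssfe.synth`) plants clades, pocket types
and loop-disrupted out-groups with machine-readable ground truth, so the
whole pipeline is testable without any database access.

## Worked example

```bash
ssfe simulate --out-dir demo/family --members-per-clade 4 --outgroup-count 2 --seed 17
ssfe run --homologs demo/family/family.fasta --out-dir demo/out --bootstrap 50 --seed 17
```

prints (stderr):

```
simulate: 19 sequences -> demo/family/family.fasta
input: 18 homologs + reference (0.0s)
align: 185 columns (0.3s)
tree: 19 clades at cut 0.5 (0.3s)
fingerprint: 18 members (0.3s)
classify: 4 pocket-type clusters (0.3s)
design: 4 representatives, 3 transplant sets (0.3s)
run: 18 members, 4 pocket types, 4 representatives -> demo/out
```

The 18 homologs fall into 4 pocket-type clusters (the 4 planted clade
variants); both out-group members are flagged disrupted and predicted
inactive; one representative per pocket type is selected. The mutation
table proposes the transplants that convert the reference pocket into
each non-reference pocket type:

```
source    scaffold_id  target_member  mutations        unresolvable_positions
cluster2  CHI_ref      C2_01          D79P,R125G       .
cluster3  CHI_ref      C3_01          D47E,D79I,K87R   .
cluster4  CHI_ref      C4_01          Q40L,E91Q,N122S  .
```

i.e. reaching pocket type 2 from the reference requires the
aspartate→proline exchange at 79 plus arginine→glycine at 125. The
per-member `report.tsv` carries, for each homolog: clade, fingerprint,
catalytic-residue status, disruption flag, distance to the reference
pocket, predicted class, cluster, per-substrate verdicts
(`compatible:1.00`, `incompatible:0.00`, ...) and a representative flag.

The same stages are available as subcommands (`align`, `tree`,
`fingerprint`, `classify`, `design`) and as library functions
(`ssfe.build_msa`, `ssfe.nj_tree`, `ssfe.extract_fingerprint`,
`ssfe.cluster_pocket_types`, `ssfe.select_representatives`,
`ssfe.propose_mutations`, ...).

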