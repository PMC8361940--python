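"""Synthetic enzyme families with planted clades, pocket types and out-groups.

The generator emulates the population structure the mining pipeline
presupposes: a reference enzyme, clades of homologs that share a
clade-specific pocket variant written at the annotated positions,
background substitutions everywhere else, and an out-group whose second
(solvent-exposed) domain is restructured by a long loop insertion. The
planted clade, pocket-type and disruption assignments are returned as a
machine-readable truth table so every pipeline stage can be scored
without external data. Background noise never touches pocket or
catalytic positions unless explicitly requested, which keeps
partition-recovery tests separate from robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    Residue,
    SequenceRecord,
    StructureModel,
    write_fasta,
    write_tsv,
)
from .pocket import ReferenceAnnotation

# Default study conditions: 4 clades x 15 members, 2% background
# substitution rate off-pocket, 5 out-group members carrying a 15-residue
# loop insertion in the second domain span.
DEFAULT_N_PER_CLADE = 15
DEFAULT_BACKGROUND_RATE = 0.02
DEFAULT_OUTGROUP_COUNT = 5
DEFAULT_INSERTION_LENGTH = 15

# Clade pocket variants (reference numbering). Clade 1 keeps the reference
# pocket; the others carry the residue exchanges observed to retarget the
# B-ring binding site (small/long residues at 79, the 87R+47E hydrogen-bond
# shift, 125G for methoxy room), always preserving the catalytic H33/Y48.
DEFAULT_CLADE_VARIANTS: tuple[dict[int, str], ...] = (
    {},
    {79: "P", 125: "G"},
    {47: "E", 79: "I", 87: "R"},
    {40: "L", 91: "Q", 122: "S"},
)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family."""

    clade_variants: tuple[dict[int, str], ...] = DEFAULT_CLADE_VARIANTS
    members_per_clade: int = DEFAULT_N_PER_CLADE
    background_rate: float = DEFAULT_BACKGROUND_RATE
    outgroup_count: int = DEFAULT_OUTGROUP_COUNT
    insertion_length: int = DEFAULT_INSERTION_LENGTH
    seed: int = 0
    noise_at_pocket: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate must be in [0, 1)")
        if self.members_per_clade < 1 or not self.clade_variants:
            raise ValueError("need at least one clade with at least one member")
        if self.outgroup_count < 0 or self.insertion_length < 0:
            raise ValueError("outgroup_count and insertion_length must be non-negative")
        for variant in self.clade_variants:
            for pos, sym in variant.items():
                if sym not in AMINO_ACIDS:
                    raise ValueError(f"pocket variant symbol {sym!r} at {pos} is not an amino acid")


@dataclass(frozen=True)
class TruthEntry:
    clade_id: str
    pocket_type: str
    disrupted: bool


@dataclass(frozen=True)
class TruthTable:
    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def pocket_partition(self) -> dict[str, list[str]]:
        """Pocket type -> sorted member ids (reference included)."""
        out: dict[str, list[str]] = {}
        for member, entry in self.entries.items():
            out.setdefault(entry.pocket_type, []).append(member)
        return {k: sorted(v) for k, v in out.items()}

    def disrupted_members(self) -> set[str]:
        return {m for m, e in self.entries.items() if e.disrupted}


def simulate_family(
    spec: FamilySpec, annotation: ReferenceAnnotation
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate the family; deterministic given ``spec.seed``.

    The reference is emitted unchanged as the first record. Out-group
    members keep the reference pocket but receive a contiguous insertion
    of random residues at a random site inside the second domain span.
    """
    for variant in spec.clade_variants:
        bad = set(variant) - set(annotation.positions)
        if bad:
            raise ValueError(f"variant positions {sorted(bad)} not in the pocket annotation")
    if spec.outgroup_count > 0 and len(annotation.domain_spans) < 2:
        raise ValueError("out-group insertions require a second domain span")

    rng = np.random.default_rng(spec.seed)
    ref_seq = annotation.ref_sequence
    n = len(ref_seq)
    pocket_set = set(annotation.positions)
    mutable_sites = np.array(
        [i for i in range(n) if spec.noise_at_pocket or (i + 1) not in pocket_set],
        dtype=np.int64,
    )
    alphabet = np.array(list(AMINO_ACIDS))

    # pocket-type ids by first appearance of each variant signature
    type_ids: dict[tuple[tuple[int, str], ...], str] = {}

    def type_of(variant: dict[int, str]) -> str:
        sig = tuple(sorted(variant.items()))
        if sig not in type_ids:
            type_ids[sig] = f"P{len(type_ids) + 1}"
        return type_ids[sig]

    records: list[SequenceRecord] = [
        SequenceRecord(annotation.ref_id, annotation.ref_description, ref_seq)
    ]
    truth: dict[str, TruthEntry] = {
        annotation.ref_id: TruthEntry("reference", type_of({}), False)
    }

    def background(seq: list[str]) -> None:
        if spec.background_rate == 0.0 or mutable_sites.size == 0:
            return
        hits = mutable_sites[rng.random(mutable_sites.size) < spec.background_rate]
        for i in hits:
            current = seq[i]
            choices = [a for a in AMINO_ACIDS if a != current]
            seq[i] = choices[int(rng.integers(0, len(choices)))]

    for c, variant in enumerate(spec.clade_variants, start=1):
        ptype = type_of(variant)
        for m in range(1, spec.members_per_clade + 1):
            seq = list(ref_seq)
            for pos, sym in variant.items():
                seq[pos - 1] = sym
            background(seq)
            member_id = f"C{c}_{m:02d}"
            records.append(
                SequenceRecord(member_id, f"synthetic clade {c} member", "".join(seq))
            )
            truth[member_id] = TruthEntry(f"C{c}", ptype, False)

    ref_type = type_of({})
    for m in range(1, spec.outgroup_count + 1):
        span = annotation.domain_spans[1]
        seq = list(ref_seq)
        background(seq)
        # insert after this reference position; kept strictly inside the span
        # so the inserted run sits between two mappable reference positions
        site = int(rng.integers(span.start, span.end))
        insert = "".join(alphabet[rng.integers(0, len(alphabet), size=spec.insertion_length)])
        full = "".join(seq[:site]) + insert + "".join(seq[site:])
        member_id = f"OG_{m:02d}"
        records.append(
            SequenceRecord(member_id, "synthetic out-group member (loop insertion)", full)
        )
        truth[member_id] = TruthEntry("outgroup", ref_type, True)

    return records, TruthTable(truth)


def write_family(
    records: list[SequenceRecord],
    truth: TruthTable,
    annotation: ReferenceAnnotation,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit family FASTA, truth TSV and the annotation config used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "family.fasta",
        "truth": out / "truth.tsv",
        "annotation": out / "annotation.yaml",
    }
    write_fasta(records, paths["fasta"])
    write_tsv(
        paths["truth"],
        ["member_id", "clade_id", "pocket_type", "disrupted"],
        [
            [m, e.clade_id, e.pocket_type, int(e.disrupted)]
            for m, e in truth.entries.items()
        ],
    )
    annotation.to_yaml(paths["annotation"])
    return paths


def make_toy_structure(
    n_residues: int, ligand_offsets: list[float], ligand_name: str = "LIG"
) -> StructureModel:
    """Deterministic line-of-residues structure for contact-geometry tests.

    Residues sit on the x-axis 5 A apart with a single CA atom each;
    one ligand atom is placed at each requested distance from residue 1
    (on the negative x-axis, away from the other residues).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if any(off < 0 for off in ligand_offsets):
        raise ValueError("ligand offsets must be non-negative")
    residues = [
        Residue("A", i, "ALA", [("CA", 5.0 * (i - 1), 0.0, 0.0)])
        for i in range(1, n_residues + 1)
    ]
    ligands = []
    if ligand_offsets:
        atoms = [(f"C{k + 1}", -float(off), 0.0, 0.0) for k, off in enumerate(ligand_offsets)]
        ligands.append(Residue("A", 900, ligand_name, atoms))
    return StructureModel(residues=residues, ligands=ligands)
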