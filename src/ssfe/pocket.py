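"""Reference pocket definition, position mapping, fingerprints, disruption.

Everything downstream of the alignment speaks *reference numbering*: a
homolog residue is named by the position of the reference residue it
aligns with. The pocket fingerprint of a homolog is the ordered string of
symbols it presents at the reference's annotated pocket positions ('-'
where the reference position falls in a gap of the homolog). Domain
disruption — long loop insertions or unalignable stretches inside an
annotated domain span — is the structural-integrity signal used to rule
out members whose fold has been restructured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .alignment import GAP, MultipleAlignment, SubstitutionMatrix
from .io_formats import StructureModel

DEFAULT_CONTACT_CUTOFF = 4.5  # Angstrom, heavy atoms, inclusive
DEFAULT_MAX_INSERT = 10
DEFAULT_MAX_UNALIGNED_FRACTION = 0.25
DEFAULT_FINGERPRINT_GAP_PENALTY = 8.0


@dataclass(frozen=True)
class PocketPosition:
    position: int
    residue: str
    role: str
    provisional: bool = False


@dataclass(frozen=True)
class DomainSpan:
    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PocketFingerprint:
    """Ordered residue symbols of one member at the annotated pocket positions."""

    member_id: str
    symbols: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.positions):
            raise ValueError("fingerprint length does not match position count")

    def symbol_at(self, position: int) -> str:
        return self.symbols[self.positions.index(position)]

    @property
    def gap_free(self) -> bool:
        return GAP not in self.symbols


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Reference enzyme: sequence, catalytic/pocket positions, domain spans."""

    ref_id: str
    ref_description: str
    ref_sequence: str
    catalytic: tuple[PocketPosition, ...]
    pocket_positions: tuple[PocketPosition, ...]
    domain_spans: tuple[DomainSpan, ...]

    def __post_init__(self) -> None:
        n = len(self.ref_sequence)
        pocket_by_pos = {p.position: p for p in self.pocket_positions}
        if len(pocket_by_pos) != len(self.pocket_positions):
            raise ValueError("duplicate pocket positions in annotation")
        for p in list(self.pocket_positions) + list(self.catalytic):
            if not 1 <= p.position <= n:
                raise ValueError(f"position {p.position} outside reference (length {n})")
            if self.ref_sequence[p.position - 1] != p.residue:
                raise ValueError(
                    f"annotation says {p.residue} at {p.position} but reference has "
                    f"{self.ref_sequence[p.position - 1]}"
                )
        for c in self.catalytic:
            if c.position not in pocket_by_pos:
                raise ValueError(f"catalytic position {c.position} not among pocket positions")
        for span in self.domain_spans:
            if not 1 <= span.start <= span.end <= n:
                raise ValueError(f"domain span {span.label!r} outside reference")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p.position for p in self.pocket_positions)

    def reference_fingerprint(self) -> PocketFingerprint:
        return PocketFingerprint(
            self.ref_id,
            "".join(self.ref_sequence[p - 1] for p in self.positions),
            self.positions,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceAnnotation":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "ReferenceAnnotation":
        ref = doc["reference"]
        pocket = tuple(
            sorted(
                (
                    PocketPosition(
                        int(row["position"]),
                        str(row["residue"]),
                        str(row["role"]),
                        bool(row.get("provisional", False)),
                    )
                    for row in doc["pocket"]
                ),
                key=lambda p: p.position,
            )
        )
        catalytic = tuple(
            sorted(
                (
                    PocketPosition(int(row["position"]), str(row["residue"]), str(row["role"]))
                    for row in doc["catalytic"]
                ),
                key=lambda p: p.position,
            )
        )
        spans = tuple(
            DomainSpan(str(row["label"]), int(row["start"]), int(row["end"]))
            for row in doc.get("domains", [])
        )
        return cls(
            ref_id=str(ref["id"]),
            ref_description=str(ref.get("description", "")),
            ref_sequence=str(ref["sequence"]).upper(),
            catalytic=catalytic,
            pocket_positions=pocket,
            domain_spans=spans,
        )

    @classmethod
    def default(cls) -> "ReferenceAnnotation":
        """The bundled CHI-like profile (synthetic reference scaffold)."""
        with resources.files("ssfe.data").joinpath("chi_reference_synthetic.yaml").open() as fh:
            return cls._from_doc(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "reference": {
                "id": self.ref_id,
                "description": self.ref_description,
                "sequence": self.ref_sequence,
            },
            "catalytic": [
                {"position": p.position, "residue": p.residue, "role": p.role}
                for p in self.catalytic
            ],
            "pocket": [
                {
                    "position": p.position,
                    "residue": p.residue,
                    "role": p.role,
                    **({"provisional": True} if p.provisional else {}),
                }
                for p in self.pocket_positions
            ],
            "domains": [
                {"label": s.label, "start": s.start, "end": s.end} for s in self.domain_spans
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class PositionMap:
    """Reference position -> homolog position (1-based), or None if unaligned."""

    ref_id: str
    member_id: str
    mapping: dict[int, int | None]

    def __post_init__(self) -> None:
        mapped = [v for v in self.mapping.values() if v is not None]
        if any(b <= a for a, b in zip(mapped, mapped[1:])):
            raise ValueError("position map must be strictly increasing over mapped positions")

    def __getitem__(self, ref_pos: int) -> int | None:
        return self.mapping[ref_pos]


@dataclass(frozen=True)
class DomainStats:
    max_insertion: int
    unaligned: int
    span_length: int
    exceeded: bool


@dataclass(frozen=True)
class DisruptionReport:
    member_id: str
    domains: dict[str, DomainStats] = field(default_factory=dict)

    @property
    def disrupted(self) -> bool:
        return any(s.exceeded for s in self.domains.values())


def build_position_map(msa: MultipleAlignment, ref_id: str, member_id: str) -> PositionMap:
    """Walk MSA columns and map reference numbering onto one member."""
    ref_row = msa.row(ref_id)
    mem_row = msa.row(member_id)
    mapping: dict[int, int | None] = {}
    ref_pos = mem_pos = 0
    for ref_c, mem_c in zip(ref_row, mem_row):
        if mem_c != GAP:
            mem_pos += 1
        if ref_c != GAP:
            ref_pos += 1
            mapping[ref_pos] = mem_pos if mem_c != GAP else None
    return PositionMap(ref_id, member_id, mapping)


def extract_fingerprint(
    msa: MultipleAlignment, annotation: ReferenceAnnotation, member_id: str
) -> PocketFingerprint:
    """Member residues at the annotated pocket positions, reference-numbered."""
    pm = build_position_map(msa, annotation.ref_id, member_id)
    residues = msa.row(member_id).replace(GAP, "")
    symbols = []
    for pos in annotation.positions:
        mapped = pm[pos]
        symbols.append(GAP if mapped is None else residues[mapped - 1])
    return PocketFingerprint(member_id, "".join(symbols), annotation.positions)


def fingerprint_distance(
    f1: PocketFingerprint,
    f2: PocketFingerprint,
    matrix: SubstitutionMatrix,
    gap_penalty: float = DEFAULT_FINGERPRINT_GAP_PENALTY,
) -> float:
    """Symmetric premetric between fingerprints.

    Per slot: ``[s(a,a) + s(b,b)] / 2 - s(a,b)`` (0 for identical symbols),
    ``gap_penalty`` when exactly one side is '-', 0 when both are.
    """
    if f1.positions != f2.positions:
        raise ValueError("fingerprints cover different pocket positions")
    total = 0.0
    for a, b in zip(f1.symbols, f2.symbols):
        if a == GAP and b == GAP:
            continue
        if a == GAP or b == GAP:
            total += gap_penalty
        else:
            total += 0.5 * (matrix.score(a, a) + matrix.score(b, b)) - matrix.score(a, b)
    return total


def detect_disruption(
    msa: MultipleAlignment,
    annotation: ReferenceAnnotation,
    member_id: str,
    max_insert: int = DEFAULT_MAX_INSERT,
    max_unaligned: int | None = None,
) -> DisruptionReport:
    """Flag members whose domains carry long insertions or unalignable runs.

    ``max_unaligned=None`` uses 25% of each span's length as the limit.
    """
    if not annotation.domain_spans:
        raise ValueError("annotation has no domain spans")
    pm = build_position_map(msa, annotation.ref_id, member_id)
    domains: dict[str, DomainStats] = {}
    for span in annotation.domain_spans:
        mapped = [
            pm[pos] for pos in range(span.start, span.end + 1) if pm[pos] is not None
        ]
        unaligned = span.length - len(mapped)
        max_ins = 0
        for a, b in zip(mapped, mapped[1:]):
            max_ins = max(max_ins, b - a - 1)
        limit = (
            float(max_unaligned)
            if max_unaligned is not None
            else DEFAULT_MAX_UNALIGNED_FRACTION * span.length
        )
        exceeded = max_ins > max_insert or unaligned > limit
        domains[span.label] = DomainStats(max_ins, unaligned, span.length, exceeded)
    return DisruptionReport(member_id, domains)


def _heavy(atom_name: str) -> bool:
    stripped = atom_name.lstrip("0123456789")
    return not stripped.upper().startswith("H")


def pocket_from_structure(
    structure: StructureModel, ligand_name: str, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list[int]:
    """Residue numbers with a heavy atom within ``cutoff`` of the named ligand.

    The boundary is inclusive; hydrogens (atom names starting with H after
    leading digits) are ignored on both sides.
    """
    matches = [lig for lig in structure.ligands if lig.name == ligand_name]
    if not matches:
        raise ValueError(f"ligand {ligand_name!r} not found in structure")
    if len(matches) > 1:
        where = ", ".join(f"{lig.chain}/{lig.number}" for lig in matches)
        raise ValueError(f"multiple ligands named {ligand_name!r}: {where}")
    lig_xyz = np.array(
        [(x, y, z) for name, x, y, z in matches[0].atoms if _heavy(name)], dtype=np.float64
    )
    if lig_xyz.size == 0:
        return []
    cutoff_sq = float(cutoff) ** 2
    hits: list[int] = []
    for res in structure.residues:
        xyz = np.array(
            [(x, y, z) for name, x, y, z in res.atoms if _heavy(name)], dtype=np.float64
        )
        if xyz.size == 0:
            continue
        d2 = ((xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
        if float(d2.min()) <= cutoff_sq:
            hits.append(res.number)
    return sorted(set(hits))

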