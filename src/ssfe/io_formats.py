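"""Readers and writers for the formats the pipeline touches.

FASTA and minimal fixed-column PDB parsing is done in-house rather than
through a lenient third-party parser because the pipeline promises precise,
line-numbered diagnostics (duplicate ids, illegal residue symbols, broken
coordinate fields) and a strict byte-level round trip for canonically
wrapped FASTA. Newick serialization is canonical: children are ordered by
their smallest descendant leaf label and branch lengths are emitted with
six decimals, so the same tree always serializes to the same bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .treemodel import PhyloTree, TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP_CHARS = frozenset("-.")

FASTA_WRAP = 60


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence: identifier, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a whitespace-free token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid symbols: {sorted(bad)}"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a multi-FASTA file into records, preserving file order.

    Residues are upper-cased and concatenated across wrapped lines; gap
    characters ('-', '.') are stripped so pre-aligned input is accepted and
    re-aligned by the pipeline. Duplicate ids and residue symbols outside
    the twenty amino acids plus X are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: tuple[str, str] | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq_id, desc = header
        records.append(SequenceRecord(seq_id, desc, "".join(chunks)))
        header, chunks = None, []

    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                seq_id = parts[0]
                if seq_id in seen:
                    raise FormatError(f"line {lineno}: duplicate sequence id {seq_id!r}")
                seen.add(seq_id)
                header = (seq_id, parts[1] if len(parts) > 1 else "")
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence data before first header")
                piece = "".join(c for c in line.upper() if c not in GAP_CHARS)
                bad = set(piece) - ALLOWED_RESIDUES
                if bad:
                    raise FormatError(
                        f"line {lineno}: non-amino-acid symbols {sorted(bad)}"
                    )
                chunks.append(piece)
    flush()
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, *, wrap: int = FASTA_WRAP) -> None:
    """Write records wrapped at ``wrap`` columns (the canonical layout)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write(format_fasta(records, wrap=wrap))


def format_fasta(records: list[SequenceRecord], *, wrap: int = FASTA_WRAP) -> str:
    lines: list[str] = []
    for rec in records:
        head = f">{rec.id}"
        if rec.description:
            head += f" {rec.description}"
        lines.append(head)
        for i in range(0, len(rec.residues), wrap):
            lines.append(rec.residues[i : i + wrap])
    return "\n".join(lines) + "\n"


def write_aligned_fasta(rows: list[tuple[str, str]], path: str | Path, *, wrap: int = FASTA_WRAP) -> None:
    """FASTA-with-gaps writer for alignments (rows of (id, aligned string))."""
    with open(path, "w", encoding="ascii") as fh:
        for rid, aligned in rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(aligned), wrap):
                fh.write(aligned[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Minimal PDB

@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)


@dataclass
class StructureModel:
    """Coordinates of polymer residues and non-polymer (ligand) groups."""

    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)


def read_pdb_minimal(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM coordinate records from a PDB file.

    First model only; alternate locations resolved by keeping the first
    occurrence of each (chain, residue number, atom name). Residue numbers
    must be strictly increasing within a chain.
    """
    model = StructureModel()
    groups: dict[tuple[str, str, int, str], Residue] = {}
    seen_atoms: set[tuple[str, int, str, str]] = set()
    n_records = 0
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            n_records += 1
            atom_name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain = line[21:22].strip() or "A"
            try:
                res_num = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unparseable coordinate field ({exc})") from None
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise FormatError(f"line {lineno}: non-finite coordinate")
            key = (chain, res_num, atom_name, rec)
            if key in seen_atoms:  # first altloc wins
                continue
            seen_atoms.add(key)
            gkey = (rec, chain, res_num, res_name)
            if gkey not in groups:
                groups[gkey] = Residue(chain, res_num, res_name)
                target = model.residues if rec == "ATOM" else model.ligands
                target.append(groups[gkey])
            groups[gkey].atoms.append((atom_name, x, y, z))
    if n_records == 0:
        raise FormatError(f"{path}: no coordinate records found")
    last: dict[str, int] = {}
    for res in model.residues:
        if res.chain in last and res.number <= last[res.chain]:
            raise FormatError(
                f"residue numbers not strictly increasing in chain {res.chain!r} at {res.number}"
            )
        last[res.chain] = res.number
    return model


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree: PhyloTree) -> str:
    """Canonical Newick text: sorted children, 6-decimal branch lengths."""
    tree = tree.copy()
    tree.canonicalize()

    def render(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            inner = ",".join(render(c, False) for c in node.children)
            body = f"({inner})"
            if node.support is not None:
                body += f"{node.support:g}"
        if top:
            return body
        return f"{body}:{node.length:.6f}"

    return render(tree.root, True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick text; reports the character offset of structural errors."""
    pos = 0
    n = len(text)

    def error(msg: str, at: int) -> FormatError:
        return FormatError(f"newick error at offset {at}: {msg}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < n and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos].strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        skip_ws()
        node = TreeNode()
        if pos < n and text[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.add_child(parse_node())
                skip_ws()
                if pos >= n:
                    raise error("unclosed '('", open_at)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected {text[pos]!r}", pos)
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            label = parse_label()
            if not label:
                raise error("expected leaf label", pos)
            node.label = label
        if pos < n and text[pos] == ":":
            pos += 1
            start = pos
            while pos < n and text[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise error("bad branch length", start) from None
        return node

    root = parse_node()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise error("expected ';'", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise error("trailing characters", pos)
    if root.is_leaf:
        raise error("tree must have at least 2 leaves", 0)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted).canonicalize()


# ---------------------------------------------------------------------------
# TSV

def write_tsv(path: str | Path, header: list[str], rows: list[list[object]]) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="ascii") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise FormatError(f"{path}: empty TSV")
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:]]
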