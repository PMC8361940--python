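"""Pairwise and progressive multiple alignment plus corrected distances.

The scoring model is classical: a substitution matrix (BLOSUM62 by default,
taken from Biopython's bundled tables) with affine gap costs where a gap of
length L costs ``gap_open + (L - 1) * gap_extend`` and terminal gaps are
penalized. Multiple alignment is progressive: pairwise p-distances feed a
neighbor-joining guide tree, and profiles are merged from the leaves to the
root with sum-of-pairs column scoring under the same gap model. All tie
rules are fixed, so alignments are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import affine_dp
from .io_formats import FormatError, SequenceRecord

GAP = "-"
_GAP_BYTE = ord(GAP)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


class SubstitutionMatrix:
    """Symmetric residue-pair scores over a fixed alphabet."""

    def __init__(self, alphabet: str, scores: np.ndarray, name: str = "") -> None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution scores must be symmetric")
        self.alphabet = alphabet
        self.scores = scores
        self.name = name
        self._index = {sym: i for i, sym in enumerate(alphabet)}

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._idx(a), self._idx(b)])

    def _idx(self, sym: str) -> int:
        try:
            return self._index[sym]
        except KeyError:
            raise ValueError(f"symbol {sym!r} not in matrix alphabet") from None

    def encode(self, residues: str) -> np.ndarray:
        return np.array([self._idx(c) for c in residues], dtype=np.int64)

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        alphabet = str(mat.alphabet)
        return cls(alphabet, np.asarray(mat, dtype=np.float64), name="BLOSUM62")

    @classmethod
    def identity(cls, alphabet: str, match: float = 1.0, mismatch: float = 0.0) -> "SubstitutionMatrix":
        n = len(alphabet)
        scores = np.full((n, n), mismatch, dtype=np.float64)
        np.fill_diagonal(scores, match)
        return cls(alphabet, scores, name="identity")

    @classmethod
    def from_ncbi_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read a matrix in NCBI text layout (header row of symbols, one row per symbol)."""
        symbols: list[str] = []
        rows: list[list[float]] = []
        row_syms: list[str] = []
        with open(path, encoding="ascii") as fh:
            for line in fh:
                line = line.rstrip()
                if not line or line.lstrip().startswith("#"):
                    continue
                parts = line.split()
                if not symbols:
                    if any(len(p) != 1 for p in parts):
                        raise FormatError(f"{path}: malformed matrix header")
                    symbols = parts
                    continue
                row_syms.append(parts[0])
                rows.append([float(v) for v in parts[1 : len(symbols) + 1]])
        if not symbols or row_syms != symbols:
            raise FormatError(f"{path}: matrix rows do not match header symbols")
        return cls("".join(symbols), np.array(rows), name=Path(path).name)


_BLOSUM62: SubstitutionMatrix | None = None


def blosum62() -> SubstitutionMatrix:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = SubstitutionMatrix.blosum62()
    return _BLOSUM62


@dataclass
class MultipleAlignment:
    """Rows of (id, aligned string); every row has the same column count."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0][1])
        for rid, aligned in self.rows:
            if len(aligned) != ncol:
                raise ValueError(f"row {rid!r} has {len(aligned)} columns, expected {ncol}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, aligned in self.rows:
            if r == rid:
                return aligned
        raise KeyError(f"id {rid!r} not in alignment")

    def encoded(self) -> np.ndarray:
        """(rows, cols) uint8 byte matrix; the gap symbol is ``ord('-')``."""
        return np.frombuffer(
            "".join(a for _, a in self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.rows), self.ncol)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def global_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps; deterministic traceback."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if gap_open < 0 or gap_extend < 0 or gap_extend > gap_open:
        raise ValueError("require 0 <= gap_extend <= gap_open")
    matrix = matrix or blosum62()
    ia = matrix.encode(a)
    ib = matrix.encode(b)
    S = matrix.scores[np.ix_(ia, ib)]
    score, ops = affine_dp(S, float(gap_open), float(gap_extend))
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for op in ops:
        if op == 0:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            out_a.append(a[i])
            out_b.append(GAP)
            i += 1
        else:
            out_a.append(GAP)
            out_b.append(b[j])
            j += 1
    return "".join(out_a), "".join(out_b), float(score)


class _Profile:
    """Alignment slice during progressive merging: ids + aligned rows."""

    __slots__ = ("ids", "rows")

    def __init__(self, ids: list[str], rows: list[str]) -> None:
        self.ids = ids
        self.rows = rows

    def counts(self, matrix: SubstitutionMatrix) -> np.ndarray:
        """(cols, |alphabet|) residue counts per column; gaps contribute nothing."""
        ncol = len(self.rows[0])
        counts = np.zeros((ncol, len(matrix.alphabet)), dtype=np.float64)
        for row in self.rows:
            arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
            mask = arr != _GAP_BYTE
            idx = matrix.encode(row.replace(GAP, "")) if mask.any() else np.empty(0, np.int64)
            counts[np.nonzero(mask)[0], idx] += 1.0
        return counts


def _merge_profiles(
    pa: _Profile, pb: _Profile, matrix: SubstitutionMatrix, gap_open: float, gap_extend: float
) -> _Profile:
    ca = pa.counts(matrix)
    cb = pb.counts(matrix)
    S = (ca @ matrix.scores) @ cb.T
    scale = float(len(pa.rows) * len(pb.rows))
    _, ops = affine_dp(S, gap_open * scale, gap_extend * scale)
    rows_a: list[list[str]] = [[] for _ in pa.rows]
    rows_b: list[list[str]] = [[] for _ in pb.rows]
    i = j = 0
    for op in ops:
        if op == 0:
            for k, row in enumerate(pa.rows):
                rows_a[k].append(row[i])
            for k, row in enumerate(pb.rows):
                rows_b[k].append(row[j])
            i += 1
            j += 1
        elif op == 1:
            for k, row in enumerate(pa.rows):
                rows_a[k].append(row[i])
            for k in range(len(pb.rows)):
                rows_b[k].append(GAP)
            i += 1
        else:
            for k in range(len(pa.rows)):
                rows_a[k].append(GAP)
            for k, row in enumerate(pb.rows):
                rows_b[k].append(row[j])
            j += 1
    return _Profile(
        pa.ids + pb.ids,
        ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
    )


def _pair_p_distance(aligned_a: str, aligned_b: str) -> float:
    xa = np.frombuffer(aligned_a.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(aligned_b.encode("ascii"), dtype=np.uint8)
    both = (xa != _GAP_BYTE) & (xb != _GAP_BYTE)
    compared = int(both.sum())
    if compared == 0:
        return 1.0
    return float(((xa != xb) & both).sum()) / compared


def build_msa(
    seqs: list[SequenceRecord],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Progressive multiple alignment over a neighbor-joining guide tree.

    Row order equals input order regardless of the merge order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for an alignment")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dup}")
    matrix = matrix or blosum62()

    if len(seqs) == 2:
        aa, ab, _ = global_align(seqs[0].residues, seqs[1].residues, matrix, gap_open, gap_extend)
        return MultipleAlignment([(ids[0], aa), (ids[1], ab)])

    from .phylogeny import midpoint_root, nj_tree  # local import: phylogeny also uses this module

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aa, ab, _ = global_align(seqs[i].residues, seqs[j].residues, matrix, gap_open, gap_extend)
            dist[i, j] = dist[j, i] = _pair_p_distance(aa, ab)
    guide = midpoint_root(nj_tree(DistanceMatrix(ids, dist)))
    guide.canonicalize()

    by_id = {s.id: s for s in seqs}

    def merge(node) -> _Profile:
        if node.is_leaf:
            rec = by_id[node.label]
            return _Profile([rec.id], [rec.residues])
        prof = merge(node.children[0])
        for child in node.children[1:]:
            prof = _merge_profiles(prof, merge(child), matrix, gap_open, gap_extend)
        return prof

    prof = merge(guide.root)
    order = {rid: k for k, rid in enumerate(prof.ids)}
    rows = [(rid, prof.rows[order[rid]]) for rid in ids]
    msa = MultipleAlignment(rows)
    for rec in seqs:  # degap contract
        assert msa.row(rec.id).replace(GAP, "") == rec.residues
    return msa


def distance_matrix(msa: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise p-distances over shared (both non-gap) columns.

    ``model="p"`` returns the raw proportion of mismatches; ``"poisson"``
    applies the multiple-hit correction ``-ln(1 - p)``.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    arr = msa.encoded()
    nong = arr != _GAP_BYTE
    compared = (nong.astype(np.int64) @ nong.T.astype(np.int64))
    neq = (arr[:, None, :] != arr[None, :, :]) & nong[:, None, :] & nong[None, :, :]
    mism = neq.sum(axis=2)
    n = len(msa.rows)
    labels = msa.ids
    for i in range(n):
        for j in range(i + 1, n):
            if compared[i, j] == 0:
                raise ValueError(
                    f"no shared non-gap columns between {labels[i]!r} and {labels[j]!r}"
                )
    p = mism / compared
    if model == "p":
        d = p
    else:
        if np.any(p[np.triu_indices(n, 1)] >= 1.0):
            i, j = next(
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if p[i, j] >= 1.0
            )
            raise ValueError(
                f"poisson distance infinite between {labels[i]!r} and {labels[j]!r} (p = 1)"
            )
        d = -np.log1p(-p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, (d + d.T) / 2.0)
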