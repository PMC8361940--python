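"""Representative panel selection and pocket-transplant mutation design.

The panel selector emulates how one would pick a diverse set of family
members for synthesis and screening: greedy maximin over fingerprint
distances, seeded at the member closest to the reference pocket, with the
constraint that every pocket-type cluster is covered before any cluster
gets a second representative, and clade coverage used as the tie-break.

A pocket transplant converts the scaffold's fingerprint into a target
fingerprint: one substitution per differing slot, named in reference
numbering (e.g. ``D79P``) regardless of the scaffold's own numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import GAP, SubstitutionMatrix
from .classify import PocketTypeCluster
from .phylogeny import CladePartition
from .pocket import (
    DEFAULT_FINGERPRINT_GAP_PENALTY,
    PocketFingerprint,
    fingerprint_distance,
)


@dataclass(frozen=True)
class Mutation:
    position: int
    from_symbol: str
    to_symbol: str

    def __str__(self) -> str:
        return f"{self.from_symbol}{self.position}{self.to_symbol}"


@dataclass(frozen=True)
class MutationSet:
    scaffold_id: str
    mutations: tuple[Mutation, ...]
    unresolvable: tuple[int, ...]
    source: str = ""

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("mutations must be in strictly increasing position order")
        for m in self.mutations:
            if m.from_symbol == m.to_symbol:
                raise ValueError(f"null mutation at position {m.position}")

    def __len__(self) -> int:
        return len(self.mutations)

    def __str__(self) -> str:
        return ",".join(str(m) for m in self.mutations)


def propose_mutations(
    scaffold_fp: PocketFingerprint, target_fp: PocketFingerprint, source: str = ""
) -> MutationSet:
    """Mutations transplanting the target pocket onto the scaffold.

    Slots where the target is '-' cannot be designed and are reported as
    unresolvable; the set is empty iff the fingerprints agree on every
    resolvable slot.
    """
    if scaffold_fp.positions != target_fp.positions:
        raise ValueError("fingerprints cover different pocket positions")
    if not scaffold_fp.gap_free:
        raise ValueError("scaffold fingerprint must be gap-free")
    mutations: list[Mutation] = []
    unresolvable: list[int] = []
    for pos, a, b in zip(scaffold_fp.positions, scaffold_fp.symbols, target_fp.symbols):
        if b == GAP:
            unresolvable.append(pos)
        elif a != b:
            mutations.append(Mutation(pos, a, b))
    return MutationSet(scaffold_fp.member_id, tuple(mutations), tuple(unresolvable), source)


def apply_mutations(scaffold_fp: PocketFingerprint, ms: MutationSet) -> PocketFingerprint:
    """Apply a mutation set; errors if a from-symbol does not match."""
    symbols = list(scaffold_fp.symbols)
    index = {pos: i for i, pos in enumerate(scaffold_fp.positions)}
    for m in ms.mutations:
        if m.position not in index:
            raise ValueError(f"position {m.position} not in fingerprint")
        i = index[m.position]
        if symbols[i] != m.from_symbol:
            raise ValueError(
                f"from-symbol mismatch at position {m.position}: scaffold has "
                f"{symbols[i]}, mutation expects {m.from_symbol}"
            )
        symbols[i] = m.to_symbol
    return PocketFingerprint(scaffold_fp.member_id, "".join(symbols), scaffold_fp.positions)


def select_representatives(
    fps: list[PocketFingerprint],
    clusters: list[PocketTypeCluster],
    partition: CladePartition | None,
    k: int,
    matrix: SubstitutionMatrix,
    reference_fp: PocketFingerprint,
    gap_penalty: float = DEFAULT_FINGERPRINT_GAP_PENALTY,
) -> list[str]:
    """Greedy maximin panel of ``k`` member ids.

    Seeded with the member closest to the reference fingerprint; each
    further pick maximizes its minimum distance to the chosen set. While
    any cluster (among clusters that contain candidate members) is still
    uncovered, candidates are restricted to uncovered clusters. Distance
    ties prefer members from not-yet-covered clades, then the smallest id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(fps):
        raise ValueError(f"k = {k} exceeds the number of candidate members ({len(fps)})")
    ids = [fp.member_id for fp in fps]
    by_id = {fp.member_id: fp for fp in fps}
    member_cluster = {m: c.cluster_id for c in clusters for m in c.members}
    member_clade = partition.member_clade() if partition is not None else {}
    coverable = {member_cluster[m] for m in ids if m in member_cluster}

    ref_dist = {
        m: fingerprint_distance(by_id[m], reference_fp, matrix, gap_penalty) for m in ids
    }
    seed = min(ids, key=lambda m: (ref_dist[m], m))
    chosen = [seed]
    covered_clusters = {member_cluster.get(seed)}
    covered_clades = {member_clade.get(seed)}

    pair = {
        (a, b): fingerprint_distance(by_id[a], by_id[b], matrix, gap_penalty)
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    }

    def dist(a: str, b: str) -> float:
        if a == b:
            return 0.0
        return pair[(a, b)] if (a, b) in pair else pair[(b, a)]

    while len(chosen) < k:
        remaining = [m for m in ids if m not in chosen]
        uncovered = coverable - covered_clusters
        if uncovered:
            restricted = [m for m in remaining if member_cluster.get(m) in uncovered]
            if restricted:
                remaining = restricted
        min_dist = {m: min(dist(m, c) for c in chosen) for m in remaining}
        best = max(min_dist.values())
        ties = [m for m in remaining if min_dist[m] == best]
        ties.sort(key=lambda m: (member_clade.get(m) in covered_clades, m))
        pick = ties[0]
        chosen.append(pick)
        covered_clusters.add(member_cluster.get(pick))
        covered_clades.add(member_clade.get(pick))
    return chosen
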