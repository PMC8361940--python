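"""Activity prediction, pocket-type clustering, substrate compatibility.

Activity prediction is deliberately categorical: a member is called
``likely_active`` exactly when every catalytic residue is conserved at its
mapped position and no annotated domain is disrupted. Pocket types are
single-linkage clusters under the fingerprint premetric — connectivity
rather than compactness, matching how enzyme families group by branch.
Substrate rules translate qualitative pocket/substrate observations
(e.g. a small residue at position 79 admits a para-methoxy B-ring) into
editable, weighted conditions; they are hints, not a fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import SubstitutionMatrix
from .pocket import (
    DEFAULT_FINGERPRINT_GAP_PENALTY,
    DisruptionReport,
    PocketFingerprint,
    ReferenceAnnotation,
    fingerprint_distance,
)

LIKELY_ACTIVE = "likely_active"
LIKELY_INACTIVE = "likely_inactive"


@dataclass(frozen=True)
class ActivityPrediction:
    member_id: str
    catalytic_ok: dict[int, bool]
    disrupted: bool
    pocket_similarity: float  # fingerprint distance to the reference pocket
    predicted_class: str

    def __post_init__(self) -> None:
        expected = (
            LIKELY_ACTIVE
            if all(self.catalytic_ok.values()) and not self.disrupted
            else LIKELY_INACTIVE
        )
        if self.predicted_class != expected:
            raise ValueError("predicted_class inconsistent with catalytic_ok/disrupted")


def predict_activity(
    fp: PocketFingerprint,
    disruption: DisruptionReport,
    annotation: ReferenceAnnotation,
    matrix: SubstitutionMatrix | None = None,
    gap_penalty: float = DEFAULT_FINGERPRINT_GAP_PENALTY,
) -> ActivityPrediction:
    """Categorical call from catalytic-residue conservation + domain integrity."""
    if fp.member_id != disruption.member_id:
        raise ValueError(
            f"fingerprint is for {fp.member_id!r} but disruption report for "
            f"{disruption.member_id!r}"
        )
    if matrix is None:
        from .alignment import blosum62

        matrix = blosum62()
    catalytic_ok = {
        c.position: fp.symbol_at(c.position) == c.residue for c in annotation.catalytic
    }
    similarity = fingerprint_distance(
        fp, annotation.reference_fingerprint(), matrix, gap_penalty
    )
    cls = (
        LIKELY_ACTIVE
        if all(catalytic_ok.values()) and not disruption.disrupted
        else LIKELY_INACTIVE
    )
    return ActivityPrediction(fp.member_id, catalytic_ok, disruption.disrupted, similarity, cls)


@dataclass(frozen=True)
class PocketTypeCluster:
    cluster_id: int
    members: tuple[str, ...]
    representative: PocketFingerprint


def cluster_pocket_types(
    fps: list[PocketFingerprint],
    matrix: SubstitutionMatrix,
    threshold: float,
    gap_penalty: float = DEFAULT_FINGERPRINT_GAP_PENALTY,
) -> list[PocketTypeCluster]:
    """Single-linkage agglomeration under fingerprint_distance.

    Merging stops once the minimum inter-cluster distance exceeds
    ``threshold``; threshold 0 groups exactly-identical fingerprints.
    Cluster ids are numbered by order of first member; the representative
    is the member fingerprint minimizing summed distance to its cluster.
    """
    if not fps:
        raise ValueError("need at least one fingerprint")
    n = len(fps)
    ids = [fp.member_id for fp in fps]
    if n == 1:
        return [PocketTypeCluster(1, (ids[0],), fps[0])]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = fingerprint_distance(fps[i], fps[j], matrix, gap_penalty)
    labels = fcluster(linkage(squareform(dist, checks=False), method="single"),
                      t=threshold, criterion="distance")
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    clusters: list[PocketTypeCluster] = []
    for raw, cid in sorted(order.items(), key=lambda kv: kv[1]):
        idx = [i for i in range(n) if labels[i] == raw]
        sums = [float(dist[i, idx].sum()) for i in idx]
        best = min(zip(sums, (ids[i] for i in idx), idx))[2]
        clusters.append(PocketTypeCluster(cid, tuple(ids[i] for i in idx), fps[best]))
    return clusters


# ---------------------------------------------------------------------------
# Substrate rules

@dataclass(frozen=True)
class RuleCondition:
    position: int
    allowed: tuple[str, ...]
    weight: float


@dataclass(frozen=True)
class RuleGroup:
    name: str
    conditions: tuple[RuleCondition, ...]


@dataclass(frozen=True)
class SubstrateRule:
    substrate_id: str
    groups: tuple[RuleGroup, ...]
    disallowed: tuple[tuple[int, tuple[str, ...]], ...]
    threshold: float

    def positions(self) -> set[int]:
        out = {c.position for g in self.groups for c in g.conditions}
        out.update(pos for pos, _ in self.disallowed)
        return out


@dataclass(frozen=True)
class SubstrateVerdict:
    substrate_id: str
    verdict: str  # compatible | incompatible | unknown
    score: float


def load_rules(path: str | Path) -> list[SubstrateRule]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _rules_from_doc(doc)


def default_rules() -> list[SubstrateRule]:
    with resources.files("ssfe.data").joinpath("substrate_rules.yaml").open() as fh:
        return _rules_from_doc(yaml.safe_load(fh))


def _rules_from_doc(doc: dict) -> list[SubstrateRule]:
    rules = []
    for entry in doc["substrates"]:
        groups = tuple(
            RuleGroup(
                str(g["name"]),
                tuple(
                    RuleCondition(
                        int(c["position"]),
                        tuple(str(s) for s in c["allowed"]),
                        float(c.get("weight", 1.0)),
                    )
                    for c in g["conditions"]
                ),
            )
            for g in entry.get("groups", [])
        )
        disallowed = tuple(
            (int(d["position"]), tuple(str(s) for s in d["symbols"]))
            for d in entry.get("disallowed", [])
        )
        rules.append(
            SubstrateRule(str(entry["id"]), groups, disallowed, float(entry.get("threshold", 1.0)))
        )
    return rules


def substrate_compatibility(
    fp: PocketFingerprint, rules: list[SubstrateRule]
) -> dict[str, SubstrateVerdict]:
    """Evaluate each substrate rule against one fingerprint.

    ``incompatible`` when any disallowed symbol is present; ``compatible``
    when some condition group is fully satisfied with weight sum reaching
    the rule threshold; ``unknown`` otherwise. The score reported is the
    best (maximum) weight sum of satisfied conditions over all groups.
    """
    annotated = set(fp.positions)
    out: dict[str, SubstrateVerdict] = {}
    for rule in rules:
        missing = rule.positions() - annotated
        if missing:
            raise ValueError(
                f"rule {rule.substrate_id!r} references unannotated positions {sorted(missing)}"
            )
        hit_disallowed = any(
            fp.symbol_at(pos) in symbols for pos, symbols in rule.disallowed
        )
        best_score = 0.0
        any_full = False
        for group in rule.groups:
            sat = [c for c in group.conditions if fp.symbol_at(c.position) in c.allowed]
            score = sum(c.weight for c in sat)
            best_score = max(best_score, score)
            if len(sat) == len(group.conditions) and score >= rule.threshold:
                any_full = True
        if hit_disallowed:
            verdict = "incompatible"
        elif any_full:
            verdict = "compatible"
        else:
            verdict = "unknown"
        out[rule.substrate_id] = SubstrateVerdict(rule.substrate_id, verdict, best_score)
    return out
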