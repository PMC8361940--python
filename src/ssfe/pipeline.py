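"""End-to-end orchestration: align -> tree -> fingerprint -> classify -> design.

``run_ssfe`` executes the whole mining workflow on a reference annotation
plus a pool of candidate homolog sequences and writes every intermediate
artifact (alignment FASTA, Newick tree with bootstrap supports, clade
table, fingerprint table, per-member report, mutation proposals) to the
output directory. Runs are deterministic: identical config and seed give
byte-identical files.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import alignment, classify, design, io_formats, phylogeny, pocket

STAGES = ("input", "align", "tree", "fingerprint", "classify", "design", "output")


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name and, when known, the member id."""

    def __init__(self, stage: str, message: str, member_id: str | None = None) -> None:
        self.stage = stage
        self.member_id = member_id
        where = f"stage {stage!r}"
        if member_id:
            where += f", member {member_id!r}"
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    homolog_fasta: str
    out_dir: str
    annotation: str | None = None  # None -> bundled CHI-like profile
    rules: str | None = None  # None -> bundled substrate rules
    reference_fasta: str | None = None  # optional consistency check/override
    gap_open: float = alignment.DEFAULT_GAP_OPEN
    gap_extend: float = alignment.DEFAULT_GAP_EXTEND
    distance_model: str = "poisson"
    bootstrap_reps: int = 100
    clade_cut: float = 0.5
    max_insert: int = pocket.DEFAULT_MAX_INSERT
    max_unaligned: int | None = None
    cluster_threshold: float = 0.0
    representatives: int | None = None  # None -> one per pocket-type cluster
    gap_penalty: float = pocket.DEFAULT_FINGERPRINT_GAP_PENALTY
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.clade_cut <= 1.0:
            raise ValueError("clade_cut must be in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.distance_model not in ("p", "poisson"):
            raise ValueError("distance_model must be 'p' or 'poisson'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})


@dataclass(frozen=True)
class ReportRow:
    member_id: str
    clade_id: int
    fingerprint: str
    disrupted: bool
    catalytic_ok: dict[int, bool]
    pocket_distance: float
    predicted_class: str
    cluster_id: int
    verdicts: dict[str, classify.SubstrateVerdict]
    representative: bool


@dataclass
class SsfeReport:
    """Everything one mining run produced."""

    rows: list[ReportRow]
    tree: phylogeny.PhyloTree  # rooted, with bootstrap supports
    partition: phylogeny.CladePartition
    clusters: list[classify.PocketTypeCluster]
    representatives: list[str]
    mutation_sets: list[design.MutationSet]
    output_files: dict[str, Path] = field(default_factory=dict)


def _stage(stage: str, fn, *args, member_id: str | None = None, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc), member_id) from exc


def run_ssfe(config: PipelineConfig, log=None) -> SsfeReport:
    """Run the full mining pipeline and write all artifacts to ``out_dir``."""

    def say(msg: str) -> None:
        if log is not None:
            log(msg)

    t0 = time.perf_counter()

    # ---- input
    annotation = _stage(
        "input",
        lambda: (
            pocket.ReferenceAnnotation.from_yaml(config.annotation)
            if config.annotation
            else pocket.ReferenceAnnotation.default()
        ),
    )
    rules = _stage(
        "input",
        lambda: classify.load_rules(config.rules) if config.rules else classify.default_rules(),
    )
    homologs = _stage("input", io_formats.read_fasta, config.homolog_fasta)
    if not homologs:
        raise StageError("input", "homolog FASTA contains no sequences")
    ref_record = io_formats.SequenceRecord(
        annotation.ref_id, annotation.ref_description, annotation.ref_sequence
    )
    if config.reference_fasta:
        given = _stage("input", io_formats.read_fasta, config.reference_fasta)
        if len(given) != 1:
            raise StageError("input", "reference FASTA must hold exactly one record")
        if given[0].residues != annotation.ref_sequence:
            raise StageError(
                "input",
                "reference FASTA sequence disagrees with the annotation sequence",
                member_id=given[0].id,
            )
        ref_record = given[0]
    for rec in homologs:
        if rec.id == ref_record.id:
            raise StageError("input", "homolog id collides with the reference id", rec.id)
    records = [ref_record] + homologs
    matrix = alignment.blosum62()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    say(f"input: {len(homologs)} homologs + reference ({time.perf_counter() - t0:.1f}s)")

    # ---- align
    msa = _stage(
        "align", alignment.build_msa, records, matrix, config.gap_open, config.gap_extend
    )
    files = {"alignment": out_dir / "alignment.fasta"}
    io_formats.write_aligned_fasta(msa.rows, files["alignment"])
    say(f"align: {msa.ncol} columns ({time.perf_counter() - t0:.1f}s)")

    # ---- tree
    if len(records) == 2:
        # degenerate family: no resolvable topology, no bootstrap
        d = _stage("tree", alignment.distance_matrix, msa, config.distance_model)
        from .treemodel import PhyloTree, TreeNode

        root = TreeNode()
        half = d.values[0, 1] / 2.0
        root.add_child(TreeNode(label=d.labels[0], length=half))
        root.add_child(TreeNode(label=d.labels[1], length=half))
        tree = PhyloTree(root, rooted=True).canonicalize()
    else:
        unrooted = _stage(
            "tree",
            phylogeny.bootstrap_support,
            msa,
            config.bootstrap_reps,
            config.seed,
            config.distance_model,
        )
        tree = _stage("tree", phylogeny.midpoint_root, unrooted)
    partition = _stage("tree", phylogeny.cut_clades, tree, config.clade_cut)
    files["tree"] = out_dir / "tree.newick"
    files["tree"].write_text(io_formats.write_newick(tree) + "\n")
    files["clades"] = out_dir / "clades.tsv"
    io_formats.write_tsv(
        files["clades"],
        ["clade_id", "member_id", "depth"],
        [[c.clade_id, m, f"{c.depth:.6f}"] for c in partition.clades for m in c.members],
    )
    say(f"tree: {len(partition)} clades at cut {config.clade_cut} ({time.perf_counter() - t0:.1f}s)")

    # ---- fingerprint
    member_clade = partition.member_clade()
    ref_fp = annotation.reference_fingerprint()
    fps: list[pocket.PocketFingerprint] = []
    disruptions: dict[str, pocket.DisruptionReport] = {}
    for rec in homologs:
        fps.append(
            _stage("fingerprint", pocket.extract_fingerprint, msa, annotation, rec.id,
                   member_id=rec.id)
        )
        disruptions[rec.id] = _stage(
            "fingerprint",
            pocket.detect_disruption,
            msa,
            annotation,
            rec.id,
            config.max_insert,
            config.max_unaligned,
            member_id=rec.id,
        )
    files["fingerprints"] = out_dir / "fingerprints.tsv"
    io_formats.write_tsv(
        files["fingerprints"],
        ["member_id"] + [str(p) for p in annotation.positions],
        [[ref_fp.member_id] + list(ref_fp.symbols)]
        + [[fp.member_id] + list(fp.symbols) for fp in fps],
    )
    say(f"fingerprint: {len(fps)} members ({time.perf_counter() - t0:.1f}s)")

    # ---- classify
    predictions = {
        fp.member_id: _stage(
            "classify",
            classify.predict_activity,
            fp,
            disruptions[fp.member_id],
            annotation,
            matrix,
            config.gap_penalty,
            member_id=fp.member_id,
        )
        for fp in fps
    }
    clusters = _stage(
        "classify",
        classify.cluster_pocket_types,
        fps,
        matrix,
        config.cluster_threshold,
        config.gap_penalty,
    )
    member_cluster = {m: c.cluster_id for c in clusters for m in c.members}
    verdicts = {
        fp.member_id: _stage(
            "classify", classify.substrate_compatibility, fp, rules, member_id=fp.member_id
        )
        for fp in fps
    }
    say(f"classify: {len(clusters)} pocket-type clusters ({time.perf_counter() - t0:.1f}s)")

    # ---- design
    candidates = [
        fp
        for fp in fps
        if predictions[fp.member_id].predicted_class == classify.LIKELY_ACTIVE and fp.gap_free
    ]
    representatives: list[str] = []
    if candidates:
        k = config.representatives
        if k is None:
            k = len({member_cluster[fp.member_id] for fp in candidates})
        representatives = _stage(
            "design",
            design.select_representatives,
            candidates,
            clusters,
            partition,
            k,
            matrix,
            ref_fp,
            config.gap_penalty,
        )
    mutation_sets: list[design.MutationSet] = []
    for cluster in clusters:
        ms = _stage(
            "design",
            design.propose_mutations,
            ref_fp,
            cluster.representative,
            f"cluster{cluster.cluster_id}",
            member_id=cluster.representative.member_id,
        )
        if len(ms) or ms.unresolvable:
            mutation_sets.append(ms)
    files["mutations"] = out_dir / "mutations.tsv"
    io_formats.write_tsv(
        files["mutations"],
        ["source", "scaffold_id", "target_member", "mutations", "unresolvable_positions"],
        [
            [
                ms.source,
                ms.scaffold_id,
                next(
                    c.representative.member_id
                    for c in clusters
                    if f"cluster{c.cluster_id}" == ms.source
                ),
                str(ms) or ".",
                ",".join(str(p) for p in ms.unresolvable) or ".",
            ]
            for ms in mutation_sets
        ],
    )
    say(
        f"design: {len(representatives)} representatives, "
        f"{len(mutation_sets)} transplant sets ({time.perf_counter() - t0:.1f}s)"
    )

    # ---- output
    rep_set = set(representatives)
    substrate_ids = [r.substrate_id for r in rules]
    rows = [
        ReportRow(
            member_id=fp.member_id,
            clade_id=member_clade[fp.member_id],
            fingerprint=fp.symbols,
            disrupted=predictions[fp.member_id].disrupted,
            catalytic_ok=predictions[fp.member_id].catalytic_ok,
            pocket_distance=predictions[fp.member_id].pocket_similarity,
            predicted_class=predictions[fp.member_id].predicted_class,
            cluster_id=member_cluster[fp.member_id],
            verdicts=verdicts[fp.member_id],
            representative=fp.member_id in rep_set,
        )
        for fp in fps
    ]
    files["report"] = out_dir / "report.tsv"
    io_formats.write_tsv(
        files["report"],
        [
            "member_id",
            "clade_id",
            "fingerprint",
            "catalytic_ok",
            "disrupted",
            "pocket_distance",
            "predicted_class",
            "cluster_id",
        ]
        + [f"substrate_{s}" for s in substrate_ids]
        + ["representative"],
        [
            [
                row.member_id,
                row.clade_id,
                row.fingerprint,
                ";".join(f"{p}:{'ok' if ok else 'lost'}" for p, ok in sorted(row.catalytic_ok.items())),
                int(row.disrupted),
                f"{row.pocket_distance:.4f}",
                row.predicted_class,
                row.cluster_id,
            ]
            + [
                f"{row.verdicts[s].verdict}:{row.verdicts[s].score:.2f}"
                for s in substrate_ids
            ]
            + [int(row.representative)]
            for row in rows
        ],
    )
    say(f"done ({time.perf_counter() - t0:.1f}s)")
    return SsfeReport(
        rows=rows,
        tree=tree,
        partition=partition,
        clusters=clusters,
        representatives=representatives,
        mutation_sets=mutation_sets,
        output_files=files,
    )
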