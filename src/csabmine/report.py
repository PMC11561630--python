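"""Cysteine-anchored class alignments and pipeline orchestration.

``run_pipeline`` wires the whole mining procedure together: size filter →
motif scan → secretion gate → mature extraction → framework → class
assignment → redundancy clustering → per-class anchored alignments, with
an auditable per-stage report at every step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .classify import ClassAssignment, ClassifierConfig, annotate, load_overrides
from .cluster import Cluster, greedy_cluster
from .filtering import (
    DEFAULT_HEURISTIC,
    DEFAULT_MOTIF,
    REASON_MATURE_TOO_SHORT,
    REASON_NO_MOTIF,
    REASON_NO_STRUCT_SUPPORT,
    FilterReport,
    HeuristicParams,
    MatureTooShortError,
    MotifSpec,
    annotate_secretion,
    extract_mature,
    motif_filter,
    secretion_gate,
    size_filter,
)
from .framework import CysteineFramework, build_framework
from .sequence_io import (
    SequenceRecord,
    read_fasta,
    read_phobius_short,
    write_fasta,
    write_table,
)


class AlignmentError(ValueError):
    pass


@dataclass
class AnchoredAlignment:
    """Class members padded so the six framework cysteines share columns."""

    ids: list[str]
    rows: list[str]
    lengths: list[int]
    charges: list[int]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _segments(mature: str, fw: CysteineFramework) -> list[str]:
    """n-tail, five inter-cysteine segments, c-tail (anchors excluded)."""
    a = fw.assignment
    parts = [mature[: a[0] - 1]]
    for i in range(5):
        parts.append(mature[a[i]: a[i + 1] - 1])
    parts.append(mature[a[5]:])
    return parts


def anchored_align(
    members: Sequence[tuple[str, CysteineFramework]],
    charges: Sequence[int] | None = None,
) -> AnchoredAlignment:
    """Pad members so the framework cysteines occupy six shared columns.

    Tails are left-justified; each inter-cysteine segment is
    right-justified against its downstream anchor cysteine. Gap character
    is "-".
    """
    if not members:
        return AnchoredAlignment(ids=[], rows=[], lengths=[], charges=[])
    seg_table = []
    for mature, fw in members:
        if fw is None:
            raise AlignmentError(f"member {mature!r} lacks a framework")
        seg_table.append(_segments(mature, fw))
    widths = [max(len(row[k]) for row in seg_table) for k in range(7)]
    rows = []
    for segs in seg_table:
        parts = [segs[0].ljust(widths[0], "-")]
        for k in range(1, 6):
            parts.append("C")
            parts.append(segs[k].rjust(widths[k], "-"))
        parts.append("C")
        parts.append(segs[6].ljust(widths[6], "-"))
        rows.append("".join(parts))
    from .classify import net_charge

    matures = [m for m, _ in members]
    return AnchoredAlignment(
        ids=[fw.mature_id for _, fw in members],
        rows=rows,
        lengths=[len(m) for m in matures],
        charges=list(charges) if charges is not None else [net_charge(m) for m in matures],
    )


def format_alignment(alignment: AnchoredAlignment) -> str:
    if not alignment.ids:
        return "(no members)\n"
    id_width = max(len(i) for i in alignment.ids) + 2
    lines = []
    for rid, row, length, charge in zip(
        alignment.ids, alignment.rows, alignment.lengths, alignment.charges
    ):
        lines.append(f"{rid.ljust(id_width)}{row}  len={length} charge={charge:+d}")
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    fasta: str | Path | None = None
    records: Sequence[SequenceRecord] | None = None
    phobius: str | Path | None = None
    min_len: int = 30
    max_len: int = 130
    motif: MotifSpec = DEFAULT_MOTIF
    heuristic: HeuristicParams = DEFAULT_HEURISTIC
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cluster_threshold: float = 0.70
    identity_denominator: str = "shorter"
    do_cluster: bool = True
    overrides: str | Path | None = None
    evidence: str | Path | None = None   # optional structural-evidence gate
    outdir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in (
            "fasta", "phobius", "min_len", "max_len", "cluster_threshold",
            "identity_denominator", "do_cluster", "overrides", "evidence", "outdir",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "motif" in data:
            kwargs["motif"] = MotifSpec(
                segment_bounds=tuple(tuple(b) for b in data["motif"])
            )
        if "classifier" in data:
            c = data["classifier"]
            kwargs["classifier"] = ClassifierConfig(
                tail_ranges={
                    k: tuple(v)
                    for k, v in c.get(
                        "tail_ranges", dict(ClassifierConfig().tail_ranges)
                    ).items()
                },
                tail0_as_I=bool(c.get("tail0_as_I", False)),
            )
        if "heuristic" in data:
            kwargs["heuristic"] = HeuristicParams(**data["heuristic"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    reports: list[FilterReport]
    matures: dict[str, SequenceRecord]
    frameworks: dict[str, CysteineFramework]
    assignments: dict[str, ClassAssignment]
    clusters: list[Cluster]
    class_counts: dict[str, int]

    def report(self, stage: str) -> FilterReport:
        for rep in self.reports:
            if rep.stage == stage:
                return rep
        raise KeyError(stage)


def load_evidence(path: str | Path) -> dict[str, bool]:
    """Two-column evidence table: id<TAB>true/false (structural support)."""
    evidence: dict[str, bool] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rid, flag = line.split("\t")[:2]
        evidence[rid] = flag.strip().lower() in ("true", "1", "yes", "y")
    return evidence


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    if config.records is not None:
        records = list(config.records)
    elif config.fasta is not None:
        records = read_fasta(config.fasta, kind="protein")
    else:
        records = []
    by_id = {r.id: r for r in records}
    reports: list[FilterReport] = []

    size_rep = size_filter(records, config.min_len, config.max_len)
    reports.append(size_rep)
    current = [by_id[i] for i in size_rep.kept]

    motif_rep = motif_filter(current, config.motif)
    reports.append(motif_rep)
    current = [by_id[i] for i in motif_rep.kept]

    phobius = read_phobius_short(config.phobius) if config.phobius else None
    annotations = annotate_secretion(current, phobius, config.heuristic)
    secretion_rep = secretion_gate(current, annotations)
    reports.append(secretion_rep)
    current = [by_id[i] for i in secretion_rep.kept]

    if config.evidence:
        evidence = load_evidence(config.evidence)
        ev_rep = FilterReport(stage="evidence")
        for rec in current:
            if evidence.get(rec.id, False):
                ev_rep.kept.append(rec.id)
            else:
                ev_rep.removed[rec.id] = REASON_NO_STRUCT_SUPPORT
        reports.append(ev_rep)
        current = [by_id[i] for i in ev_rep.kept]

    mature_rep = FilterReport(stage="mature")
    matures: dict[str, SequenceRecord] = {}
    frameworks: dict[str, CysteineFramework] = {}
    for rec in current:
        try:
            mature = extract_mature(rec, annotations[rec.id])
        except MatureTooShortError:
            mature_rep.removed[rec.id] = REASON_MATURE_TOO_SHORT
            continue
        matched, assignments_found = motif_scan_mature(mature, config.motif)
        if not matched:
            mature_rep.removed[rec.id] = REASON_NO_MOTIF
            continue
        mature_rep.kept.append(rec.id)
        matures[rec.id] = mature
        frameworks[rec.id] = build_framework(
            mature.residues,
            assignments_found,
            mature_id=mature.id,
            spec=config.motif,
        )
    reports.append(mature_rep)

    overrides = load_overrides(config.overrides) if config.overrides else None
    assignments = {
        rid: annotate(fw, config.classifier, overrides)
        for rid, fw in frameworks.items()
    }

    clusters: list[Cluster] = []
    if config.do_cluster and matures:
        clusters = greedy_cluster(
            list(matures.values()),
            threshold=config.cluster_threshold,
            denominator=config.identity_denominator,
        )

    class_counts: dict[str, int] = {}
    for assignment in assignments.values():
        class_counts[assignment.label] = class_counts.get(assignment.label, 0) + 1

    result = PipelineResult(
        reports=reports,
        matures=matures,
        frameworks=frameworks,
        assignments=assignments,
        clusters=clusters,
        class_counts=class_counts,
    )
    if config.outdir is not None:
        write_outputs(result, config)
    return result


def motif_scan_mature(mature: SequenceRecord, spec: MotifSpec):
    from .filtering import motif_scan

    return motif_scan(mature, spec)


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    """Write per-stage reports, tables and alignments; deterministic bytes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in result.reports:
        lines = ["id\tstatus\treason"]
        for rid in rep.kept:
            lines.append(f"{rid}\tkept\t")
        for rid, reason in sorted(rep.removed.items()):
            lines.append(f"{rid}\tremoved\t{reason}")
        (outdir / f"stage_{rep.stage}.tsv").write_text("\n".join(lines) + "\n")

    cluster_of: dict[str, str] = {}
    for ci, cluster in enumerate(result.clusters):
        for member in cluster.members:
            cluster_of[member] = f"c{ci}"
    rows = []
    for rid in sorted(result.assignments):
        a = result.assignments[rid]
        rows.append(
            {
                "id": rid,
                "class": a.label,
                "mature_length": len(result.matures[rid]),
                "net_charge": a.net_charge,
                "gamma_core": a.gamma_core,
                "kcxn": ",".join(map(str, a.kcxn)),
                "conserved_gly": a.conserved_gly,
                "cluster": cluster_of.get(result.matures[rid].id, ""),
            }
        )
    write_table(rows, outdir / "classification.tsv", format="tsv")
    write_table(rows, outdir / "classification.json", format="json")

    lines = ["cluster_id\trepresentative\tmember\tidentity"]
    for ci, cluster in enumerate(result.clusters):
        for member in cluster.members:
            lines.append(
                f"c{ci}\t{cluster.representative}\t{member}\t"
                f"{cluster.identities[member]:.4f}"
            )
    (outdir / "clusters.tsv").write_text("\n".join(lines) + "\n")

    if result.matures:
        write_fasta(
            [result.matures[r] for r in sorted(result.matures)],
            outdir / "matures.fasta",
        )

    labels = sorted({a.label for a in result.assignments.values()})
    for label in labels:
        member_ids = sorted(
            rid for rid, a in result.assignments.items() if a.label == label
        )
        members = [
            (result.matures[rid].residues, result.frameworks[rid])
            for rid in member_ids
        ]
        text = format_alignment(anchored_align(members))
        (outdir / f"class_{label}.aln.txt").write_text(text)

    log = {
        "csabmine_version": __version__,
        "min_len": config.min_len,
        "max_len": config.max_len,
        "motif_bounds": list(config.motif.segment_bounds),
        "tail_ranges": {k: list(v) for k, v in config.classifier.tail_ranges.items()},
        "cluster_threshold": config.cluster_threshold,
        "identity_denominator": config.identity_denominator,
        "n_input": result.reports[0].n_in if result.reports else 0,
        "class_counts": dict(sorted(result.class_counts.items())),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
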