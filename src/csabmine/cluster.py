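"""Redundancy removal: Needleman-Wunsch identity + greedy clustering.

Mimics CD-HIT-style 70% redundancy removal at desk scale: sequences are
processed in decreasing length, each joins the first cluster whose
representative aligns above the identity threshold, otherwise it founds a
new cluster. No k-mer prefilter: mature defensins are short (<=130
residues) and sets are small, so exact O(n^2) alignment is fine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .sequence_io import SequenceRecord


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: int
    matches: int

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def global_align(
    a: str, b: str, match: int = 1, mismatch: int = 0, gap: int = -1
) -> Alignment:
    """Optimal global alignment (Needleman-Wunsch, linear gap penalty).

    Traceback ties are broken deterministically: diagonal > up (gap in b)
    > left (gap in a).
    """
    if not a or not b:
        raise ValueError("global_align requires nonempty sequences")
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        row = score[i]
        prev = score[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            row[j] = best

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return Alignment(aligned_a, aligned_b, score[n][m], matches)


def identity(
    a: str, b: str, denominator: str = "shorter", alignment: Alignment | None = None
) -> float:
    """Percent identity in [0,1].

    ``denominator="alignment"`` divides matches by the alignment length
    (gap columns included); ``"shorter"`` divides by the shorter sequence
    length, the convention closer to CD-HIT's.
    """
    aln = alignment or global_align(a, b)
    if denominator == "alignment":
        return aln.matches / aln.length
    if denominator == "shorter":
        return aln.matches / min(len(a), len(b))
    raise ValueError(f"unknown identity denominator {denominator!r}")


def greedy_cluster(
    records: Sequence[SequenceRecord],
    threshold: float = 0.70,
    denominator: str = "shorter",
) -> list[Cluster]:
    """Greedy representative clustering at the given identity threshold.

    Sequences are processed in decreasing length (ties: lexicographic id);
    each joins the first existing cluster whose representative it matches
    at >= threshold identity, else founds a new cluster. Representatives
    end up pairwise below the threshold by construction.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in clustering input")
    by_id = {r.id: r for r in records}
    order = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    for rec in order:
        placed = False
        for cluster in clusters:
            rep = by_id[cluster.representative]
            ident = identity(rec.residues, rep.residues, denominator)
            if ident >= threshold:
                cluster.members.append(rec.id)
                cluster.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    representative=rec.id,
                    members=[rec.id],
                    identities={rec.id: 1.0},
                )
            )
    return clusters
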