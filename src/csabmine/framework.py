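"""Cysteine-framework features of a mature peptide.

The six framework cysteines anchor everything downstream: tail lengths,
inter-cysteine gap (loop) lengths, extra cysteines and the inferred
disulfide topology. Coordinates are 1-based on the mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .filtering import DEFAULT_MOTIF, MotifSpec, cysteine_positions, motif_scan
from .sequence_io import SequenceRecord

TOPOLOGY_SIX = "SIX_CYS"
TOPOLOGY_EIGHT_FLANKING = "EIGHT_CYS_FLANKING"
TOPOLOGY_EIGHT_INTERNAL = "EIGHT_CYS_INTERNAL"
TOPOLOGY_OTHER = "OTHER"

#: Canonical cis-defensin disulfide connectivity over framework numbering.
CANONICAL_BONDS = ((1, 4), (2, 5), (3, 6))


class FrameworkError(ValueError):
    pass


@dataclass(frozen=True)
class CysteineFramework:
    mature_id: str
    sequence: str
    cys_positions: tuple[int, ...]    # every cysteine in the mature peptide
    assignment: tuple[int, ...]       # the six framework cysteines
    segment_gaps: tuple[int, ...]     # five inter-cysteine gap lengths g1..g5
    n_tail_len: int                   # residues before framework C1
    c_tail_len: int                   # residues after framework C6
    extra_cys: tuple[int, ...]        # cysteines outside the framework
    topology: str


@dataclass(frozen=True)
class DisulfideTopology:
    """Predicted disulfide pairing.

    ``canonical_bonds`` use framework numbering (1-6); ``extra_bond`` uses
    the full cysteine numbering over all cysteines of the mature peptide.
    """

    canonical_bonds: tuple[tuple[int, int], ...] = CANONICAL_BONDS
    extra_bond: tuple[int, int] | None = None
    resolved: bool = True


def _is_flanking(cys: Sequence[int], assignment: Sequence[int]) -> bool:
    extras = [p for p in cys if p not in assignment]
    return (
        len(extras) == 2
        and extras[0] == cys[0]
        and extras[1] == cys[-1]
    )


def _classify_topology(cys: Sequence[int], assignment: Sequence[int]) -> str:
    extras = [p for p in cys if p not in assignment]
    if not extras:
        return TOPOLOGY_SIX
    if len(extras) == 2:
        if _is_flanking(cys, assignment):
            return TOPOLOGY_EIGHT_FLANKING
        if extras[0] < assignment[0] and assignment[3] < extras[1] < assignment[5]:
            return TOPOLOGY_EIGHT_INTERNAL
    return TOPOLOGY_OTHER


def choose_assignment(
    cys: Sequence[int], assignments: Sequence[tuple[int, ...]]
) -> tuple[int, ...]:
    """Deterministic tie-break among satisfying framework assignments.

    Preference order: (a) assignments that leave the extra cysteines
    flanking the framework on both sides (the plant-like 8-cysteine
    pattern), (b) smallest framework span, (c) leftmost (lexicographically
    smallest position tuple).
    """
    pool = list(assignments)
    flanking = [a for a in pool if _is_flanking(cys, a)]
    if flanking:
        pool = flanking
    return min(pool, key=lambda a: (a[-1] - a[0], a))


def build_framework(
    mature: SequenceRecord | str,
    assignments: Sequence[tuple[int, ...]] | None = None,
    mature_id: str | None = None,
    spec: MotifSpec = DEFAULT_MOTIF,
) -> CysteineFramework:
    """Build the framework for a mature peptide.

    ``assignments`` are the satisfying assignments from the motif scan; when
    omitted the scan is run here. Zero assignments is a precondition error.
    """
    if isinstance(mature, SequenceRecord):
        sequence = mature.residues
        mature_id = mature_id or mature.id
    else:
        sequence = mature.upper()
        mature_id = mature_id or "mature"
    if assignments is None:
        _, assignments = motif_scan(sequence, spec)
    if not assignments:
        raise FrameworkError(f"{mature_id}: no framework assignment matches")
    cys = tuple(cysteine_positions(sequence))
    chosen = choose_assignment(cys, assignments)
    gaps = tuple(
        chosen[i + 1] - chosen[i] - 1 for i in range(len(chosen) - 1)
    )
    extras = tuple(p for p in cys if p not in chosen)
    return CysteineFramework(
        mature_id=mature_id,
        sequence=sequence,
        cys_positions=cys,
        assignment=tuple(chosen),
        segment_gaps=gaps,
        n_tail_len=chosen[0] - 1,
        c_tail_len=len(sequence) - chosen[-1],
        extra_cys=extras,
        topology=_classify_topology(cys, chosen),
    )


def infer_topology(framework: CysteineFramework) -> DisulfideTopology:
    """Infer disulfide pairing from the framework topology.

    Six cysteines pair canonically (1-4, 2-5, 3-6). With two flanking
    extras the fourth bond links the first and last cysteines (1-8 in full
    numbering); with two internal-pattern extras the fourth bond links the
    observed extra positions. Other cysteine counts are left unresolved.
    """
    if framework.topology == TOPOLOGY_SIX:
        return DisulfideTopology()
    full_rank = {pos: i + 1 for i, pos in enumerate(framework.cys_positions)}
    if framework.topology == TOPOLOGY_EIGHT_FLANKING:
        return DisulfideTopology(extra_bond=(1, len(framework.cys_positions)))
    if framework.topology == TOPOLOGY_EIGHT_INTERNAL:
        first, second = framework.extra_cys
        return DisulfideTopology(extra_bond=(full_rank[first], full_rank[second]))
    return DisulfideTopology(extra_bond=None, resolved=False)


def loop_lengths(framework: CysteineFramework) -> tuple[int, int, int]:
    """(n, m, c) loop lengths.

    Operational convention: n = gap 1 (C1-C2), m = gap 3 (C3-C4),
    c = gap 4 (C4-C5). Gaps 2 and 5 are fixed by the motif (3 and 1).
    """
    g = framework.segment_gaps
    return (g[0], g[2], g[3])
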