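"""Five-class structural-archetype classification of bacterial cis-defensins.

Classes are assigned from two framework features: the disulfide topology
(six cysteines, or eight with flanking / internal extras) and the length of
the N-terminal tail preceding framework cysteine 1.

  V   : eight cysteines, extras flanking (plant-like fourth bond 1-8)
  III : eight cysteines, internal extra pattern, tail within the class range
  I   : six cysteines, tail 1-4
  II  : six cysteines, tail 8-13
  IV  : six cysteines, tail 21-53

Everything else is UNCLASSIFIED with a machine-readable reason. Sequence
motifs (γ-core GXC, KCXN, conserved glycine) and the net charge are
annotated alongside the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .framework import (
    TOPOLOGY_EIGHT_FLANKING,
    TOPOLOGY_EIGHT_INTERNAL,
    TOPOLOGY_SIX,
    CysteineFramework,
)

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassifierConfig:
    """Numeric class bounds; every bound is overridable.

    Tail ranges merge the two printed variants where the source material
    disagrees: class II uses 8-13 (union of 9-13 and 8-13) and class IV
    uses 21-53 (union of 21-53 and 23-53). ``tail0_as_I`` optionally
    extends class I to tail length 0.
    """

    tail_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "I": (1, 4),
            "II": (8, 13),
            "III": (0, 15),
            "IV": (21, 53),
        }
    )
    tail0_as_I: bool = False

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.tail_ranges.items():
            if lo > hi:
                raise ValueError(f"class {label}: empty tail range ({lo},{hi})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        ranges = {
            k: tuple(v) for k, v in data.get("tail_ranges", {}).items()
        }
        base = cls()
        merged = dict(base.tail_ranges)
        merged.update(ranges)
        return cls(tail_ranges=merged, tail0_as_I=bool(data.get("tail0_as_I", False)))


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class ClassAssignment:
    mature_id: str
    label: str                      # I..V or UNCLASSIFIED
    rationale: tuple[str, ...]
    gamma_core: bool
    gamma_core_pos: int | None
    kcxn: tuple[int, ...]
    conserved_gly: bool
    net_charge: int


def _in_range(value: int, bounds: tuple[int, int]) -> bool:
    return bounds[0] <= value <= bounds[1]


def assign_class(
    framework: CysteineFramework, config: ClassifierConfig = DEFAULT_CONFIG
) -> tuple[str, tuple[str, ...]]:
    """Label a framework; returns (label, rationale codes)."""
    tail = framework.n_tail_len
    if framework.topology == TOPOLOGY_EIGHT_FLANKING:
        return "V", ("TOPOLOGY_EIGHT_CYS_FLANKING",)
    if framework.topology == TOPOLOGY_EIGHT_INTERNAL:
        if _in_range(tail, config.tail_ranges["III"]):
            return "III", ("TOPOLOGY_EIGHT_CYS_INTERNAL", "TAIL_IN_III_RANGE")
        return UNCLASSIFIED, ("TOPOLOGY_EIGHT_CYS_INTERNAL", "TAIL_GAP")
    if framework.topology == TOPOLOGY_SIX:
        for label in ("I", "II", "IV"):
            if _in_range(tail, config.tail_ranges[label]):
                return label, ("TOPOLOGY_SIX_CYS", f"TAIL_IN_{label}_RANGE")
        if tail == 0 and config.tail0_as_I:
            return "I", ("TOPOLOGY_SIX_CYS", "TAIL_ZERO_AS_I")
        return UNCLASSIFIED, ("TOPOLOGY_SIX_CYS", "TAIL_GAP")
    return UNCLASSIFIED, ("TOPOLOGY_UNRESOLVED",)


def detect_gamma_core(
    mature: str, framework: CysteineFramework
) -> tuple[bool, int | None]:
    """γ-core: G-X-C ending at framework cysteine 5 (between β1 and β2)."""
    p = framework.assignment[4]
    if p >= 3 and mature[p - 3] == "G":
        return True, p - 2
    return False, None


def detect_kcxn(mature: str) -> tuple[int, ...]:
    """All start positions of the K-C-x-N motif (overlaps included)."""
    hits = []
    for i in range(len(mature) - 3):
        if mature[i] == "K" and mature[i + 1] == "C" and mature[i + 3] == "N":
            hits.append(i + 1)
    return tuple(hits)


def net_charge(mature: str) -> int:
    """Net charge counting only K/R (+1) and D/E (-1); His and termini ignored."""
    return sum(mature.count(a) for a in "KR") - sum(mature.count(a) for a in "DE")


def detect_conserved_gly(
    mature: str, framework: CysteineFramework, offset: int | None = None
) -> bool:
    """Conserved glycine inside gap segment 4 (between C4 and C5).

    By default this is the γ-core glycine (position C5 - 2); a configured
    ``offset`` checks segment position ``offset`` (1-based) instead.
    """
    if offset is None:
        present, _ = detect_gamma_core(mature, framework)
        return present
    c4 = framework.assignment[3]
    g4 = framework.segment_gaps[3]
    if not 1 <= offset <= g4:
        return False
    return mature[c4 + offset - 1] == "G"


def annotate(
    framework: CysteineFramework,
    config: ClassifierConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, str] | None = None,
) -> ClassAssignment:
    """Full class assignment with motif and charge annotations."""
    mature = framework.sequence
    label, rationale = assign_class(framework, config)
    if overrides and framework.mature_id in overrides:
        label = overrides[framework.mature_id]
        rationale = rationale + ("EXPERT_OVERRIDE",)
    gamma, gamma_pos = detect_gamma_core(mature, framework)
    return ClassAssignment(
        mature_id=framework.mature_id,
        label=label,
        rationale=rationale,
        gamma_core=gamma,
        gamma_core_pos=gamma_pos,
        kcxn=detect_kcxn(mature),
        conserved_gly=detect_conserved_gly(mature, framework),
        net_charge=net_charge(mature),
    )


def load_overrides(path: str | Path) -> dict[str, str]:
    """Expert override file: ``id<TAB>class<TAB>note`` (note optional)."""
    overrides: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"override line needs id<TAB>class: {line!r}")
        overrides[parts[0]] = parts[1]
    return overrides
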