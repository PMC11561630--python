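"""Labeled synthetic precursors and decoys for every pipeline stage.

Positives are secreted-precursor sequences built to the five structural
archetypes: a signal peptide the secretion heuristic accepts (n-region
basic residues, hydrophobic h-region, small-residue cleavage region), an
N-terminal tail drawn from the class range, a six-cysteine framework with
gaps drawn inside the mining-pattern bounds, a γ-core glycine at framework
C5 - 2, and — for the eight-cysteine classes — two extra cysteines placed
internally (class III) or flanking (class V). Each generated record is
validated against the real pipeline at generation time and carries its
ground truth (class, cleavage site, framework positions).

Decoys violate exactly one named rule so each filter stage has sequences
it must reject.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from .classify import DEFAULT_CONFIG, annotate
from .filtering import (
    DEFAULT_HEURISTIC,
    DEFAULT_MOTIF,
    MotifSpec,
    extract_mature,
    heuristic_signal_predict,
    motif_scan,
)
from .framework import (
    TOPOLOGY_EIGHT_FLANKING,
    TOPOLOGY_EIGHT_INTERNAL,
    TOPOLOGY_SIX,
    build_framework,
)
from .sequence_io import SequenceRecord

#: Background alphabet: uniform over the 19 non-cysteine amino acids.
BACKGROUND = "ADEFGHIKLMNPQRSTVWY"

DECOY_KINDS = (
    "TOO_SHORT",
    "TOO_LONG",
    "NO_CYS",
    "BAD_SPACING",
    "NO_SIGNAL",
    "TM_LIKE",
    "SHUFFLED_POSITIVE",
)

#: Default N-terminal tail draw range per class (measured on the mature
#: peptide, includes the flanking/internal extra cysteine where present).
#: Classes II-IV follow the published archetype ranges; classes I and V
#: need >= 2 (>= 3 with an extra cysteine) so the constructed cleavage
#: region stays consistent.
DEFAULT_TAIL_DRAW = {
    "I": (2, 4),
    "II": (8, 13),
    "III": (3, 15),
    "IV": (21, 53),
    "V": (4, 8),
}

CLASS_TOPOLOGY = {
    "I": TOPOLOGY_SIX,
    "II": TOPOLOGY_SIX,
    "III": TOPOLOGY_EIGHT_INTERNAL,
    "IV": TOPOLOGY_SIX,
    "V": TOPOLOGY_EIGHT_FLANKING,
}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; (spec, seed) fully determines the output."""

    defensin_class: str
    seed: int
    tail_range: tuple[int, int] | None = None
    gap_ranges: tuple[tuple[int, int], ...] | None = None
    gamma_core: bool = True
    n_region_basic: int = 2
    h_region_len: int = 8
    c_tail_range: tuple[int, int] = (0, 6)
    background: str = BACKGROUND
    motif: MotifSpec = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        if self.defensin_class not in CLASS_TOPOLOGY:
            raise ValueError(f"unknown class {self.defensin_class!r}")
        if self.h_region_len < 7:
            raise ValueError("h-region must be >= 7 residues")
        tail = self.tail_range or DEFAULT_TAIL_DRAW[self.defensin_class]
        floor = 3 if self.defensin_class in ("III", "V") else 2
        if tail[0] < floor or tail[0] > tail[1]:
            raise ValueError(
                f"class {self.defensin_class}: tail range {tail} incompatible "
                f"with construction (min {floor})"
            )
        gaps = self.gap_ranges or self.motif.segment_bounds
        for (lo, hi), (blo, bhi) in zip(gaps, self.motif.segment_bounds):
            if lo < blo or hi > bhi:
                raise ValueError("gap draw range outside motif bounds")


@dataclass(frozen=True)
class LabeledRecord:
    """A generated sequence plus its ground truth."""

    record: SequenceRecord
    label: str                           # I..V or REJECT:<KIND>
    mature: str | None = None
    cleavage_site: int | None = None
    framework: tuple[int, ...] | None = None  # six positions, mature coords
    extra_cys: tuple[int, ...] = ()
    gamma_core_pos: int | None = None
    expected_stage: str | None = None    # decoys: stage that must reject
    expected_reason: str | None = None


def _bg(rng: random.Random, n: int, background: str = BACKGROUND) -> str:
    return "".join(rng.choice(background) for _ in range(n))


def _signal_peptide(rng: random.Random, spec_basic: int, spec_hlen: int) -> str:
    """M + basic n-region + hydrophobic h-region + A; the secretion
    heuristic cleaves exactly after the final A by construction."""
    n_region = "".join(rng.choice("KR") for _ in range(spec_basic))
    h_region = "".join(rng.choice("LLIVF") for _ in range(spec_hlen))
    return "M" + n_region + h_region + "A"


def _draw_mature(rng: random.Random, spec: SyntheticSpec) -> tuple[str, dict]:
    """One mature-sequence draw with its intended ground truth."""
    cls = spec.defensin_class
    bg = spec.background
    tail_lo, tail_hi = spec.tail_range or DEFAULT_TAIL_DRAW[cls]
    gap_ranges = spec.gap_ranges or spec.motif.segment_bounds

    tail_len = rng.randint(tail_lo, tail_hi)
    tail = list(_bg(rng, tail_len, bg))
    tail[1] = "A"  # keeps the constructed cleavage site deterministic
    extra_positions: list[int] = []
    if cls in ("III", "V"):
        tail[2] = "C"
        extra_positions.append(3)

    gaps = [rng.randint(lo, hi) for lo, hi in gap_ranges]
    segments = [list(_bg(rng, g, bg)) for g in gaps]
    if spec.gamma_core:
        segments[3][-2] = "G"
    if cls == "III":
        segments[3][0] = "C"

    c_tail = list(_bg(rng, rng.randint(*spec.c_tail_range), bg))
    if cls == "V":
        c_tail = ["C"] + c_tail

    pieces = ["".join(tail)]
    positions = []
    cursor = tail_len
    for seg in segments:
        cursor += 1
        positions.append(cursor)  # a framework cysteine
        pieces.append("C")
        pieces.append("".join(seg))
        cursor += len(seg)
    cursor += 1
    positions.append(cursor)
    pieces.append("C")
    pieces.append("".join(c_tail))
    mature = "".join(pieces)

    if cls == "III":
        extra_positions.append(positions[3] + 1)
    elif cls == "V":
        extra_positions.append(positions[5] + 1)

    truth = {
        "tail_len": tail_len,
        "gaps": tuple(gaps),
        "framework": tuple(positions),
        "extra_cys": tuple(extra_positions),
        "gamma_core_pos": positions[4] - 2 if spec.gamma_core else None,
    }
    return mature, truth


def _validated_positive(
    rng: random.Random, spec: SyntheticSpec, record_id: str
) -> LabeledRecord | None:
    """One construction attempt, validated against the real pipeline."""
    signal = _signal_peptide(rng, spec.n_region_basic, spec.h_region_len)
    mature, truth = _draw_mature(rng, spec)
    precursor = signal + mature
    if not 30 <= len(precursor) <= 130:
        return None

    matched, _ = motif_scan(precursor, spec.motif)
    if not matched:
        return None
    ann = heuristic_signal_predict(
        SequenceRecord(id=record_id, residues=precursor), DEFAULT_HEURISTIC
    )
    if (
        not ann.has_signal_peptide
        or ann.has_transmembrane
        or ann.cleavage_site != len(signal)
    ):
        return None
    rec = SequenceRecord(id=record_id, residues=precursor)
    if extract_mature(rec, ann).residues != mature:
        return None
    fw = build_framework(mature, mature_id=record_id, spec=spec.motif)
    if fw.assignment != truth["framework"]:
        return None
    if fw.topology != CLASS_TOPOLOGY[spec.defensin_class]:
        return None
    assignment = annotate(fw, DEFAULT_CONFIG)
    if assignment.label != spec.defensin_class:
        return None
    if spec.gamma_core and not assignment.gamma_core:
        return None
    return LabeledRecord(
        record=rec,
        label=spec.defensin_class,
        mature=mature,
        cleavage_site=len(signal),
        framework=truth["framework"],
        extra_cys=truth["extra_cys"],
        gamma_core_pos=truth["gamma_core_pos"],
    )


def generate_defensin(spec: SyntheticSpec, record_id: str | None = None) -> LabeledRecord:
    """Generate one validated precursor of the requested class."""
    rng = random.Random(spec.seed)
    rid = record_id or f"syn{spec.defensin_class}_{spec.seed}"
    for _ in range(1000):
        result = _validated_positive(rng, spec, rid)
        if result is not None:
            return result
    raise GenerationError(
        f"could not satisfy spec for class {spec.defensin_class} "
        f"(seed {spec.seed}); ranges may be incompatible"
    )


def generate_defensins(
    defensin_class: str, n: int, seed: int, **overrides
) -> list[LabeledRecord]:
    """n validated precursors of one class from a single seeded stream."""
    spec = SyntheticSpec(defensin_class=defensin_class, seed=seed, **overrides)
    rng = random.Random(seed)
    out: list[LabeledRecord] = []
    for i in range(n):
        rid = f"syn{defensin_class}_{seed}_{i:04d}"
        for _ in range(1000):
            result = _validated_positive(rng, spec, rid)
            if result is not None:
                out.append(result)
                break
        else:
            raise GenerationError(f"exhausted attempts at record {i}")
    return out


def _decoy(record_id: str, residues: str, kind: str, stage: str | None,
           reason: str | None) -> LabeledRecord:
    return LabeledRecord(
        record=SequenceRecord(id=record_id, residues=residues),
        label=f"REJECT:{kind}",
        expected_stage=stage,
        expected_reason=reason,
    )


_BAD_GAPS = (
    (0, 1), (0, 19), (1, 2), (1, 4), (2, 1), (2, 13), (3, 3), (3, 18), (4, 0), (4, 2),
)


def generate_decoys(kind: str, n: int, seed: int) -> list[LabeledRecord]:
    """Decoys violating exactly the named rule.

    TOO_SHORT / TOO_LONG fail the size filter; NO_CYS and BAD_SPACING fail
    the motif scan; NO_SIGNAL and TM_LIKE carry a valid framework but fail
    the secretion gate; SHUFFLED_POSITIVE permutes a positive's mature
    residues (composition preserved) with no rejection guarantee — it is a
    pass-rate regression probe only.
    """
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    rng = random.Random(seed)
    base_spec = SyntheticSpec(defensin_class="II", seed=seed)
    out: list[LabeledRecord] = []
    for i in range(n):
        rid = f"decoy{kind}_{seed}_{i:04d}"
        if kind == "TOO_SHORT":
            out.append(
                _decoy(rid, _bg(rng, rng.randint(10, 29)), kind, "size", "TOO_SHORT")
            )
        elif kind == "TOO_LONG":
            out.append(
                _decoy(rid, _bg(rng, rng.randint(131, 180)), kind, "size", "TOO_LONG")
            )
        elif kind == "NO_CYS":
            signal = _signal_peptide(rng, 2, 8)
            body = _bg(rng, rng.randint(30, 100))
            out.append(_decoy(rid, signal + body, kind, "motif", "NO_MOTIF"))
        elif kind == "BAD_SPACING":
            for _ in range(1000):
                signal = _signal_peptide(rng, 2, 8)
                gaps = [rng.randint(lo, hi) for lo, hi in DEFAULT_MOTIF.segment_bounds]
                seg_idx, bad = _BAD_GAPS[rng.randrange(len(_BAD_GAPS))]
                gaps[seg_idx] = bad
                tail = list(_bg(rng, rng.randint(2, 10)))
                tail[1] = "A"
                mature = "".join(tail) + "C" + "C".join(
                    _bg(rng, g) for g in gaps
                ) + "C"
                precursor = signal + mature
                matched, _ = motif_scan(precursor, DEFAULT_MOTIF)
                if not matched and 30 <= len(precursor) <= 130:
                    out.append(_decoy(rid, precursor, kind, "motif", "NO_MOTIF"))
                    break
            else:
                raise GenerationError("BAD_SPACING decoy construction failed")
        elif kind == "NO_SIGNAL":
            for _ in range(1000):
                mature, _truth = _draw_mature(rng, base_spec)
                if not 30 <= len(mature) <= 130:
                    continue
                rec = SequenceRecord(id=rid, residues=mature)
                ann = heuristic_signal_predict(rec)
                if not ann.has_signal_peptide and not ann.has_transmembrane:
                    out.append(_decoy(rid, mature, kind, "secretion", "NO_SIGNAL"))
                    break
            else:
                raise GenerationError("NO_SIGNAL decoy construction failed")
        elif kind == "TM_LIKE":
            for _ in range(1000):
                sub = random.Random(rng.randrange(2**31))
                positive = None
                for _ in range(50):
                    positive = _validated_positive(sub, base_spec, rid)
                    if positive is not None:
                        break
                if positive is None:
                    continue
                residues = positive.record.residues + "I" * 10
                if not 50 <= len(residues) <= 130:
                    continue
                rec = SequenceRecord(id=rid, residues=residues)
                ann = heuristic_signal_predict(rec)
                matched, _ = motif_scan(residues, DEFAULT_MOTIF)
                if ann.has_signal_peptide and ann.has_transmembrane and matched:
                    out.append(_decoy(rid, residues, kind, "secretion", "HAS_TM"))
                    break
            else:
                raise GenerationError("TM_LIKE decoy construction failed")
        elif kind == "SHUFFLED_POSITIVE":
            sub = random.Random(rng.randrange(2**31))
            positive = None
            for _ in range(1000):
                positive = _validated_positive(sub, base_spec, rid + "|src")
                if positive is not None:
                    break
            if positive is None:
                raise GenerationError("SHUFFLED_POSITIVE source generation failed")
            mature_chars = list(positive.mature)
            rng.shuffle(mature_chars)
            signal = positive.record.residues[: positive.cleavage_site]
            out.append(
                _decoy(rid, signal + "".join(mature_chars), kind, None, None)
            )
    return out


def generate_family(
    n_members: int,
    mutation_rate: float,
    seed: int,
    defensin_class: str = "II",
) -> list[LabeledRecord]:
    """A founder mature peptide plus point-mutated copies.

    Cysteines are never mutated, so the framework positions are identical
    across the family; expected pairwise identity ~ (1 - mutation_rate)^2
    away from the founder lineage.
    """
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation rate must be in [0,1]")
    rng = random.Random(seed)
    spec = SyntheticSpec(defensin_class=defensin_class, seed=seed)
    founder = None
    for _ in range(1000):
        founder = _validated_positive(rng, spec, f"fam{seed}_0")
        if founder is not None:
            break
    if founder is None:
        raise GenerationError("family founder generation failed")
    members = [
        LabeledRecord(
            record=SequenceRecord(id=f"fam{seed}_0", residues=founder.mature),
            label=defensin_class,
            mature=founder.mature,
            framework=founder.framework,
            extra_cys=founder.extra_cys,
        )
    ]
    for i in range(1, n_members):
        mutated = []
        for a in founder.mature:
            if a != "C" and rng.random() < mutation_rate:
                choices = [x for x in BACKGROUND if x != a]
                mutated.append(rng.choice(choices))
            else:
                mutated.append(a)
        members.append(
            LabeledRecord(
                record=SequenceRecord(id=f"fam{seed}_{i}", residues="".join(mutated)),
                label=defensin_class,
                mature="".join(mutated),
                framework=founder.framework,
                extra_cys=founder.extra_cys,
            )
        )
    return members
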