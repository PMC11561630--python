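"""The candidate-filtering cascade: size, cysteine-spacing motif, secretion.

Candidate CSαβ-defensin precursors are kept when they (1) are 30-130
residues long, (2) contain six cysteines whose spacing matches the mining
pattern ``C-x(2,18)-C-x(3)-C-x(2,12)-C-x(4,17)-C-x-C``, and (3) look
secreted (signal peptide present, no transmembrane segment). Secretion
calls come from a Phobius short-format file when available, otherwise from
a built-in hydropathy heuristic that approximates one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_io import SecretionAnnotation, SequenceRecord

REASON_TOO_SHORT = "TOO_SHORT"
REASON_TOO_LONG = "TOO_LONG"
REASON_NO_MOTIF = "NO_MOTIF"
REASON_NO_SIGNAL = "NO_SIGNAL"
REASON_HAS_TM = "HAS_TM"
REASON_MATURE_TOO_SHORT = "MATURE_TOO_SHORT"
REASON_NO_STRUCT_SUPPORT = "NO_STRUCT_SUPPORT"

#: Kyte-Doolittle hydropathy; X (unknown residue) is scored neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


class ConfigurationError(ValueError):
    pass


class MatureTooShortError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """Inter-cysteine gap bounds of the six-cysteine mining pattern."""

    segment_bounds: tuple[tuple[int, int], ...] = (
        (2, 18), (3, 3), (2, 12), (4, 17), (1, 1),
    )
    n_framework_cysteines: int = 6

    def __post_init__(self) -> None:
        if len(self.segment_bounds) != self.n_framework_cysteines - 1:
            raise ConfigurationError("need one gap bound per cysteine pair")
        for lo, hi in self.segment_bounds:
            if lo < 1 or lo > hi:
                raise ConfigurationError(f"bad gap bound ({lo},{hi})")


DEFAULT_MOTIF = MotifSpec()


@dataclass
class FilterReport:
    """Audit record of one cascade stage: who was kept, who was removed, why."""

    stage: str
    kept: list[str] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)

    @property
    def n_in(self) -> int:
        return len(self.kept) + len(self.removed)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def size_filter(
    records: Sequence[SequenceRecord], min_len: int = 30, max_len: int = 130
) -> FilterReport:
    """Keep records with min_len <= length <= max_len (bounds inclusive)."""
    report = FilterReport(stage="size")
    for rec in records:
        if len(rec) < min_len:
            report.removed[rec.id] = REASON_TOO_SHORT
        elif len(rec) > max_len:
            report.removed[rec.id] = REASON_TOO_LONG
        else:
            report.kept.append(rec.id)
    return report


def cysteine_positions(residues: str) -> list[int]:
    """1-based positions of every cysteine."""
    return [i + 1 for i, a in enumerate(residues) if a == "C"]


def motif_scan(
    record: SequenceRecord | str, spec: MotifSpec = DEFAULT_MOTIF
) -> tuple[bool, list[tuple[int, ...]]]:
    """Find every ordered 6-subset of cysteines matching the spacing pattern.

    Residues between framework cysteines may themselves be cysteines (an
    8-cysteine sequence can satisfy the 6-cysteine pattern), so the search
    runs over ordered subsets of cysteine positions rather than a plain
    regular expression. Returns (matched, all satisfying assignments); the
    search prunes on the sortedness of positions, so it stays fast even for
    cysteine-rich inputs.
    """
    residues = record if isinstance(record, str) else record.residues
    cys = cysteine_positions(residues)
    k = spec.n_framework_cysteines
    bounds = spec.segment_bounds
    assignments: list[tuple[int, ...]] = []
    if len(cys) < k:
        return False, assignments

    def extend(path: list[int], start: int) -> None:
        if len(path) == k:
            assignments.append(tuple(path))
            return
        lo, hi = bounds[len(path) - 1]
        for j in range(start, len(cys)):
            gap = cys[j] - path[-1] - 1
            if gap > hi:
                break  # positions are sorted; gaps only grow
            if gap < lo:
                continue
            path.append(cys[j])
            extend(path, j + 1)
            path.pop()

    for i in range(len(cys) - k + 1):
        extend([cys[i]], i + 1)
    return bool(assignments), assignments


def motif_filter(
    records: Sequence[SequenceRecord], spec: MotifSpec = DEFAULT_MOTIF
) -> FilterReport:
    report = FilterReport(stage="motif")
    for rec in records:
        matched, _ = motif_scan(rec, spec)
        if matched:
            report.kept.append(rec.id)
        else:
            report.removed[rec.id] = REASON_NO_MOTIF
    return report


def secretion_gate(
    records: Sequence[SequenceRecord],
    annotations: Mapping[str, SecretionAnnotation],
) -> FilterReport:
    """Keep records predicted secreted: signal peptide and no TM segment."""
    missing = [rec.id for rec in records if rec.id not in annotations]
    if missing:
        raise ConfigurationError(
            f"no secretion annotation for ids: {', '.join(missing)}"
        )
    report = FilterReport(stage="secretion")
    for rec in records:
        ann = annotations[rec.id]
        if ann.has_transmembrane:
            report.removed[rec.id] = REASON_HAS_TM
        elif not ann.has_signal_peptide:
            report.removed[rec.id] = REASON_NO_SIGNAL
        else:
            report.kept.append(rec.id)
    return report


@dataclass(frozen=True)
class HeuristicParams:
    """Tunables of the built-in signal-peptide heuristic."""

    h_min: float = 1.5          # min mean hydropathy of the h-region window
    window: int = 7             # h-region window length
    n_search: int = 35          # signal window must lie in the first 35 residues
    kr_lookback: int = 5        # K/R required within 5 residues before window
    tm_after: int = 40          # hydrophobic window after here marks a TM
    cleavage_scan: int = 12     # residues scanned after window for a cleavage site


DEFAULT_HEURISTIC = HeuristicParams()


def _window_means(residues: str, width: int) -> list[float]:
    kd = [KYTE_DOOLITTLE[a] for a in residues]
    if len(kd) < width:
        return []
    acc = sum(kd[:width])
    means = [acc / width]
    for i in range(width, len(kd)):
        acc += kd[i] - kd[i - width]
        means.append(acc / width)
    return means


def heuristic_signal_predict(
    record: SequenceRecord, params: HeuristicParams = DEFAULT_HEURISTIC
) -> SecretionAnnotation:
    """Approximate secretion call from hydropathy alone.

    Signal peptide: a hydrophobic window (length ``window``, mean
    Kyte-Doolittle >= ``h_min``) inside the first ``n_search`` residues,
    preceded within ``kr_lookback`` residues by at least one K/R (the
    n-region charge). Cleavage site: the first A/G/S/C/T after the window
    followed two residues later by a small residue (A/G/S), else window end
    + 3. Transmembrane: any such hydrophobic window starting after position
    ``tm_after``. This is a deliberately simple stand-in for a dedicated
    predictor and is bypassed whenever a Phobius file is supplied.
    """
    seq = record.residues
    n = len(seq)
    w = params.window
    means = _window_means(seq, w)

    signal_start = None  # 0-based
    limit = min(params.n_search, n) - w
    for s0 in range(0, max(limit + 1, 0)):
        if means[s0] < params.h_min:
            continue
        before = seq[max(0, s0 - params.kr_lookback):s0]
        if any(a in "KR" for a in before):
            signal_start = s0
            break

    has_tm = any(
        means[s0] >= params.h_min
        for s0 in range(params.tm_after, len(means))
    )

    if signal_start is None:
        return SecretionAnnotation(record.id, False, has_tm, None)

    window_end = signal_start + w  # 0-based, exclusive
    cleavage = None
    for p0 in range(window_end, min(n - 2, window_end + params.cleavage_scan)):
        if seq[p0] in "AGSCT" and seq[p0 + 2] in "AGS":
            cleavage = p0 + 1  # 1-based
            break
    if cleavage is None:
        cleavage = window_end + 3  # 1-based window end (= window_end) + 3
    cleavage = max(1, min(cleavage, n - 1))
    return SecretionAnnotation(record.id, True, has_tm, cleavage)


def annotate_secretion(
    records: Sequence[SequenceRecord],
    phobius: Iterable[SecretionAnnotation] | None = None,
    params: HeuristicParams = DEFAULT_HEURISTIC,
) -> dict[str, SecretionAnnotation]:
    """Annotation map for a record set: Phobius file if given, else heuristic."""
    if phobius is not None:
        return {a.id: a for a in phobius}
    return {rec.id: heuristic_signal_predict(rec, params) for rec in records}


def extract_mature(
    record: SequenceRecord, annotation: SecretionAnnotation
) -> SequenceRecord:
    """Drop the signal peptide; the mature peptide keeps the id + "|mature"."""
    if not annotation.has_signal_peptide or annotation.cleavage_site is None:
        raise MatureTooShortError(f"{record.id}: no signal peptide/cleavage site")
    site = annotation.cleavage_site
    if site >= len(record) - 10:
        raise MatureTooShortError(
            f"{record.id}: cleavage at {site} leaves a mature region too "
            "short to hold a cysteine framework"
        )
    return SequenceRecord(
        id=f"{record.id}|mature",
        residues=record.residues[site:],
        kind=record.kind,
        description=record.description,
    )
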