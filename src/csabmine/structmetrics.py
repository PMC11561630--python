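"""Structural verification toolkit.

Small, exact utilities supporting the structural claims around a solved
NMR ensemble: Kabsch least-squares superposition, iterative ensemble RMSD
to the mean structure, NOE distance-restraint tallies by residue
separation, and exact-match in-silico PCR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio.Seq import Seq

BACKBONE_ATOMS = ("N", "CA", "C")


class StructureError(ValueError):
    pass


@dataclass
class StructureEnsemble:
    """Multi-model coordinates sharing one atom ordering.

    ``atoms`` is a list of (residue number, residue name, atom name);
    ``coords`` has shape (n_models, n_atoms, 3) in Angstroms.
    """

    atoms: list[tuple[int, str, str]]
    coords: np.ndarray

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def select(
        self,
        residue_range: tuple[int, int] | None = None,
        atom_names: Sequence[str] = BACKBONE_ATOMS,
    ) -> np.ndarray:
        """Coordinates restricted to a residue range and atom-name set."""
        names = set(atom_names)
        idx = [
            k
            for k, (resnum, _resname, atom) in enumerate(self.atoms)
            if atom in names
            and (residue_range is None or residue_range[0] <= resnum <= residue_range[1])
        ]
        if residue_range is not None:
            resnums = {a[0] for a in self.atoms}
            lo, hi = residue_range
            if not any(lo <= r <= hi for r in resnums):
                raise StructureError(
                    f"residue range {lo}-{hi} outside ensemble "
                    f"({min(resnums)}-{max(resnums)})"
                )
        return self.coords[:, idx, :]


def load_ensemble(
    path: str | Path, atom_names: Sequence[str] | None = None
) -> StructureEnsemble:
    """Load a multi-model PDB or mmCIF file (residue numbering kept verbatim)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    keep = set(atom_names) if atom_names else None

    def model_atoms(model: gemmi.Model):
        out = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if keep is None or atom.name in keep:
                        out.append(
                            (
                                residue.seqid.num,
                                residue.name,
                                atom.name,
                                (atom.pos.x, atom.pos.y, atom.pos.z),
                            )
                        )
        return out

    first = model_atoms(st[0])
    atoms = [(r, n, a) for r, n, a, _ in first]
    coords = np.empty((len(st), len(atoms), 3))
    for mi, model in enumerate(st):
        rows = model_atoms(model)
        if [(r, n, a) for r, n, a, _ in rows] != atoms:
            raise StructureError(
                f"{path}: model {mi + 1} atom ordering differs from model 1"
            )
        coords[mi] = [xyz for _, _, _, xyz in rows]
    return StructureEnsemble(atoms=atoms, coords=coords)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A.

    Returns (R, t, rmsd) with R a proper rotation (det +1) minimising
    ||B @ R.T + t - A||. Requires >= 3 non-collinear points.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise StructureError("coordinate sets must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise StructureError("superposition needs at least 3 points")
    cA = A.mean(axis=0)
    cB = B.mean(axis=0)
    Ac = A - cA
    Bc = B - cB
    if min(np.linalg.matrix_rank(Ac), np.linalg.matrix_rank(Bc)) < 2:
        raise StructureError("degenerate (collinear) coordinates")
    H = Bc.T @ Ac
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cA - R @ cB
    moved = Bc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Ac) ** 2, axis=1))))
    return R, t, rmsd


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    residue_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Mean +/- SD of per-model RMSD to the mean structure.

    Models are iteratively superposed onto the running coordinate mean
    until the mean RMSD changes by less than ``tol``. The headline value is
    the to-mean convention; SD uses ddof=1 (sample SD), or 0 for a single
    model.
    """
    coords = ensemble.select(residue_range, atom_names).copy()
    if coords.shape[1] < 3:
        raise StructureError("selection too small for superposition")
    reference = coords[0].copy()
    previous = None
    rmsds = np.zeros(coords.shape[0])
    for _ in range(max_iter):
        for mi in range(coords.shape[0]):
            R, t, _ = kabsch_superpose(reference, coords[mi])
            coords[mi] = coords[mi] @ R.T + t
        mean_struct = coords.mean(axis=0)
        rmsds = np.array([_rmsd(coords[mi], mean_struct) for mi in range(len(coords))])
        current = float(rmsds.mean())
        if previous is not None and abs(current - previous) < tol:
            break
        previous = current
        reference = mean_struct
    sd = float(rmsds.std(ddof=1)) if len(rmsds) > 1 else 0.0
    return float(rmsds.mean()), sd


# --- NOE distance restraints -------------------------------------------------

@dataclass(frozen=True)
class DistanceRestraint:
    residue_i: int
    residue_j: int
    bound: float | None = None

    def __post_init__(self) -> None:
        if self.residue_i < 1 or self.residue_j < 1:
            raise StructureError("residue indices are 1-based (>= 1)")


@dataclass(frozen=True)
class RestraintTally:
    intraresidue: int
    sequential: int
    medium: int
    long: int

    @property
    def total(self) -> int:
        return self.intraresidue + self.sequential + self.medium + self.long


def restraint_category(i: int, j: int) -> str:
    """Category by residue separation d=|i-j|: 0 intraresidue, 1 sequential,
    2-4 medium range, >=5 long range."""
    d = abs(i - j)
    if d == 0:
        return "intraresidue"
    if d == 1:
        return "sequential"
    if d < 5:
        return "medium"
    return "long"


def tally_restraints(restraints: Iterable[DistanceRestraint]) -> RestraintTally:
    counts = {"intraresidue": 0, "sequential": 0, "medium": 0, "long": 0}
    for r in restraints:
        counts[restraint_category(r.residue_i, r.residue_j)] += 1
    return RestraintTally(**counts)


def read_restraints_tsv(path: str | Path) -> list[DistanceRestraint]:
    """Two-column (i, j) restraint list; optional third column = bound in Å."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise StructureError(f"{path}: line {lineno}: need two columns")
        bound = float(parts[2]) if len(parts) > 2 else None
        out.append(DistanceRestraint(int(parts[0]), int(parts[1]), bound))
    return out


def read_restraints_upl(path: str | Path) -> list[DistanceRestraint]:
    """CYANA .upl upper-limit list: ``i resname atom j resname atom bound``."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise StructureError(f"{path}: line {lineno}: not a .upl row")
        out.append(
            DistanceRestraint(int(parts[0]), int(parts[3]), float(parts[6]))
        )
    return out


def read_restraints_nmrstar(path: str | Path) -> list[DistanceRestraint]:
    """Distance restraints from an NMR-STAR general-distance-constraint loop.

    Ambiguous restraints (several rows sharing a constraint ID) count once,
    using the first row's residue pair.
    """
    text = Path(path).read_text()
    restraints: list[DistanceRestraint] = []
    for loop in re.split(r"\bloop_\b", text)[1:]:
        lines = loop.splitlines()
        tags: list[str] = []
        data_start = None
        for k, line in enumerate(lines):
            token = line.strip()
            if token.startswith("_"):
                tags.append(token.split(".")[-1])
            elif token and tags:
                data_start = k
                break
        if data_start is None or "Seq_ID_1" not in tags or "Seq_ID_2" not in tags:
            continue
        i_col = tags.index("Seq_ID_1")
        j_col = tags.index("Seq_ID_2")
        id_col = tags.index("ID") if "ID" in tags else None
        seen_ids: set[str] = set()
        for line in lines[data_start:]:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token == "stop_":
                break
            parts = token.split()
            if len(parts) < len(tags):
                continue
            if id_col is not None:
                rid = parts[id_col]
                if rid in seen_ids:
                    continue
                seen_ids.add(rid)
            restraints.append(
                DistanceRestraint(int(parts[i_col]), int(parts[j_col]))
            )
    return restraints


def read_restraints(path: str | Path, format: str | None = None) -> list[DistanceRestraint]:
    path = Path(path)
    fmt = format or {
        ".upl": "upl",
        ".str": "nmrstar",
        ".tsv": "tsv",
        ".txt": "tsv",
    }.get(path.suffix.lower(), "tsv")
    reader = {
        "tsv": read_restraints_tsv,
        "upl": read_restraints_upl,
        "nmrstar": read_restraints_nmrstar,
    }.get(fmt)
    if reader is None:
        raise StructureError(f"unknown restraint format {fmt!r}")
    return reader(path)


# --- in-silico PCR -----------------------------------------------------------

@dataclass(frozen=True)
class PcrProduct:
    start: int    # 1-based start of forward primer site
    end: int      # 1-based end of reverse primer site
    length: int


@dataclass(frozen=True)
class PcrResult:
    status: str   # "OK" or "NO_PRODUCT"
    products: tuple[PcrProduct, ...] = field(default=())


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return hits
        hits.append(pos)
        start = pos + 1


def insilico_pcr(template: str, fwd_primer: str, rev_primer: str) -> PcrResult:
    """Exact-match PCR product prediction on the plus strand.

    The forward primer must match the template exactly; the reverse primer
    matches as its reverse complement downstream. Product length = end of
    the reverse site - start of the forward site + 1; every primer-site
    combination is reported. Absent sites give a NO_PRODUCT result, not an
    exception.
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise StructureError("primers must be >= 15 nt")
    rev_rc = str(Seq(rev).reverse_complement())
    fwd_sites = _find_all(template, fwd)
    rev_sites = _find_all(template, rev_rc)
    products = []
    for f0 in fwd_sites:
        for r0 in rev_sites:
            r_end = r0 + len(rev_rc)  # 0-based exclusive
            if r0 >= f0 + len(fwd):
                products.append(
                    PcrProduct(start=f0 + 1, end=r_end, length=r_end - f0)
                )
    if not products:
        return PcrResult(status="NO_PRODUCT")
    return PcrResult(status="OK", products=tuple(products))
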