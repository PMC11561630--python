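"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (exhaustive enumeration, closed
forms) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pytest

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


# --- exhaustive motif oracle -------------------------------------------------

def brute_force_motif(residues: str, bounds) -> list[tuple[int, ...]]:
    """All satisfying 6-subsets of cysteine positions, by full enumeration."""
    cys = [i + 1 for i, a in enumerate(residues) if a == "C"]
    hits = []
    for combo in itertools.combinations(cys, 6):
        gaps = [combo[k + 1] - combo[k] - 1 for k in range(5)]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, bounds)):
            hits.append(combo)
    return hits


# --- exhaustive global-alignment oracle --------------------------------------

def enumerate_alignments(a: str, b: str, match=1, mismatch=0, gap=-1):
    """(max score, set of (matches, length) over optimal alignments)."""
    best: dict = {"score": None, "shapes": set()}

    def walk(i, j, score, matches, length):
        if i == len(a) and j == len(b):
            if best["score"] is None or score > best["score"]:
                best["score"] = score
                best["shapes"] = {(matches, length)}
            elif score == best["score"]:
                best["shapes"].add((matches, length))
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, matches + (a[i] == b[j]), length + 1)
        if i < len(a):
            walk(i + 1, j, score + gap, matches, length + 1)
        if j < len(b):
            walk(i, j + 1, score + gap, matches, length + 1)

    walk(0, 0, 0, 0, 0)
    return best["score"], best["shapes"]


# --- quaternion superposition oracle (Horn's method) -------------------------

def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD superposing B onto A via the quaternion eigenvalue method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = Bc.T @ Ac
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = A.shape[0]
    e2 = (np.sum(Ac**2) + np.sum(Bc**2) - 2.0 * lam) / n
    return float(np.sqrt(max(e2, 0.0)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# --- synthetic multi-model PDB fixture ---------------------------------------

def write_model_pdb(path: Path, models: list[np.ndarray]) -> None:
    """Write an n-model backbone-only (N, CA, C) PDB file.

    Each model array has shape (3 * n_residues, 3); residues are numbered
    from 1 and named ALA (synthetic fixture, sequence-agnostic).
    """
    lines = []
    for mi, coords in enumerate(models, 1):
        lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for ri in range(len(coords) // 3):
            for ai, name in enumerate(("N", "CA", "C")):
                x, y, z = coords[ri * 3 + ai]
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}ALA A{ri + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        path.write_text(
            "".join(f">{header}\n{seq}\n" for header, seq in entries)
        )
        return path

    return _write
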