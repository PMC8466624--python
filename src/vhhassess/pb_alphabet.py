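"""Protein Blocks (PB) structural-alphabet assignment.

The PB alphabet discretises local backbone conformation into 16 prototypes
labelled ``a``..``p``, each defined by 8 dihedral angles over a five-residue
window centred on the assigned residue (order: psi(i-2), phi(i-1), psi(i-1),
phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2)).  PB ``m`` approximates the
core alpha-helix and ``d`` the central beta-strand.  Assignment picks the
prototype with the smallest RMSDA (root mean square deviation over the 8
wrapped angular differences).  Positions whose window is incomplete — the
two first and two last residues, or any window touching a missing atom —
receive the placeholder letter ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .structure_io import DihedralSeries, wrap_angle

PB_LETTERS = "abcdefghijklmnop"
UNDEFINED = "Z"

#: column order of the 8-angle window
WINDOW_ANGLES = (
    "psi_m2", "phi_m1", "psi_m1", "phi_0", "psi_0", "phi_p1", "psi_p1", "phi_p2",
)


@dataclass(frozen=True)
class PBReferenceTable:
    """The 16 PB dihedral prototypes as a (16, 8) array (degrees)."""

    angles: np.ndarray  # (16, 8), row order a..p

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.shape != (16, 8):
            raise ValueError("reference table must be 16 prototypes x 8 angles")
        if not ((a > -180.0) & (a <= 180.0)).all():
            raise ValueError("reference angles must lie in (-180, 180]")
        object.__setattr__(self, "angles", a)

    def prototype(self, letter: str) -> np.ndarray:
        """8-angle window of one prototype letter."""
        return self.angles[PB_LETTERS.index(letter)]

    def central_angles(self, letter: str) -> tuple:
        """(phi, psi) of the central residue of one prototype."""
        row = self.prototype(letter)
        return float(row[3]), float(row[4])


def load_reference_table() -> PBReferenceTable:
    """Load the canonical PB prototype table shipped as package data."""
    text = resources.files("vhhassess.data").joinpath(
        "pb_reference_angles.tsv").read_text()
    rows = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("pb\t"):
            continue
        parts = line.split("\t")
        rows[parts[0]] = [float(v) for v in parts[1:9]]
    if sorted(rows) != list(PB_LETTERS):
        raise ValueError("reference table must define letters a..p exactly once")
    return PBReferenceTable(np.array([rows[c] for c in PB_LETTERS]))


def rmsda(window, prototype) -> float:
    """Root mean square angular deviation between two 8-angle windows.

    Each per-component difference is wrapped to [-180, 180] degrees, so
    -179 vs +179 counts as 2 degrees, not 358.
    """
    w = np.asarray(window, dtype=float)
    p = np.asarray(prototype, dtype=float)
    if w.shape != (8,) or p.shape != (8,):
        raise ValueError("rmsda expects two 8-vectors")
    if not (np.isfinite(w).all() and np.isfinite(p).all()):
        raise ValueError("rmsda requires fully defined angle vectors")
    d = wrap_angle(w - p)
    return float(np.sqrt(np.mean(d * d)))


def dihedral_windows(dihedrals: DihedralSeries) -> np.ndarray:
    """Stack the 8-angle assignment window for every position.

    Returns an (L, 8) array; rows with any undefined contributing angle
    contain NaN (including the first two and last two positions).
    """
    L = len(dihedrals)
    phi, psi = dihedrals.phi, dihedrals.psi
    out = np.full((L, 8), np.nan)
    for i in range(2, L - 2):
        out[i] = (
            psi[i - 2], phi[i - 1], psi[i - 1], phi[i],
            psi[i], phi[i + 1], psi[i + 1], phi[i + 2],
        )
    return out


def assign_pb_sequence(dihedrals: DihedralSeries,
                       table: PBReferenceTable = None) -> str:
    """Assign one PB letter per residue by nearest prototype (RMSDA).

    Ties are broken alphabetically; positions without a fully defined
    window get ``Z``.  Chains shorter than 5 residues are all ``Z``.
    """
    if table is None:
        table = load_reference_table()
    L = len(dihedrals)
    windows = dihedral_windows(dihedrals)
    letters = [UNDEFINED] * L
    defined = np.isfinite(windows).all(axis=1)
    if defined.any():
        diff = wrap_angle(windows[defined][:, None, :] - table.angles[None, :, :])
        scores = np.sqrt(np.mean(diff * diff, axis=2))  # (n_defined, 16)
        best = np.argmin(scores, axis=1)  # first minimum == alphabetical tie-break
        for row, i in enumerate(np.nonzero(defined)[0]):
            letters[i] = PB_LETTERS[best[row]]
    return "".join(letters)


def pb_mismatch_count(s1: str, s2: str) -> int:
    """Count positions where both letters are defined (not Z) and differ."""
    if len(s1) != len(s2):
        raise ValueError("PB sequences must have equal length")
    return sum(
        1 for a, b in zip(s1, s2)
        if a != UNDEFINED and b != UNDEFINED and a != b
    )
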