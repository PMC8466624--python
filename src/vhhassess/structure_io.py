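"""Backbone-centric PDB structure I/O and dihedral geometry.

A :class:`BackboneChain` holds the four backbone heavy atoms (N, CA, C, O)
of one protein chain, re-indexed to a contiguous 1-based internal index.
Original author numbering (residue sequence number + insertion code) is
retained for reporting only; every residue range used elsewhere in this
package refers to the contiguous 1-based index with inclusive ends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA_1TO3 = {v: k for k, v in _AA_3TO1.items()}
_AA_1TO3["X"] = "UNK"


class ChainNotFoundError(KeyError):
    """Requested chain identifier is absent from the structure."""


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


@dataclass
class DihedralSeries:
    """Per-residue backbone (phi, psi) torsions in degrees; NaN = undefined.

    phi is undefined for the first residue and psi for the last; both are
    undefined wherever a contributing atom is missing.
    """

    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 1:
            raise ValueError("phi and psi must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.phi.shape[0]


@dataclass
class BackboneChain:
    """Ordered backbone (N, CA, C, O) coordinates of one chain.

    Parameters
    ----------
    chain_id : str
        Single-character chain identifier.
    sequence : str
        One-letter amino-acid codes; non-standard residues mapped to ``X``.
    coords : ndarray, shape (L, 4, 3)
        Coordinates in Angstrom, atom axis ordered N, CA, C, O.  Missing
        atoms are NaN.
    seq_numbers : ndarray of int, shape (L,)
        Original author residue numbers (reporting only).
    insertion_codes : list of str
        Original insertion codes ('' when none).
    """

    chain_id: str
    sequence: str
    coords: np.ndarray
    seq_numbers: np.ndarray = field(default=None)
    insertion_codes: list = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        L = len(self.sequence)
        if L < 1:
            raise ValueError("chain must contain at least one residue")
        if self.coords.shape != (L, 4, 3):
            raise ValueError(
                f"coords must have shape ({L}, 4, 3), got {self.coords.shape}"
            )
        if self.seq_numbers is None:
            self.seq_numbers = np.arange(1, L + 1)
        self.seq_numbers = np.asarray(self.seq_numbers, dtype=int)
        if self.insertion_codes is None:
            self.insertion_codes = [""] * L
        if len(self.insertion_codes) != L or self.seq_numbers.shape != (L,):
            raise ValueError("numbering metadata length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of residues with all four backbone atoms present."""
        return np.isfinite(self.coords).all(axis=(1, 2))

    @property
    def ca(self) -> np.ndarray:
        """C-alpha coordinates, shape (L, 3)."""
        return self.coords[:, 1, :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneChain":
        """Return a copy with every coordinate mapped to R.x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new = self.coords @ rotation.T + translation
        return BackboneChain(
            chain_id=self.chain_id,
            sequence=self.sequence,
            coords=new,
            seq_numbers=self.seq_numbers.copy(),
            insertion_codes=list(self.insertion_codes),
        )


def _select_altloc(atoms):
    """Pick one atom among altloc copies: highest occupancy, ties prefer
    blank altloc then 'A', then alphabetical."""
    def key(atom):
        alt = atom.altloc or ""
        return (-atom.occ, alt != "", alt)
    return sorted(atoms, key=key)[0]


def read_pdb_chain(path, chain_id: str, model_index: int = 0) -> BackboneChain:
    """Read one chain of a PDB file into a :class:`BackboneChain`.

    HETATM residues are excluded; alternate locations are resolved to the
    highest-occupancy conformer (ties to blank/'A'); residues missing any of
    N/CA/C/O keep NaN coordinates for the absent atoms.

    Parameters
    ----------
    path : str or Path
        PDB coordinate file.
    chain_id : str
        Chain identifier to extract.
    model_index : int
        Which MODEL record to read (0-based; default first).
    """
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"no models in {path}")
    if model_index >= len(structure):
        raise IndexError(
            f"model index {model_index} out of range ({len(structure)} models)"
        )
    model = structure[model_index]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(
            f"chain not found: {chain_id!r} absent from {path}"
        )

    seq, coords, numbers, icodes = [], [], [], []
    for res in chain:
        if res.het_flag == "H":
            continue
        by_name = {}
        for atom in res:
            if atom.name in BACKBONE_ATOMS:
                by_name.setdefault(atom.name, []).append(atom)
        if not by_name:
            continue
        xyz = np.full((4, 3), np.nan)
        for k, name in enumerate(BACKBONE_ATOMS):
            if name in by_name:
                pos = _select_altloc(by_name[name]).pos
                xyz[k] = (pos.x, pos.y, pos.z)
        seq.append(_AA_3TO1.get(res.name, "X"))
        coords.append(xyz)
        numbers.append(res.seqid.num)
        icodes.append(res.seqid.icode.strip())

    if not seq:
        raise ValueError(f"no parsable ATOM residues for chain {chain_id!r} in {path}")
    return BackboneChain(
        chain_id=chain_id,
        sequence="".join(seq),
        coords=np.asarray(coords),
        seq_numbers=np.asarray(numbers),
        insertion_codes=icodes,
    )


def write_pdb(chain: BackboneChain, path) -> None:
    """Write a backbone chain as fixed-column PDB ATOM records.

    Coordinates survive a write/read round trip to 1e-3 Angstrom (the PDB
    fixed-column precision).  Atoms with NaN coordinates are omitted.
    """
    if len(chain) < 1:
        raise ValueError("cannot write an empty chain")
    lines = []
    serial = 1
    for i in range(len(chain)):
        resname = _AA_1TO3.get(chain.sequence[i], "UNK")
        for k, name in enumerate(BACKBONE_ATOMS):
            x, y, z = chain.coords[i, k]
            if not np.isfinite([x, y, z]).all():
                continue
            lines.append(
                f"ATOM  {serial:>5d} {name:^4s} {resname:>3s} {chain.chain_id:1s}"
                f"{int(chain.seq_numbers[i]):>4d}{(chain.insertion_codes[i] or ' '):1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _torsion(p0, p1, p2, p3):
    """Torsion angle p0-p1-p2-p3 in degrees, (-180, 180]; NaN if degenerate."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    if not np.isfinite(np.concatenate([p0, p1, p2, p3])).all():
        return np.nan
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        return np.nan
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        # contributing atoms nearly collinear: torsion undefined
        warnings.warn("torsion numerically undefined (collinear atoms)")
        return np.nan
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def compute_backbone_dihedrals(chain: BackboneChain) -> DihedralSeries:
    """Compute per-residue (phi, psi) from backbone coordinates.

    phi_i is the torsion C(i-1)-N(i)-CA(i)-C(i); psi_i is
    N(i)-CA(i)-C(i)-N(i+1).  Positions adjacent to missing atoms are NaN.
    """
    L = len(chain)
    if L < 2:
        raise ValueError("need at least 2 residues for backbone dihedrals")
    N, CA, C = chain.coords[:, 0], chain.coords[:, 1], chain.coords[:, 2]
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    for i in range(L):
        if i > 0:
            phi[i] = _torsion(C[i - 1], N[i], CA[i], C[i])
        if i < L - 1:
            psi[i] = _torsion(N[i], CA[i], C[i], N[i + 1])
    return DihedralSeries(phi=phi, psi=psi)


def chain_to_fasta(chain: BackboneChain, record_id: str = None) -> str:
    """Render the chain sequence as a FASTA record."""
    rid = record_id or f"chain_{chain.chain_id}"
    return f">{rid}\n{chain.sequence}\n"
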