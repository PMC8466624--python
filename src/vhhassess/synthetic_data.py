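"""Synthetic backbone chains and model ensembles.

This module generates the inputs that the assessment pipeline is normally
fed by a comparative-modelling engine: an ensemble of backbone models of one
query sharing its sequence and length.  A reference conformation is written
down as a PB string, converted to (phi, psi) torsions via the PB prototype
table, perturbed per model with position-dependent von Mises angular noise
(low concentration kappa in CDR-like segments, high in frameworks), and
rebuilt to Cartesian coordinates from ideal internal coordinates (NeRF-style
chain extension, omega fixed trans).  Each model also receives a synthetic
quality score that is an affine function of its true C-alpha RMSD to the
reference plus Gaussian noise, mimicking how a statistical potential such as
DOPE correlates with model quality: lower score = better model.

All randomness flows through a single ``numpy`` Generator seeded from the
spec; draws are made in a fixed documented order (per model: phi noise for
all positions, then psi noise, then the score noise), so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pb_alphabet import PB_LETTERS, PBReferenceTable, load_reference_table
from .structure_io import BackboneChain, DihedralSeries, wrap_angle
from .superpose_metrics import superpose_calpha

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) = angle,
    torsion(a,b,c,d) = torsion."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _seed_residue(coords, i):
    """Place residue i's N/CA/C in the canonical frame (N at origin, CA on
    x, C in the xy-plane)."""
    coords[i, 0] = np.zeros(3)
    coords[i, 1] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    coords[i, 2] = coords[i, 1] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])


def _extend_backbone(coords, phi, psi, first: int, last: int, seed):
    """Fill N/CA/C of residues first..last (0-based, inclusive) by NeRF
    extension from ``seed`` = (N, CA, C) of residue first-1."""
    prev_n, prev_ca, prev_c = seed
    for i in range(first, last + 1):
        n = _place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca = _place_atom(prev_ca, prev_c, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c = _place_atom(prev_c, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = n, ca, c
        prev_n, prev_ca, prev_c = n, ca, c


def _place_oxygens(coords, psi):
    """Carbonyl O in the peptide plane, trans to the following amide N."""
    L = coords.shape[0]
    for i in range(L):
        psi_i = psi[i] if i < L - 1 and np.isfinite(psi[i]) else 0.0
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            BOND_C_O, ANGLE_CA_C_O, wrap_angle(psi_i - 180.0))


def chain_from_dihedrals(dihedrals: DihedralSeries, sequence: str,
                         chain_id: str = "A") -> BackboneChain:
    """Build Cartesian backbone coordinates from (phi, psi) torsions.

    Ideal bond lengths and angles are used and omega is fixed trans, so the
    torsions are the only degrees of freedom; ``compute_backbone_dihedrals``
    on the result recovers the inputs to numerical precision.  The carbonyl
    oxygen is placed in the peptide plane opposite the next amide nitrogen.
    """
    L = len(sequence)
    if len(dihedrals) != L:
        raise ValueError("dihedral series length must equal sequence length")
    phi, psi = dihedrals.phi, dihedrals.psi
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        raise ValueError("undefined interior dihedral; cannot build chain")

    coords = np.full((L, 4, 3), np.nan)
    _seed_residue(coords, 0)
    if L > 1:
        _extend_backbone(coords, phi, psi, 1, L - 1, tuple(coords[0, :3]))
    _place_oxygens(coords, psi)
    return BackboneChain(chain_id=chain_id, sequence=sequence, coords=coords)


def chain_from_dihedrals_anchored(dihedrals: DihedralSeries, sequence: str,
                                  reference: BackboneChain, segments,
                                  chain_id: str = "A") -> BackboneChain:
    """Segment-anchored backbone assembly.

    Each 1-based inclusive segment of ``segments`` is rebuilt by NeRF from
    the given torsions, but seeded from the *reference* chain's backbone
    frame at the residue preceding the segment (the first segment uses the
    canonical seed).  This emulates template-restrained modelling: torsion
    noise inside one segment displaces that segment only, instead of
    levering every downstream residue, at the cost of small peptide-bond
    discontinuities at segment boundaries.  With zero noise the reference
    coordinates are reproduced exactly.
    """
    L = len(sequence)
    if len(dihedrals) != L or len(reference) != L:
        raise ValueError("dihedrals, sequence and reference must share length")
    segs = sorted((int(s), int(e)) for s, e in segments)
    if segs[0][0] != 1 or segs[-1][1] != L or any(
            segs[k + 1][0] != segs[k][1] + 1 for k in range(len(segs) - 1)):
        raise ValueError("segments must partition 1..L")
    phi, psi = dihedrals.phi, dihedrals.psi
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        raise ValueError("undefined interior dihedral; cannot build chain")

    ref_dih = None
    coords = np.full((L, 4, 3), np.nan)
    for s, e in segs:
        if s == 1:
            _seed_residue(coords, 0)
            if e > 1:
                _extend_backbone(coords, phi, psi, 1, e - 1, tuple(coords[0, :3]))
        else:
            # the anchor residue s-1 lies outside the segment: its psi (which
            # orients the whole segment) is taken from the reference so that
            # noise in a preceding segment cannot lever this one
            if ref_dih is None:
                from .structure_io import compute_backbone_dihedrals
                ref_dih = compute_backbone_dihedrals(reference)
            psi_loc = psi.copy()
            psi_loc[s - 2] = ref_dih.psi[s - 2]
            seed = tuple(reference.coords[s - 2, :3])
            _extend_backbone(coords, phi, psi_loc, s - 1, e - 1, seed)
    _place_oxygens(coords, psi)
    return BackboneChain(chain_id=chain_id, sequence=sequence, coords=coords)


def pb_string_to_dihedrals(pb_string: str,
                           table: PBReferenceTable = None) -> DihedralSeries:
    """Torsions whose per-position (phi, psi) are each PB letter's
    central-residue prototype angles.

    The first phi and last psi are left undefined, as in a measured series.
    """
    if table is None:
        table = load_reference_table()
    bad = set(pb_string) - set(PB_LETTERS)
    if bad:
        raise ValueError(f"PB string contains non-assignable letters: {sorted(bad)}")
    centres = np.array([table.central_angles(c) for c in pb_string])
    phi, psi = centres[:, 0].copy(), centres[:, 1].copy()
    phi[0] = np.nan
    psi[-1] = np.nan
    return DihedralSeries(phi=phi, psi=psi)


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic model ensemble of one query.

    Attributes
    ----------
    reference_pb_string : str
        PB letters (a..p) defining the reference conformation.
    kappa_profile : array-like
        Per-position von Mises concentration; small kappa = strong angular
        noise (CDR-like), large kappa = near-rigid (framework-like).
    n_models : int
        Ensemble size (the study default is 100 models per query).
    seed : int
        Seed of the single generator driving all draws.
    score_noise : float
        Std-dev of the Gaussian noise on the synthetic quality score.
    score_slope / score_offset : float
        score = offset + slope * (global CA RMSD to reference) + noise; the
        defaults give DOPE-like magnitudes with lower = better.
    sequence : str, optional
        Amino-acid sequence; defaults to poly-alanine of matching length.
    anchor_segments : list of (start, end), optional
        1-based inclusive segments (typically the FR/CDR region map) for
        segment-anchored assembly; each model segment is rebuilt from the
        reference anchor frame so noise stays local (see
        :func:`chain_from_dihedrals_anchored`).  None = plain NeRF
        propagation over the whole chain.
    """

    reference_pb_string: str
    kappa_profile: np.ndarray
    n_models: int = 100
    seed: int = 0
    score_noise: float = 5.0
    score_slope: float = 150.0
    score_offset: float = -13000.0
    sequence: str = None
    anchor_segments: list = None

    def __post_init__(self):
        self.kappa_profile = np.asarray(self.kappa_profile, dtype=float)
        L = len(self.reference_pb_string)
        if self.kappa_profile.shape != (L,):
            raise ValueError("kappa_profile length must match the PB string")
        if (self.kappa_profile <= 0).any() or np.isnan(self.kappa_profile).any():
            raise ValueError("kappa must be > 0 everywhere (inf = no noise)")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.sequence is None:
            self.sequence = "A" * L
        if len(self.sequence) != L:
            raise ValueError("sequence length must match the PB string")


def reference_chain(spec: EnsembleSpec,
                    table: PBReferenceTable = None) -> BackboneChain:
    """The unperturbed reference conformation of an ensemble spec."""
    return chain_from_dihedrals(
        pb_string_to_dihedrals(spec.reference_pb_string, table), spec.sequence)


def generate_ensemble(spec: EnsembleSpec, table: PBReferenceTable = None):
    """Sample a model ensemble and its synthetic quality scores.

    Returns
    -------
    models : list of BackboneChain
    scores : pandas.DataFrame with columns model_id, rmsd_to_reference, score
    """
    if table is None:
        table = load_reference_table()
    ref_dih = pb_string_to_dihedrals(spec.reference_pb_string, table)
    ref = chain_from_dihedrals(ref_dih, spec.sequence)
    rng = np.random.default_rng(spec.seed)
    L = len(spec.reference_pb_string)

    finite = np.isfinite(spec.kappa_profile)
    kappa_draw = np.where(finite, spec.kappa_profile, 1.0)  # placeholder at inf
    models, rows = [], []
    for k in range(spec.n_models):
        dphi = np.degrees(rng.vonmises(0.0, kappa_draw, size=L)) * finite
        dpsi = np.degrees(rng.vonmises(0.0, kappa_draw, size=L)) * finite
        phi = wrap_angle(ref_dih.phi + dphi)
        psi = wrap_angle(ref_dih.psi + dpsi)
        phi[0] = np.nan
        psi[-1] = np.nan
        noisy = DihedralSeries(phi, psi)
        if spec.anchor_segments is not None:
            model = chain_from_dihedrals_anchored(
                noisy, spec.sequence, ref, spec.anchor_segments)
        else:
            model = chain_from_dihedrals(noisy, spec.sequence)
        rmsd = superpose_calpha(model, ref).rmsd
        score = (spec.score_offset + spec.score_slope * rmsd
                 + rng.normal(0.0, spec.score_noise))
        models.append(model)
        rows.append({"model_id": f"model_{k:03d}",
                     "rmsd_to_reference": rmsd, "score": score})
    return models, pd.DataFrame(rows)


# a solved llama VHH-like variable-domain sequence used as the family
# ancestor (synthetic: hand-assembled from consensus framework motifs with
# the conserved Cys22/Cys92 pair and the FR4 WGQG motif)
ANCESTOR_VHH = (
    "QVQLVESGGGLVQAGGSLRLSCAASGRTFSSYAMGWFRQAPGKEREFVAAISWSGGSTYY"
    "ADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAADRGSYYYTRSEYDYWGQGTQVTVSS"
)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _identity_for_rate(p: float) -> float:
    # expected pairwise identity between two independently mutated copies:
    # both unmutated, or both mutated to the same of the 19 alternatives
    return (1.0 - p) ** 2 + (p ** 2) / 19.0


def generate_vhh_like_family(n_sequences: int, target_identity: float,
                             seed: int = 0, ancestor: str = ANCESTOR_VHH) -> dict:
    """Sequence family with a prescribed mean pairwise identity.

    An ancestor sequence is independently mutated per copy at a per-position
    substitution rate solved so the expected pairwise identity equals
    ``target_identity`` percent (the VHH structural dataset this emulates
    averages ~64%).  Returns an ordered {id: sequence} mapping.
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target identity must be in (0, 100]")
    t = target_identity / 100.0
    floor = _identity_for_rate(1.0)
    if t < floor:
        raise ValueError(
            f"unreachable target: minimum achievable identity is {100 * floor:.1f}%")
    if t >= 1.0:
        p = 0.0
    else:
        from scipy.optimize import brentq
        p = brentq(lambda q: _identity_for_rate(q) - t, 0.0, 1.0)

    rng = np.random.default_rng(seed)
    L = len(ancestor)
    out = {}
    for k in range(n_sequences):
        seq = list(ancestor)
        mutate = rng.random(L) < p
        for i in np.nonzero(mutate)[0]:
            choices = _ALPHABET.replace(seq[i], "")
            seq[i] = choices[rng.integers(len(choices))]
        out[f"seq_{k:03d}"] = "".join(seq)
    return out


def family_to_fasta(family: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in family.items():
            fh.write(f">{name}\n{seq}\n")
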