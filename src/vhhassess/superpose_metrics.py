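"""Rigid-body superposition, C-alpha RMSD metrics and backbone validation.

Superposition minimises sum ||R.x + t - y||^2 over proper rotations via the
standard SVD least-squares solution (reflections corrected), as implemented
by :func:`scipy.spatial.transform.Rotation.align_vectors`.  Region-wise RMSD
supports two frames:

``local_fit``
    each region is superposed on its own C-alpha atoms, so framework and
    loop values are independent of one another;
``frame_fit``
    the model is superposed once on all framework C-alpha atoms and every
    region RMSD is then measured without refitting, which exposes loops that
    swing relative to a well-modelled scaffold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial.transform import Rotation

from .structure_io import BackboneChain, DihedralSeries


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map R.x + t of mobile onto reference C-alpha atoms."""

    rotation: np.ndarray   # (3, 3) proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float            # Angstrom
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _paired_ca(mobile: BackboneChain, reference: BackboneChain, pairing):
    if pairing is None:
        if len(mobile) != len(reference):
            raise ValueError("positional pairing requires equal-length chains")
        idx_m = idx_r = np.arange(len(mobile))
    else:
        pairs = np.asarray(list(pairing), dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairing must be a list of (mobile, reference) pairs")
        idx_m, idx_r = pairs[:, 0] - 1, pairs[:, 1] - 1  # 1-based API
    x, y = mobile.ca[idx_m], reference.ca[idx_r]
    ok = np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1)
    return x[ok], y[ok]


def superpose_points(x: np.ndarray, y: np.ndarray) -> Superposition:
    """Least-squares superposition of point set x onto y (shape (n, 3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - cx, y - cy
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2 or np.linalg.matrix_rank(yc, tol=1e-8) < 2:
        raise ValueError("superposition undefined: points are collinear")
    rot, _ = Rotation.align_vectors(yc, xc)
    R = rot.as_matrix()
    t = cy - R @ cx
    # recompute the residual directly: scipy's rssd loses precision to
    # cancellation when the fit is near-exact
    d = xc @ R.T - yc
    return Superposition(
        rotation=R,
        translation=t,
        rmsd=float(np.sqrt(np.mean(np.sum(d * d, axis=1)))),
        n_atoms=int(n),
    )


def superpose_calpha(mobile: BackboneChain, reference: BackboneChain,
                     pairing=None) -> Superposition:
    """Optimal C-alpha superposition of ``mobile`` onto ``reference``.

    ``pairing`` is an optional list of 1-based (mobile_index,
    reference_index) pairs; by default chains are paired positionally
    (models of the same query).  Pairs with missing C-alpha atoms are
    dropped.
    """
    x, y = _paired_ca(mobile, reference, pairing)
    return superpose_points(x, y)


def _region_indices(region) -> np.ndarray:
    start, end = int(region[0]), int(region[1])
    if end < start:
        raise ValueError("region end before start")
    return np.arange(start - 1, end)


def region_rmsd(model: BackboneChain, native: BackboneChain, regions,
                mode: str = "local_fit") -> dict:
    """Per-region C-alpha RMSD between a model and its native structure.

    ``regions`` is a RegionMap or a mapping name -> (start, end) with
    1-based inclusive bounds.  Chains must share length and numbering.
    """
    if len(model) != len(native):
        raise ValueError("model and native must share length/numbering")
    items = regions.items() if hasattr(regions, "items") else dict(regions).items()
    segs = {name: _region_indices(rng) for name, rng in items}
    for name, idx in segs.items():
        if idx.min() < 0 or idx.max() >= len(model):
            raise ValueError(f"region {name} outside chain (length {len(model)})")

    out = {}
    if mode == "local_fit":
        for name, idx in segs.items():
            if idx.size < 3:
                raise ValueError(
                    f"region {name} shorter than 3 residues in local_fit mode")
            sup = superpose_points(model.ca[idx], native.ca[idx])
            out[name] = sup.rmsd
    elif mode == "frame_fit":
        fr_idx = np.concatenate(
            [idx for name, idx in segs.items() if name.upper().startswith("FR")])
        if fr_idx.size < 3:
            raise ValueError("frame_fit requires framework regions (FR*)")
        sup = superpose_points(model.ca[fr_idx], native.ca[fr_idx])
        moved = sup.apply(model.ca)
        for name, idx in segs.items():
            d = moved[idx] - native.ca[idx]
            out[name] = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    else:
        raise ValueError("mode must be 'local_fit' or 'frame_fit'")
    return out


def loop_termini_distance(chain: BackboneChain, region) -> float:
    """Euclidean C-alpha distance between the first and last residues of a
    region (1-based inclusive range), e.g. the anchor separation of a CDR
    loop."""
    idx = _region_indices(region)
    if idx.min() < 0 or idx.max() >= len(chain):
        raise ValueError("region outside chain")
    first, last = idx[0], idx[-1]
    comp = chain.complete
    if not (comp[first] and comp[last]):
        raise ValueError("terminal residue of region is incomplete")
    return float(np.linalg.norm(chain.ca[last] - chain.ca[first]))


def _load_rama_regions():
    text = resources.files("vhhassess.data").joinpath(
        "ramachandran_regions.json").read_text()
    spec = json.loads(text)
    return {
        kind: [MplPath(np.asarray(poly["vertices"], dtype=float))
               for poly in spec[kind]]
        for kind in ("favored", "allowed")
    }


def ramachandran_fractions(dihedrals: DihedralSeries) -> dict:
    """Classify defined (phi, psi) pairs into favored/allowed/unfavorable.

    Uses the simplified region polygons shipped with the package (see
    ``data/ramachandran_regions.json``); returns percentages over the
    defined positions, summing to 100.
    """
    mask = np.isfinite(dihedrals.phi) & np.isfinite(dihedrals.psi)
    if not mask.any():
        raise ValueError("no positions with both phi and psi defined")
    pts = np.column_stack([dihedrals.phi[mask], dihedrals.psi[mask]])
    regions = _load_rama_regions()
    fav = np.zeros(len(pts), dtype=bool)
    for path in regions["favored"]:
        fav |= path.contains_points(pts, radius=1e-9)
    allowed = np.zeros(len(pts), dtype=bool)
    for path in regions["allowed"]:
        allowed |= path.contains_points(pts, radius=1e-9)
    allowed &= ~fav
    n = len(pts)
    pf = 100.0 * fav.sum() / n
    pa = 100.0 * allowed.sum() / n
    return {"favored": pf, "allowed": pa, "unfavorable": 100.0 - pf - pa}
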