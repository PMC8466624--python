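import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import TOY_PB_STRING, TOY_REGIONS, make_helix_chain, random_rigid_transform
from helpers_oracles import grid_search_rmsd
from vhhassess.structure_io import BackboneChain, DihedralSeries, compute_backbone_dihedrals
from vhhassess.superpose_metrics import (
    loop_termini_distance,
    ramachandran_fractions,
    region_rmsd,
    superpose_calpha,
    superpose_points,
)
from vhhassess.synthetic_data import EnsembleSpec, generate_ensemble, reference_chain


def chain_with_ca(ca_coords):
    """Backbone chain whose CA atoms are given; N/C/O placed nearby."""
    ca = np.asarray(ca_coords, dtype=float)
    L = ca.shape[0]
    coords = np.empty((L, 4, 3))
    coords[:, 1] = ca
    coords[:, 0] = ca + [1.0, 0.0, 0.0]
    coords[:, 2] = ca + [0.0, 1.0, 0.0]
    coords[:, 3] = ca + [0.0, 0.0, 1.0]
    return BackboneChain(chain_id="A", sequence="A" * L, coords=coords)


class TestSuperposition:
    def test_self_superposition_identity(self, helix_chain):
        sup = superpose_calpha(helix_chain, helix_chain)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert sup.n_atoms == len(helix_chain)

    def test_rigid_copy_recovered(self, helix_chain):
        rng = np.random.default_rng(1)
        R, t = random_rigid_transform(rng)
        moved = helix_chain.transformed(R, t)
        sup = superpose_calpha(moved, helix_chain)
        assert sup.rmsd < 1e-9
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_search(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            x = rng.normal(size=(4, 3))
            y = rng.normal(size=(4, 3))
            analytic = superpose_points(x, y).rmsd
            grid = grid_search_rmsd(x, y)
            assert analytic <= grid + 1e-12      # optimality
            assert grid - analytic < 0.02        # grid resolution bound

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        a = superpose_points(x, y).rmsd
        b = superpose_points(y, x).rmsd
        assert a == pytest.approx(b, abs=1e-9)

    def test_invariant_to_pretransform(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(8, 3))
        y = rng.normal(size=(8, 3))
        base = superpose_points(x, y).rmsd
        R, t = random_rigid_transform(rng)
        assert superpose_points(x @ R.T + t, y).rmsd == pytest.approx(base, abs=1e-9)
        assert superpose_points(x, y @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            superpose_points(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            superpose_points(line, line)

    def test_proper_rotation_never_reflection(self):
        # near-planar point sets tempt the solver into a reflection
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 3)) * [1.0, 1.0, 1e-4]
        y = -x  # mirror image
        sup = superpose_points(x, y)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


class TestRegionRmsd:
    def test_whole_chain_region_equals_global(self, helix_chain):
        rng = np.random.default_rng(2)
        other = make_helix_chain(20, phi=-60.0, psi=-45.0)
        whole = region_rmsd(other, helix_chain, {"ALL": (1, 20)},
                            mode="local_fit")["ALL"]
        assert whole == pytest.approx(
            superpose_calpha(other, helix_chain).rmsd, abs=1e-9)

    def test_identical_chains_zero_everywhere(self):
        spec = EnsembleSpec(TOY_PB_STRING, np.full(75, 100.0))
        ref = reference_chain(spec)
        for mode in ("local_fit", "frame_fit"):
            rr = region_rmsd(ref, ref, TOY_REGIONS, mode=mode)
            assert all(v == pytest.approx(0.0, abs=1e-9) for v in rr.values())

    def test_cdr3_only_perturbation_localised(self):
        kappa = np.full(75, np.inf)
        kappa[50:62] = 2.0  # CDR3 window only
        spec = EnsembleSpec(TOY_PB_STRING, kappa, n_models=3, seed=5,
                            anchor_segments=list(TOY_REGIONS.values()))
        models, _ = generate_ensemble(spec)
        ref = reference_chain(spec)
        rr = region_rmsd(models[0], ref, TOY_REGIONS, mode="frame_fit")
        for name, value in rr.items():
            if name == "CDR3":
                assert value > 1.0
            else:
                assert value < 0.05

    def test_bad_regions_rejected(self, helix_chain):
        with pytest.raises(ValueError):
            region_rmsd(helix_chain, helix_chain, {"FR1": (1, 30)})
        with pytest.raises(ValueError, match="shorter than 3"):
            region_rmsd(helix_chain, helix_chain, {"FR1": (1, 2)},
                        mode="local_fit")


class TestLoopTerminiDistance:
    def test_pythagorean_distance(self):
        chain = chain_with_ca([[0, 0, 0], [1, 1, 1], [3, 4, 0]])
        assert loop_termini_distance(chain, (1, 3)) == pytest.approx(5.0)

    def test_rigid_invariance(self, helix_chain):
        d0 = loop_termini_distance(helix_chain, (3, 15))
        rng = np.random.default_rng(6)
        R, t = random_rigid_transform(rng)
        d1 = loop_termini_distance(helix_chain.transformed(R, t), (3, 15))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_incomplete_terminus_rejected(self, helix_chain):
        helix_chain.coords[2, 3] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            loop_termini_distance(helix_chain, (3, 15))


class TestRamachandran:
    def test_ideal_helix_fully_favored(self):
        dih = compute_backbone_dihedrals(make_helix_chain(20))
        frac = ramachandran_fractions(dih)
        assert frac["favored"] == pytest.approx(100.0)
        assert frac["unfavorable"] == pytest.approx(0.0)

    def test_disallowed_corner_fully_unfavorable(self):
        dih = compute_backbone_dihedrals(make_helix_chain(20, phi=60.0, psi=-120.0))
        frac = ramachandran_fractions(dih)
        assert frac["unfavorable"] == pytest.approx(100.0)

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(17)
        phi = np.r_[np.nan, rng.uniform(-180, 180, 30)]
        psi = np.r_[rng.uniform(-180, 180, 30), np.nan]
        frac = ramachandran_fractions(DihedralSeries(phi, psi))
        assert frac["favored"] + frac["allowed"] + frac["unfavorable"] == pytest.approx(100.0)

    def test_no_defined_positions_rejected(self):
        dih = DihedralSeries(np.full(4, np.nan), np.full(4, np.nan))
        with pytest.raises(ValueError):
            ramachandran_fractions(dih)


def test_mean_rmsd_increases_with_angular_noise():
    """Ensembles sampled at growing angular noise drift monotonically
    further from the reference (Spearman rho > 0.9 over 5 noise levels)."""
    kappas = [500.0, 100.0, 20.0, 5.0, 1.0]  # decreasing kappa = more noise
    means = []
    for i, kappa in enumerate(kappas):
        spec = EnsembleSpec("d" * 30, np.full(30, kappa), n_models=50, seed=21)
        _, scores = generate_ensemble(spec)
        means.append(scores.rmsd_to_reference.mean())
    rho = spearmanr(np.arange(5), means).statistic
    assert rho > 0.9
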