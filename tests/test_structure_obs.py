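import numpy as np
import pytest

from idplens.ensemble import Ensemble, Topology, topology_for
from idplens.rg_decompose import assign_groups, ensemble_rg
from idplens.seqprofile import load_peptide
from idplens.structure_obs import (DEFAULT_RAMA_REGIONS, KarplusParams,
                                   ObservableError, SS_CLASSES,
                                   assign_frame_ss,
                                   assign_secondary_structure,
                                   backbone_dihedrals, hbond_map,
                                   j_couplings, karplus_j2, karplus_j3,
                                   min_ca_distance_map, ramachandran, sasa,
                                   sasa_group_summary)
from idplens.synthetic import GeneratorConfig, build_chain, sample_ensemble

from conftest import as_mdtraj


def _atoms(coords, radii_el="C"):
    n = len(coords)
    top = Topology(tuple("CA" for _ in range(n)),
                   tuple(radii_el for _ in range(n)),
                   np.arange(n), tuple("A" for _ in range(n)), np.ones(n))
    return Ensemble(top, np.asarray(coords, float)[None])


class TestSasa:
    def test_isolated_sphere_analytic(self):
        ens = _atoms([[0.0, 0.0, 0.0]])
        s = sasa(ens, probe=1.4, n_points=960)
        expect = 4 * np.pi * (1.7 + 1.4) ** 2 / 100.0
        assert s.total[0] == pytest.approx(expect, rel=5e-3)

    def test_far_separated_atoms_additive(self):
        iso = sasa(_atoms([[0, 0, 0]])).total[0]
        two = sasa(_atoms([[0, 0, 0], [100.0, 0, 0]])).total[0]
        assert two == pytest.approx(2 * iso, rel=1e-12)

    def test_overlap_reduces_area_symmetrically(self):
        ens = _atoms([[0, 0, 0], [1.0, 0, 0]])
        s = sasa(ens)
        iso = sasa(_atoms([[0, 0, 0]])).total[0]
        assert s.total[0] < 2 * iso
        # symmetric up to sphere-point discretization
        assert s.per_residue[0, 0] == pytest.approx(s.per_residue[0, 1],
                                                    rel=0.02)

    def test_per_residue_sums_to_total(self, free_ensemble):
        s = sasa(free_ensemble.subset([0, 50]))
        assert np.allclose(s.per_residue.sum(axis=1), s.total, atol=1e-6)

    def test_matches_mdtraj_within_two_percent(self, free_ensemble):
        md = pytest.importorskip("mdtraj")
        sub = free_ensemble.subset([0, 100])
        ours = sasa(sub).total
        traj = as_mdtraj(sub, sub.topology)
        ref = md.shrake_rupley(traj, probe_radius=0.14,
                               n_sphere_points=960).sum(axis=1)
        assert np.all(np.abs(ours - ref) / ref < 0.02)

    def test_translation_rotation_invariance(self, free_ensemble):
        from scipy.spatial.transform import Rotation
        sub = free_ensemble.subset(np.arange(0, 40, 10))
        # translation: exact (test points ride with their atoms)
        shifted = Ensemble(sub.topology, sub.coords + 8.0)
        assert np.allclose(sasa(sub).per_residue,
                           sasa(shifted).per_residue, atol=1e-9)
        # rotation: exact up to the fixed sphere-point discretization
        R = Rotation.from_euler("xyz", [0.4, 1.0, -0.2]).as_matrix()
        rotated = Ensemble(sub.topology, sub.coords @ R.T)
        assert np.allclose(sasa(sub).per_residue,
                           sasa(rotated).per_residue, rtol=0.05, atol=0.01)


class TestSasaGroupSummary:
    def test_identical_frames_zero_deviations(self, free_ensemble):
        sub = Ensemble(free_ensemble.topology,
                       np.repeat(free_ensemble.coords[:1], 4, axis=0))
        sr = sasa(sub)
        part = assign_groups(np.array([10.2, 10.3, 14.8, 15.1]))
        summ = sasa_group_summary(sr, part)
        assert np.allclose(summ["totals"]["normalized"], 0.0, atol=1e-9)

    def test_grand_mean_is_unweighted_over_groups(self):
        # two groups with totals 40 and 50 -> grand mean 45, deviations -5/+5
        sr_total = np.array([40.0, 40.0, 40.0, 50.0])
        sr = type("S", (), {})()
        sr.total = sr_total
        sr.per_residue = np.tile(sr_total[:, None] / 2, (1, 2))
        part = assign_groups(np.array([10.0, 10.1, 9.9, 20.0]))
        summ = sasa_group_summary(sr, part)
        assert summ["grand_mean"] == pytest.approx(45.0)
        assert summ["totals"]["normalized"].tolist() == [-5.0, 5.0]

    def test_mean_total_increases_with_rg(self, compact_extended):
        means = {}
        for t, ens in compact_extended.items():
            means[t] = sasa(ens.subset(np.arange(0, 150, 10))).total.mean()
        assert means[20.0] > means[10.0]


class TestContactMap:
    def test_single_frame_is_distance_matrix(self, free_ensemble):
        sub = free_ensemble.subset([0])
        M = min_ca_distance_map(sub)
        ca = sub.topology.atom_indices("CA")
        d01 = np.linalg.norm(sub.coords[0, ca[0]] - sub.coords[0, ca[1]])
        assert M[0, 1] == pytest.approx(d01)
        assert np.allclose(M, M.T)

    def test_adding_frames_only_lowers_entries(self, free_ensemble):
        one = min_ca_distance_map(free_ensemble.subset([0]))
        two = min_ca_distance_map(free_ensemble.subset([0, 1]))
        assert np.all(two <= one + 1e-12)

    def test_sequential_neighbors_at_virtual_bond_length(self, free_ensemble):
        M = min_ca_distance_map(free_ensemble.subset(np.arange(5)))
        off = np.diagonal(M, offset=1)
        assert np.allclose(off, 3.8, atol=0.1)


class TestHbondMap:
    def test_ideal_helix_i_ip4_occupancy_one(self, helix16, ala16_top):
        ens = Ensemble(ala16_top, helix16[None])
        M = hbond_map(ens)
        occ = np.diagonal(M, offset=4)[2:-2]
        assert np.all(occ == 1.0)

    def test_distance_cut_excludes_long_bonds(self, helix16, ala16_top):
        ens = Ensemble(ala16_top, helix16[None])
        M = hbond_map(ens, d_cut=2.0)     # tighter than helical N...O ~3.0
        assert np.diagonal(M, offset=4).sum() == 0

    def test_occupancies_bounded(self, free_ensemble):
        M = hbond_map(free_ensemble.subset(np.arange(0, 60, 10)))
        assert np.all((M >= 0) & (M <= 1))
        assert np.allclose(np.diag(M), 0)


class TestSecondaryStructure:
    def test_ideal_helix_matches_full_dssp(self, helix16, ala16_top):
        md = pytest.importorskip("mdtraj")
        ours = assign_frame_ss(helix16, ala16_top)
        full = md.compute_dssp(as_mdtraj(helix16, ala16_top),
                               simplified=False)[0]
        collapse = {"H": 0, "G": 0, "I": 0, "E": 1, "B": 1, "T": 2, "S": 3}
        ref = np.array([collapse.get(c, 4) for c in full])
        assert np.array_equal(ours, ref)

    def test_hairpin_strands_match_full_dssp(self, hairpin12):
        md = pytest.importorskip("mdtraj")
        coords, top = hairpin12
        ours = assign_frame_ss(coords, top)
        full = md.compute_dssp(as_mdtraj(coords, top), simplified=False)[0]
        collapse = {"H": 0, "G": 0, "I": 0, "E": 1, "B": 1, "T": 2, "S": 3}
        ref = np.array([collapse.get(c, 4) for c in full])
        assert np.array_equal(ours, ref)
        assert (ours == 1).sum() >= 4          # paired strand residues

    def test_extended_chain_no_helix_no_strand(self):
        p = load_peptide("A" * 14)
        top = topology_for(p)
        c = build_chain(p, np.tile((180.0, 180.0), (14, 1)), top)
        cls = assign_frame_ss(c, top)
        assert not np.any(cls == 0) and not np.any(cls == 1)

    def test_probabilities_sum_to_one(self, free_ensemble):
        res = assign_secondary_structure(free_ensemble.subset(np.arange(10)))
        assert np.allclose(res["per_residue"].sum(axis=1), 1.0)

    def test_group_fractions_are_convex(self, free_ensemble):
        sub = free_ensemble.subset(np.arange(0, 100, 5))
        part = assign_groups(ensemble_rg(sub))
        res = assign_secondary_structure(sub, part)
        gf = res["group_fractions"]
        assert np.allclose(gf.sum(axis=1), 1.0)
        assert np.all((gf >= 0) & (gf <= 1))

    def test_helix_and_hbond_map_agree_on_helical_bonds(self, helix16,
                                                        ala16_top):
        ens = Ensemble(ala16_top, helix16[None])
        hmap = np.diagonal(hbond_map(ens), offset=4)
        ss = assign_frame_ss(helix16, ala16_top)
        assert hmap.max() == 1.0 and np.any(ss == 0)


class TestRamachandran:
    def test_full_torus_fraction_one(self, free_ensemble):
        r = ramachandran(free_ensemble.subset(np.arange(10)),
                         regions={"all": (-180, 180, -180, 180)})
        assert r["fractions"]["all"] == 1.0

    def test_pure_helix_dihedrals_fill_alpha_region(self):
        p = load_peptide("A" * 10)
        top = topology_for(p)
        c = build_chain(p, np.tile((-63.0, -43.0), (10, 1)), top)
        r = ramachandran(Ensemble(top, c[None]))
        assert r["fractions"]["alphaR"] == 1.0

    def test_histogram_counts_all_points(self, free_ensemble):
        r = ramachandran(free_ensemble)
        assert r["hist"].sum() == r["n_points"]

    def test_too_short_chain_rejected(self):
        p = load_peptide("GA")
        top = topology_for(p)
        with pytest.raises(ObservableError):
            ramachandran(Ensemble(top, np.zeros((1, top.n_atoms, 3))))

    def test_basin_weight_recovery(self, aicd):
        """Mixture weights are recovered from sampled dihedrals when the
        hard-core radius is negligible and the regions partition the
        basins (beta/PPII split at phi = -97.5)."""
        cfg = GeneratorConfig(seed=11, n_replicas=1, frames_per_replica=320,
                              clash_cutoff=0.1)
        ens = sample_ensemble(aicd, cfg)
        regions = {"alphaR": (-108, -18, -88, 2),
                   "beta": (-165, -97.5, 85, 175),
                   "PPII": (-97.5, -30, 105, 180),
                   "alphaL": (15, 105, 0, 90)}
        r = ramachandran(ens, regions=regions)
        assert r["n_points"] >= 10_000
        for name, w in zip(("alphaR", "beta", "PPII", "alphaL"),
                           cfg.basin_weights):
            assert r["fractions"][name] == pytest.approx(w, abs=0.03)


class TestKarplus:
    @pytest.mark.parametrize("phi,expect", [(90.0, 1.9), (180.0, 9.7),
                                            (0.0, 6.9), (-90.0, 1.9)])
    def test_j3_printed_coefficients(self, phi, expect):
        assert karplus_j3(phi) == pytest.approx(expect)

    @pytest.mark.parametrize("psi,expect", [(90.0, 0.5), (180.0, 3.0)])
    def test_j2_printed_coefficients(self, psi, expect):
        assert karplus_j2(psi) == pytest.approx(expect)

    def test_j3_bounded_by_quadratic_extremes(self):
        grid = np.linspace(-180, 180, 100_000)
        vals = karplus_j3(grid)
        assert vals.max() == pytest.approx(9.7, abs=1e-4)
        assert vals.min() >= 1.9 - 1.4 ** 2 / (4 * 6.4) - 1e-9

    def test_offset_shifts_argument(self):
        kp = KarplusParams(phi_offset=-60.0)
        assert karplus_j3(120.0, kp) == pytest.approx(karplus_j3(60.0))

    def test_per_group_table(self, free_ensemble):
        part = assign_groups(ensemble_rg(free_ensemble))
        df = j_couplings(free_ensemble, part=part)
        n_res = free_ensemble.topology.n_residues
        assert len(df) == len(part.labels) * n_res
        # first residue lacks phi, last lacks psi
        first = df[df.residue == 1]
        last = df[df.residue == n_res]
        assert first["j3_mean"].isna().all()
        assert last["j2_mean"].isna().all()
        mid = df[(df.residue > 1) & (df.residue < n_res)]
        assert ((mid["j3_mean"] >= 1.5) & (mid["j3_mean"] <= 9.7)).all()


class TestDihedrals:
    def test_build_chain_round_trip_through_ensemble(self, aicd):
        top = topology_for(aicd)
        rng = np.random.default_rng(4)
        pp = rng.uniform(-180, 180, (35, 2))
        ens = Ensemble(top, build_chain(aicd, pp, top)[None])
        phi, psi = backbone_dihedrals(ens)
        assert np.allclose(phi[0, 1:], pp[1:, 0], atol=1e-8)
        assert np.allclose(psi[0, :-1], pp[:-1, 1], atol=1e-8)
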