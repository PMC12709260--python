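import numpy as np
import pytest

from idplens import constants as C
from idplens.ensemble import Ensemble, topology_for
from idplens.rg_decompose import radius_of_gyration
from idplens.saxs import (FormFactorTable, SaxsError, ScatteringProfile,
                          average_profiles, chi_square, debye_profile,
                          default_q_grid, ensemble_average, guinier_rg,
                          kratky, pr_direct, pr_indirect, read_dat,
                          write_dat)
from idplens.seqprofile import load_peptide


class _UnitF:
    """Dummy table: f == 1 for every atom, no excluded volume."""

    def __init__(self, n):
        self.n = n

    def effective(self, q):
        return np.ones((self.n, len(q)))


@pytest.fixture(scope="module")
def aicd_fft(aicd):
    return FormFactorTable.for_topology(topology_for(aicd))


class TestFormFactors:
    def test_f0_matches_element_electron_count(self):
        for el, z in C.ELEMENT_ELECTRONS.items():
            top_f = FormFactorTable([[(el, 1)]], np.array([0.0]),
                                    solvent_density=0.0)
            assert top_f.effective(np.array([0.0]))[0, 0] == pytest.approx(
                z, abs=0.1)

    def test_lumped_f0_equals_total_residue_electrons(self, aicd, aicd_fft):
        # vacuum f(0) summed over all atoms = total electrons of the peptide
        top = topology_for(aicd)
        vac = FormFactorTable.for_topology(top, vacuum=True)
        f0 = vac.effective(np.array([0.0]))[:, 0].sum()
        expect = sum(C.residue_electrons(a) for a in aicd.sequence) + 2 + 8
        assert f0 == pytest.approx(expect, abs=0.1 * top.n_residues)

    def test_unknown_element_rejected(self):
        from idplens.ensemble import Topology
        top = Topology(("X",), ("X",), np.array([0]), ("A",), np.ones(1))
        with pytest.raises(SaxsError):
            FormFactorTable.for_topology(top)


class TestDebye:
    def test_two_point_dumbbell_closed_form(self):
        d = 10.0
        q = np.linspace(1e-4, 1.0, 300)
        sp = debye_profile(np.array([[0, 0, 0], [d, 0, 0]], float),
                           _UnitF(2), q)
        expect = (1.0 + np.sinc(q * d / np.pi)) / 2.0
        assert np.allclose(sp.I / sp.I[0] * expect[0], expect, rtol=1e-8)

    def test_single_atom_is_f_squared(self, aicd_fft):
        q = default_q_grid()
        one = FormFactorTable([[("C", 1)]], np.array([C.EXCLUDED_VOLUME["C"]]))
        sp = debye_profile(np.zeros((1, 3)), one, q)
        assert np.allclose(sp.I, one.effective(q)[0] ** 2, rtol=1e-12)

    def test_matches_brute_force_double_loop(self, aicd):
        top = topology_for(load_peptide(aicd.sequence[:8]))  # <= 50 atoms
        fft = FormFactorTable.for_topology(top)
        rng = np.random.default_rng(7)
        X = rng.normal(0, 4, (top.n_atoms, 3))
        q = default_q_grid()
        f = fft.effective(q)
        brute = np.zeros_like(q)
        for i in range(top.n_atoms):
            for j in range(top.n_atoms):
                r = np.linalg.norm(X[i] - X[j])
                brute += f[i] * f[j] * np.sinc(q * r / np.pi)
        sp = debye_profile(X, fft, q)
        assert np.allclose(sp.I, brute, rtol=1e-10)

    def test_zero_angle_limit(self, aicd, aicd_fft):
        top = topology_for(aicd)
        rng = np.random.default_rng(1)
        X = rng.normal(0, 6, (top.n_atoms, 3))
        f0 = aicd_fft.effective(np.array([0.0]))[:, 0]
        sp = debye_profile(X, aicd_fft, np.array([1e-9]))
        assert sp.I[0] == pytest.approx(f0.sum() ** 2, rel=1e-6)


class TestEnsembleAverage:
    def test_identical_frames_equal_single(self, aicd, aicd_fft):
        top = topology_for(aicd)
        X = np.random.default_rng(0).normal(0, 5, (top.n_atoms, 3))
        ens = Ensemble(top, np.stack([X, X, X]))
        q = default_q_grid(n=20)
        avg = ensemble_average(ens, aicd_fft, q)
        single = debye_profile(X, aicd_fft, q)
        assert np.allclose(avg.I, single.I, rtol=1e-12)

    def test_two_frames_midpoint_and_permutation(self):
        q = np.linspace(0.01, 0.3, 10)
        a = ScatteringProfile(q, np.full(10, 2.0))
        b = ScatteringProfile(q, np.full(10, 4.0))
        assert np.allclose(average_profiles([a, b]).I, 3.0)
        assert np.allclose(average_profiles([b, a]).I,
                           average_profiles([a, b]).I)

    def test_mismatched_grids_rejected(self):
        a = ScatteringProfile([0.1, 0.2], [1, 1])
        b = ScatteringProfile([0.1, 0.3], [1, 1])
        with pytest.raises(SaxsError):
            average_profiles([a, b])

    def test_extended_group_decays_faster_at_low_q(self, compact_extended,
                                                   aicd_fft):
        q = np.linspace(0.01, 0.08, 12)
        curves = {}
        for t, ens in compact_extended.items():
            curves[t] = ensemble_average(ens, aicd_fft, q, stride=10)
        drop = {t: sp.I[-1] / sp.I[0] for t, sp in curves.items()}
        assert drop[20.0] < drop[10.0]


class TestGuinier:
    def test_exact_gaussian_curve_inverts(self):
        q = np.linspace(0.005, 0.3, 150)
        rg, diag = guinier_rg(ScatteringProfile(
            q, 7.0 * np.exp(-q ** 2 * 16.0 ** 2 / 3.0)))
        assert rg == pytest.approx(16.0, abs=0.01)
        assert diag["I0"] == pytest.approx(7.0, rel=1e-6)

    def test_flat_curve_rejected(self):
        q = np.linspace(0.01, 0.3, 50)
        with pytest.raises(SaxsError):
            guinier_rg(ScatteringProfile(q, np.ones(50)))

    def test_dumbbell_matches_point_mass_rg(self):
        # maximally anisotropic scatterer: the Guinier regime requires
        # qRg < 1 here rather than the globular 1.3 rule of thumb
        d, q = 10.0, np.linspace(0.002, 1.0, 400)
        I = (1.0 + np.sinc(q * d / np.pi)) / 2.0
        rg, _ = guinier_rg(ScatteringProfile(q, I), qmax_rg=1.0)
        true = radius_of_gyration(
            np.array([[0, 0, 0], [d, 0, 0]], float), np.ones(2))  # 5 A
        assert abs(rg - true) / true < 0.03


class TestKratky:
    def test_zero_at_origin(self):
        q = np.linspace(0.0, 0.3, 50)
        sp = ScatteringProfile(q, np.exp(-q ** 2))
        x, y = kratky(sp, rg=10.0, I0=1.0)
        assert y[0] == 0.0

    def test_gaussian_curve_peak_at_sqrt3(self):
        rg = 16.0
        q = np.linspace(1e-4, 0.4, 4000)
        sp = ScatteringProfile(q, np.exp(-q ** 2 * rg ** 2 / 3.0))
        x, y = kratky(sp, rg, I0=1.0)
        assert x[np.argmax(y)] == pytest.approx(np.sqrt(3.0), abs=0.01)
        assert y.max() == pytest.approx(3.0 / np.e, abs=0.005)

    def test_nonpositive_I0_rejected(self):
        sp = ScatteringProfile([0.1], [1.0])
        with pytest.raises(SaxsError):
            kratky(sp, 10.0, I0=0.0)


class TestPr:
    def test_direct_two_points_single_bin(self):
        pr = pr_direct(np.array([[0, 0, 0], [10.0, 0, 0]]), dmax=12.0,
                       n_bins=24)
        assert pr.mode == pytest.approx(10.0, abs=0.5)

    def test_direct_unit_area(self, free_ensemble):
        pr = pr_direct(free_ensemble.coords[:5])
        assert np.trapezoid(pr.P, pr.r) == pytest.approx(1.0, abs=1e-6)

    def test_indirect_dumbbell_peak(self):
        d = 10.0
        q = np.linspace(1e-3, 1.0, 200)
        sp = ScatteringProfile(q, (1.0 + np.sinc(q * d / np.pi)) / 2.0)
        pr = pr_indirect(sp, dmax=12.0, n_basis=16, alpha=1e-6)
        assert abs(pr.mode - d) < 0.5

    def test_indirect_strong_regularization_flattens(self):
        q = np.linspace(1e-3, 1.0, 100)
        sp = ScatteringProfile(q, (1.0 + np.sinc(q * 10.0 / np.pi)) / 2.0)
        weak = pr_indirect(sp, dmax=12.0, alpha=1e-6)
        strong = pr_indirect(sp, dmax=12.0, alpha=1e9)
        assert np.abs(strong.P).max() < 1e-3 * np.abs(weak.P).max()

    def test_indirect_mode_agrees_with_direct_histogram(self,
                                                        compact_extended):
        # constant f(0) contrast: the model under which P(r) and I(q)
        # are exact Fourier mates; compact ensemble -> peaked P(r)
        ens = compact_extended[10.0]
        sub = ens.coords[::3]
        const = FormFactorTable.for_topology(ens.topology,
                                             constant_contrast=True)
        fft = FormFactorTable.for_topology(ens.topology)
        prof = ensemble_average(Ensemble(ens.topology, sub), const,
                                default_q_grid())
        direct = pr_direct(sub, fft, dmax=40.0, n_bins=30)
        indirect = pr_indirect(prof, dmax=40.0, n_basis=30, alpha=1e-4)
        bin_width = direct.r[2] - direct.r[1]
        assert abs(direct.mode - indirect.mode) <= bin_width

    def test_forward_transform_reproduces_input(self):
        d, q = 10.0, np.linspace(1e-3, 1.0, 150)
        I = (1.0 + np.sinc(q * d / np.pi)) / 2.0
        pr = pr_indirect(ScatteringProfile(q, I), dmax=12.0, alpha=1e-6)
        assert np.allclose(pr.I_fit, I, atol=1e-3)


class TestChiSquare:
    def test_identical_curves_zero(self):
        sp = ScatteringProfile([0.1, 0.2, 0.3], [5.0, 3.0, 1.0])
        assert chi_square(sp, sp)[0] == 0.0

    @pytest.mark.parametrize("E,S,expect", [
        ([2.0], [1.0], 1.0),
        ([3.0, 1.0], [1.0, 2.0], 4.25),
    ])
    def test_hand_computed_fixtures(self, E, S, expect):
        q = np.linspace(0.1, 0.2, len(E))
        val, _ = chi_square(ScatteringProfile(q, E), ScatteringProfile(q, S))
        assert val == pytest.approx(expect)

    def test_scale_fit_recovers_scalar_multiple(self):
        q = np.linspace(0.01, 0.3, 40)
        I = np.exp(-q ** 2 * 50)
        val, c = chi_square(ScatteringProfile(q, I),
                            ScatteringProfile(q, 3.0 * I), scale="fit")
        assert val == pytest.approx(0.0, abs=1e-20)
        assert c == pytest.approx(1.0 / 3.0)

    def test_zero_simulated_intensity_rejected(self):
        q = [0.1, 0.2]
        with pytest.raises(SaxsError):
            chi_square(ScatteringProfile(q, [1, 1]),
                       ScatteringProfile(q, [1, 0]))

    def test_nonnegative_with_equality_iff_identical(self):
        rng = np.random.default_rng(0)
        q = np.linspace(0.01, 0.4, 30)
        a = ScatteringProfile(q, np.abs(rng.normal(5, 1, 30)) + 1)
        b = ScatteringProfile(q, a.I + 0.01)
        assert chi_square(a, b)[0] > 0


class TestIo:
    def test_dat_round_trip(self, tmp_path):
        sp = ScatteringProfile([0.1, 0.2], [3.0, 1.0], sigma=[0.1, 0.2])
        path = tmp_path / "c.dat"
        write_dat(sp, path)
        back = read_dat(path)
        assert np.allclose(back.q, sp.q)
        assert np.allclose(back.I, sp.I)
        assert np.allclose(back.sigma, sp.sigma)
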