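import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdgsensor import (
    FourSiteModelParams,
    ITCProtocol,
    NoiseSpec,
    fit_four_site,
    gen_itc_thermogram,
    macroscopic_to_microscopic,
    occupancy,
    simulate_thermogram,
    solve_free_ligand,
)
from cdgsensor.errors import InvalidParameterError, InvalidProtocolError

from conftest import ITC_FITTED


class TestFreeLigandSolver:
    def test_no_protein_is_identity(self, itc_params):
        """Without protein all ligand stays free; occupancy is 0 by convention."""
        st_ = solve_free_ligand(3e-6, 0.0, itc_params)
        assert st_.free_ligand == 3e-6
        assert st_.nbar == 0.0
        assert st_.populations[0] == pytest.approx(1.0)

    def test_saturating_limit(self, itc_params):
        st_ = solve_free_ligand(1e-2, 1e-6, itc_params)
        assert st_.nbar == pytest.approx(4.0, abs=2e-3)
        assert st_.populations[4] == pytest.approx(1.0, abs=2e-3)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        lk1=st.floats(6, 10), lk3=st.floats(3, 7),
        ltot=st.floats(1e-7, 2e-4), ptot=st.floats(1e-7, 5e-5),
    )
    def test_polynomial_root_oracle(self, lk1, lk3, ltot, ptot):
        """The mass-balance solution equals the admissible root of the
        degree-5 polynomial obtained by clearing denominators, found by an
        independent companion-matrix root-finder."""
        params = FourSiteModelParams(K1=10**lk1, K3=10**lk3, dH1=-10, dH3=-5)
        st_ = solve_free_ligand(ltot, ptot, params)
        b = params.betas
        # (x - L)(1 + sum b_i x^i) + P sum i b_i x^i = 0
        coeffs = np.zeros(6)  # ascending powers 0..5
        coeffs[0] -= ltot
        coeffs[1] += 1.0
        for i in range(1, 5):
            coeffs[i + 1] += b[i - 1]
            coeffs[i] -= ltot * b[i - 1]
            coeffs[i] += ptot * i * b[i - 1]
        roots = np.roots(coeffs[::-1])
        real = roots[np.abs(roots.imag) < 1e-9 * np.abs(roots.real + 1e-300)].real
        admissible = real[(real >= -1e-15) & (real <= ltot * (1 + 1e-9))]
        assert admissible.size >= 1
        oracle = admissible[np.argmin(np.abs(admissible - st_.free_ligand))]
        assert st_.free_ligand == pytest.approx(oracle, rel=1e-6, abs=1e-18)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(ltot=st.floats(1e-8, 2e-4), ptot=st.floats(0, 5e-5))
    def test_mass_conservation_and_bounds(self, ltot, ptot):
        params = FourSiteModelParams(**ITC_FITTED)
        st_ = solve_free_ligand(ltot, ptot, params)
        assert st_.free_ligand + ptot * st_.nbar == pytest.approx(ltot, rel=1e-8)
        assert 0.0 <= st_.nbar <= 4.0
        assert st_.populations.sum() == pytest.approx(1.0, rel=1e-10)

    def test_occupancy_monotone_in_free_ligand(self, itc_params):
        xs = np.logspace(-10, -3, 60)
        nbars = [occupancy(x, itc_params).nbar for x in xs]
        assert np.all(np.diff(nbars) > 0)

    def test_statistical_factor_constraints(self, itc_params):
        """K2/K1 = K4/K3 = 1/4 and the shared enthalpies hold identically."""
        assert itc_params.K2 / itc_params.K1 == 0.25
        assert itc_params.K4 / itc_params.K3 == 0.25
        H = itc_params.cumulative_enthalpies
        assert H[2] - H[1] == H[1] - H[0]  # dH2 == dH1
        assert H[4] - H[3] == H[3] - H[2]  # dH4 == dH3

    def test_pair_closed_form_when_second_class_negligible(self):
        """With K3 tiny, occupancy over the first phase reduces exactly to the
        two-equivalent-site closed form nbar = 2sx/(1+sx), s = 0.5 K1."""
        K1 = 4e8
        params = FourSiteModelParams(K1=K1, K3=1e-2, dH1=-16.0, dH3=-7.0)
        s = 0.5 * K1
        for x in np.logspace(-10, -6, 25):
            nbar = occupancy(x, params).nbar
            assert nbar == pytest.approx(2 * s * x / (1 + s * x), rel=1e-6)


class TestSimulateThermogram:
    def test_zero_enthalpy_zero_heat(self, itc_protocol):
        params = FourSiteModelParams(K1=1e8, K3=1e5, dH1=0.0, dH3=0.0)
        tg = simulate_thermogram(itc_protocol, params)
        assert np.allclose(tg.heats, 0.0)

    def test_two_phase_plateaus(self, itc_protocol, itc_params):
        """First-phase injections release ~dH1 per mole injected, the
        post-2:1 phase ~dH3, reproducing the two-step signature."""
        tg = simulate_thermogram(itc_protocol, itc_params)
        assert np.mean(tg.heats[1:4]) == pytest.approx(-16.2, abs=0.3)
        assert tg.heats[7] == pytest.approx(-7.5, abs=1.0)
        assert abs(tg.heats[-1]) < 0.5  # saturated endpoint

    def test_telescoping_total_heat(self, itc_protocol, itc_params):
        """Total evolved heat telescopes to the final cell heat content plus
        the displacement corrections (independent state-by-state recompute),
        and the final content approximates V0 * P * (2dH1 + 2dH3) at
        near-saturation."""
        tg = simulate_thermogram(itc_protocol, itc_params)
        vols = np.array(itc_protocol.injection_volumes) * 1e-6
        moles = vols * itc_protocol.syringe_ligand_conc
        total = float(np.sum(tg.heats * moles))  # kcal
        V0 = itc_protocol.cell_volume * 1e-6
        # independent recompute of the cell heat content after each injection
        H = itc_params.cumulative_enthalpies
        p_tot = itc_params.f * itc_protocol.cell_protein_conc
        l_tot = 0.0
        Qs = [0.0]
        for dV in vols:
            f = 1 - dV / V0
            p_tot *= f
            l_tot = l_tot * f + dV / V0 * itc_protocol.syringe_ligand_conc
            st_ = solve_free_ligand(l_tot, p_tot, itc_params)
            Qs.append(V0 * p_tot * float(np.dot(st_.populations, H)))
        corrections = sum(
            (dV / V0) * (Qs[i + 1] + Qs[i]) / 2 for i, dV in enumerate(vols)
        )
        assert total == pytest.approx(Qs[-1] + corrections, rel=1e-9)
        saturated = V0 * p_tot * (2 * itc_params.dH1 + 2 * itc_params.dH3)
        assert Qs[-1] == pytest.approx(saturated, rel=0.05)

    def test_single_phase_when_classes_equal(self, itc_protocol):
        """With K3 = K1 and dH3 = dH1 the two-phase structure collapses: all
        pre-saturation heats sit near dH1, with no intermediate plateau."""
        params = FourSiteModelParams(K1=4e8, K3=4e8, dH1=-12.0, dH3=-12.0)
        tg = simulate_thermogram(itc_protocol, params)
        pre = tg.heats[1:9]  # molar ratio < 4:1 region
        assert np.all(np.abs(pre - (-12.0)) < 0.8)

    def test_protocol_overflow_rejected(self):
        with pytest.raises(InvalidProtocolError):
            ITCProtocol(injection_volumes=(50.0,) * 5, syringe_ligand_conc=1e-3,
                        cell_protein_conc=25e-6, cell_volume=200.0)


class TestFitFourSite:
    def test_noiseless_exact_recovery(self, itc_protocol, itc_params):
        tg = simulate_thermogram(itc_protocol, itc_params)
        fit = fit_four_site(tg, itc_protocol, jackknife=False)
        assert fit.params["K1"] == pytest.approx(3.98e8, rel=1e-2)
        assert fit.params["K3"] == pytest.approx(6.05e5, rel=1e-3)
        assert fit.params["dH1"] == pytest.approx(-16.2, rel=1e-4)
        assert fit.params["dH3"] == pytest.approx(-7.5, rel=1e-4)
        assert fit.params["f"] == pytest.approx(0.96, rel=1e-4)
        assert fit.derived["kd_site_high"] == pytest.approx(5.0e-9, rel=2e-2)

    def test_blank_subtraction_removes_dilution_offset(self, itc_protocol, itc_params):
        sample, blank = gen_itc_thermogram(itc_protocol, itc_params,
                                           NoiseSpec("additive", 0.0, seed=0))
        clean = simulate_thermogram(itc_protocol, itc_params)
        assert np.allclose((sample - blank).heats, clean.heats)

    def test_jackknife_se_grows_with_noise(self, itc_protocol, itc_params):
        """Leave-one-injection-out SEs shrink to zero with the injection
        noise: monotone over three noise levels."""
        ses = []
        for sd in (0.01, 0.15, 0.6):
            sample, blank = gen_itc_thermogram(itc_protocol, itc_params,
                                               NoiseSpec("additive", sd, seed=11))
            fit = fit_four_site(sample, itc_protocol, blank=blank, jackknife=True)
            ses.append(fit.jackknife_se["dH1"])
        assert ses[0] < ses[1] < ses[2]
        assert ses[0] < 0.05


class TestMicroscopicConstants:
    def test_published_site_constants(self):
        """Statistical-factor arithmetic: the fitted macroscopic constants
        give 5.0 nM and 3.3 µM site dissociation constants."""
        assert round(macroscopic_to_microscopic(3.98e8) * 1e9, 1) == 5.0
        assert round(macroscopic_to_microscopic(6.05e5) * 1e6, 1) == 3.3

    def test_trivial_and_invalid(self):
        assert macroscopic_to_microscopic(2.0) == 1.0
        with pytest.raises(InvalidParameterError):
            macroscopic_to_microscopic(0.0)
        with pytest.raises(InvalidParameterError):
            macroscopic_to_microscopic(-5.0)
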