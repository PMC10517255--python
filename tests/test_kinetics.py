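"""Reaction-chain simulation, spectral SVD, and fitting: oracle cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from uoxcoopt import kinetics as kn


def bateman(rates, c0, t, species):
    """Closed-form irreversible cascade concentrations (first species = c0)."""
    lam = np.asarray(rates, dtype=float)
    i = species
    ls = lam[: i + 1]
    out = np.zeros_like(t, dtype=float)
    for j in range(i + 1):
        num = np.prod(ls[:i]) if i > 0 else 1.0
        den = np.prod([ls[m] - ls[j] for m in range(i + 1) if m != j]) or 1.0
        out += num * np.exp(-ls[j] * t) / den
    return c0 * out


class TestSimulateChain:
    def test_one_step_exponential(self):
        model = kn.KineticModel((1.0, 0.0, 0.0), reversible=False,
                                k_reverse=(0, 0, 0), c0=(25, 0, 0, 0))
        t = np.linspace(0, 5, 60)
        prof = kn.simulate_chain(model, t)
        assert np.allclose(prof[:, 0], 25 * np.exp(-t), atol=1e-10)
        assert np.allclose(prof[:, 1], 25 * (1 - np.exp(-t)), atol=1e-10)

    def test_two_species_equilibrium_symmetry(self):
        model = kn.KineticModel((1.0, 0.0, 0.0), (1.0, 0.0, 0.0),
                                c0=(25, 0, 0, 0))
        prof = kn.simulate_chain(model, np.array([0.0, 50.0]))
        assert prof[-1, 0] == pytest.approx(12.5, abs=1e-9)
        assert prof[-1, 1] == pytest.approx(12.5, abs=1e-9)

    def test_bateman_cascade_dual_oracle(self):
        """Distinct irreversible rates: matches both the Bateman closed form
        and a high-accuracy numerical integrator."""
        k = (3.0, 1.0, 0.3)
        model = kn.KineticModel(k, (0, 0, 0), c0=(25, 0, 0, 0),
                                reversible=False)
        t = np.linspace(0, 10, 80)
        prof = kn.simulate_chain(model, t)
        for i in range(3):
            assert np.allclose(prof[:, i], bateman(k, 25.0, t, i), atol=1e-8)
        A = model.rate_matrix()
        ivp = solve_ivp(lambda _, c: A @ c, (0, t[-1]), [25, 0, 0, 0],
                        t_eval=t, rtol=1e-11, atol=1e-12, method="LSODA")
        assert np.allclose(prof.T, ivp.y, atol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 50.0), min_size=6, max_size=6))
    def test_mass_conservation(self, rates):
        """Total concentration is conserved to 1e-9 relative for any rates."""
        model = kn.KineticModel(tuple(rates[:3]), tuple(rates[3:]),
                                c0=(25, 0, 0, 0))
        t = np.logspace(-3, 2, 40)
        prof = kn.simulate_chain(model, t)
        assert np.allclose(prof.sum(axis=1), 25.0, rtol=1e-9)

    def test_repeated_eigenvalue_fallback(self):
        """Equal rates create degenerate eigenvalues; the expm fallback must
        agree with an integrator."""
        model = kn.KineticModel((1.0, 1.0, 1.0), (0, 0, 0), c0=(10, 0, 0, 0),
                                reversible=False)
        t = np.linspace(0, 5, 30)
        prof = kn.simulate_chain(model, t)
        A = model.rate_matrix()
        ivp = solve_ivp(lambda _, c: A @ c, (0, t[-1]), [10, 0, 0, 0],
                        t_eval=t, rtol=1e-11, atol=1e-13, method="LSODA")
        assert np.allclose(prof.T, ivp.y, atol=1e-7)

    def test_detailed_balance_limit(self):
        """Fully reversible chain: species ratios at t -> inf equal k_i/k_-i."""
        kf, kr = (2.0, 1.5, 0.8), (0.5, 1.0, 2.0)
        model = kn.KineticModel(kf, kr, c0=(25, 0, 0, 0))
        eq = kn.simulate_chain(model, np.array([0.0, 500.0]))[-1]
        for i in range(3):
            assert eq[i + 1] / eq[i] == pytest.approx(kf[i] / kr[i], rel=1e-6)

    def test_hiu_plateau_below_initial_when_back_reaction_dominates(self):
        """k-3 > k3 caps HIU well below the initial urate; raising k3
        monotonically raises the plateau."""
        plateaus = []
        for k3 in (0.5, 1.0, 2.0):
            model = kn.KineticModel((2000.0, 1500.0, k3), (0.0, 0.0, 2.0),
                                    c0=(25, 0, 0, 0))
            plateaus.append(kn.simulate_chain(model, np.array([0, 500.0]))[-1, 3])
        assert plateaus[0] < 25.0
        assert plateaus[0] == pytest.approx(0.2 * 25.0, rel=1e-3)
        assert plateaus[0] < plateaus[1] < plateaus[2]

    def test_negative_time_rejected(self):
        model = kn.KineticModel((1, 1, 1))
        with pytest.raises(ValueError):
            kn.simulate_chain(model, np.array([-1.0, 0.0]))

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            kn.KineticModel((-1, 0, 0))
        with pytest.raises(ValueError):
            kn.KineticModel((1, 1, 1), (0.5, 0, 0), reversible=False)
        with pytest.raises(ValueError):
            kn.KineticModel((1, 1, 1), c0=(-1, 0, 0, 0))

    def test_h2o2_tracks_forward_flux_only(self):
        """Irreversible chain: cumulative H2O2 equals HIU formed; with a
        dominant back reaction H2O2 keeps accumulating past the HIU plateau."""
        irr = kn.KineticModel((3.0, 1.0, 0.3), (0, 0, 0), c0=(25, 0, 0, 0),
                              reversible=False)
        t = np.array([0.0, 5.0, 50.0])
        h = kn.h2o2_production(irr, t)
        prof = kn.simulate_chain(irr, t)
        assert np.allclose(h, prof[:, 3], atol=1e-8)
        rev = kn.KineticModel((2000.0, 1500.0, 0.5), (0, 0, 2.0),
                              c0=(25, 0, 0, 0))
        t2 = np.array([10.0, 100.0])
        h2 = kn.h2o2_production(rev, t2)
        hiu = kn.simulate_chain(rev, t2)[:, 3]
        assert h2[1] > h2[0] * 1.5  # still rising
        assert abs(hiu[1] - hiu[0]) < 0.1  # HIU already at plateau


class TestSpectra:
    def test_beer_lambert_single_species(self, species_spectra):
        """1 uM of urate at its 292 nm peak gives A = 0.01265 for all times."""
        t = np.linspace(0, 1, 5)
        profiles = np.zeros((5, 4))
        profiles[:, 0] = 1.0
        mat = kn.synthesize_spectra(profiles, t, species_spectra)
        assert np.allclose(mat.trace(292.0), 0.01265, atol=1e-12)

    def test_zero_concentrations_zero_matrix(self, species_spectra):
        t = np.linspace(0, 1, 4)
        mat = kn.synthesize_spectra(np.zeros((4, 4)), t, species_spectra)
        assert not mat.absorbance.any()

    def test_noiseless_matrix_rank_bounded_by_species(self, species_spectra):
        model = kn.KineticModel((3.0, 1.0, 0.3), (0.2, 0.1, 0.05),
                                c0=(25, 0, 0, 0))
        t = np.logspace(-2, 2, 50)
        prof = kn.simulate_chain(model, t)
        mat = kn.synthesize_spectra(prof, t, species_spectra)
        assert np.linalg.matrix_rank(mat.absorbance, tol=1e-10) <= 4

    def test_grid_mismatch_rejected(self, species_spectra):
        with pytest.raises(ValueError):
            kn.synthesize_spectra(np.zeros((3, 5)), np.arange(3.0),
                                  species_spectra)


class TestSVD:
    def test_rank_one_matrix_single_component(self, species_spectra):
        t = np.logspace(-2, 1, 30)
        profiles = np.zeros((30, 4))
        profiles[:, 0] = 25 * np.exp(-t)
        mat = kn.synthesize_spectra(profiles, t, species_spectra)
        svd = kn.svd_components(mat)
        assert svd.explained_variance[0] >= 1 - 1e-12

    def test_reconstruction_and_monotone_truncation_error(self, species_spectra):
        model = kn.KineticModel((5.0, 2.0, 0.5), (0.5, 0.2, 1.0),
                                c0=(25, 0, 0, 0))
        t = np.logspace(-3, 2, 40)
        prof = kn.simulate_chain(model, t)
        mat = kn.synthesize_spectra(prof, t, species_spectra, noise_sigma=0.002,
                                    rng=np.random.default_rng(0))
        svd = kn.svd_components(mat)
        A = mat.absorbance
        full = (svd.temporal * svd.singular_values) @ svd.spectral
        assert np.linalg.norm(full - A) <= 1e-10 * np.linalg.norm(A)
        errs = []
        for k in range(1, len(svd.singular_values) + 1):
            approx = (svd.temporal[:, :k] * svd.singular_values[:k]) @ svd.spectral[:k]
            errs.append(np.linalg.norm(approx - A))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_time_permutation_leaves_singular_values_unchanged(self,
                                                               species_spectra):
        t = np.logspace(-2, 1, 25)
        prof = kn.simulate_chain(kn.KineticModel((3, 1, 0.3), (0, 0, 0),
                                                 c0=(25, 0, 0, 0),
                                                 reversible=False), t)
        mat = kn.synthesize_spectra(prof, t, species_spectra)
        svd = kn.svd_components(mat)
        perm = np.random.default_rng(1).permutation(25)
        mat2 = kn.SpectraMatrix(times=t, wavelengths=mat.wavelengths,
                                absorbance=mat.absorbance[perm])
        svd2 = kn.svd_components(mat2)
        assert np.allclose(svd.singular_values, svd2.singular_values)

    def test_nan_matrix_rejected(self, species_spectra):
        t = np.array([0.0, 1.0])
        A = np.zeros((2, species_spectra.wavelengths.size))
        A[0, 0] = np.nan
        mat = kn.SpectraMatrix(times=t, wavelengths=species_spectra.wavelengths,
                               absorbance=A)
        with pytest.raises(ValueError, match="NaN"):
            kn.svd_components(mat)

    def test_difference_component_has_published_landmarks(self, species_spectra):
        """A slow PIU <-> HIU conversion after a fast initial phase yields a
        first difference-spectrum component with a negative peak at 294 nm and
        a positive peak at 314 nm (sign fixed by the largest-|loading| rule)."""
        model = kn.KineticModel((2000.0, 1500.0, 0.5), (0.0, 0.0, 2.0),
                                c0=(25, 0, 0, 0))
        t = kn.log_times(5e-3, 60.0, 100)
        prof = kn.simulate_chain(model, t)
        mat = kn.synthesize_spectra(prof, t, species_spectra)
        svd = kn.svd_components(mat, center=True)
        v1 = svd.spectral[0]
        wl = svd.wavelengths
        assert wl[np.argmin(v1)] == pytest.approx(294.0, abs=0.5)
        assert wl[np.argmax(v1)] == pytest.approx(314.0, abs=0.5)
        # with realistic noise the landmarks stay within a few nm
        noisy = kn.synthesize_spectra(prof, t, species_spectra,
                                      noise_sigma=0.002,
                                      rng=np.random.default_rng(1))
        nsvd = kn.svd_components(noisy, center=True)
        assert abs(wl[np.argmin(nsvd.spectral[0])] - 294.0) <= 3.0
        assert abs(wl[np.argmax(nsvd.spectral[0])] - 314.0) <= 3.0


class TestIsolatedWavelength:
    @staticmethod
    def svd_from_loadings(wavelengths, loadings):
        """Build an SVDResult carrying prescribed singular-value-scaled
        spectral loadings (unit singular values)."""
        loadings = np.asarray(loadings, dtype=float)
        return kn.SVDResult(
            singular_values=np.ones(loadings.shape[0]),
            temporal=np.eye(loadings.shape[0]),
            spectral=loadings,
            explained_variance=np.full(loadings.shape[0],
                                       1.0 / loadings.shape[0]),
            wavelengths=np.asarray(wavelengths, dtype=float),
        )

    def test_zero_crossing_of_other_component_is_selected(self):
        """Component 2 crosses zero at exactly 320 nm while component 1 is
        nonzero there: 320 nm is the isolated wavelength for component 1."""
        wl = np.array([300.0, 310.0, 320.0, 330.0, 340.0])
        c1 = np.array([0.5, 0.6, 0.7, 0.6, 0.5])
        c2 = np.array([0.4, 0.2, 0.0, -0.2, -0.4])
        svd = self.svd_from_loadings(wl, [c1, c2])
        assert kn.select_isolated_wavelength(svd, component=1, n_retained=2) == 320.0

    def test_single_component_boundary_contract(self):
        wl = np.array([300.0, 310.0, 320.0])
        svd = self.svd_from_loadings(wl, [[0.1, 0.9, 0.3]])
        assert kn.select_isolated_wavelength(svd, component=1, n_retained=1) == 310.0

    def test_dominance_ratio_hand_computation(self):
        """5-point grid with known dominance ratios: the maximizer of
        |target| / sum|others| is returned."""
        wl = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c1 = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        c2 = np.array([1.0, 0.5, 2.0, 0.1, 1.0])
        c3 = np.array([0.5, 0.5, 1.0, 0.3, 0.5])
        # ratios: 1/1.5, 2/1.0, 3/3.0, 2/0.4=5.0 <- max, 1/1.5
        svd = self.svd_from_loadings(wl, [c1, c2, c3])
        assert kn.select_isolated_wavelength(svd, component=1, n_retained=3) == 4.0

    def test_degenerate_all_zero_loadings_rejected(self):
        wl = np.array([1.0, 2.0])
        svd = self.svd_from_loadings(wl, [[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            kn.select_isolated_wavelength(svd, component=1, n_retained=2)


class TestChainFit:
    def test_noiseless_irreversible_recovery(self, species_spectra):
        """Rates (50, 20, 4.11) recovered from a noiseless isolated-wavelength
        trace to better than 1e-2 absolute on the final step."""
        model = kn.KineticModel((50.0, 20.0, 4.11), (0, 0, 0),
                                c0=(25, 0, 0, 0), reversible=False)
        t = kn.log_times(1e-3, 10.0, 150)
        prof = kn.simulate_chain(model, t)
        mat = kn.synthesize_spectra(prof, t, species_spectra)
        svd = kn.svd_components(mat, center=True)
        lam = kn.select_isolated_wavelength(svd, component=1)
        j = int(np.argmin(np.abs(mat.wavelengths - lam)))
        eps = np.array([species_spectra.eps[s][j] for s in kn.SPECIES])
        fit = kn.fit_chain_model(t, mat.absorbance[:, j], eps,
                                 c0=(25, 0, 0, 0))
        assert fit.rates["k3"] == pytest.approx(4.11, abs=0.01)
        assert fit.identifiable

    def test_constant_trace_fits_zero_rates(self, species_spectra):
        t = kn.log_times(1e-3, 10.0, 60)
        j = 42
        eps = np.array([species_spectra.eps[s][j] for s in kn.SPECIES])
        trace = np.full(t.size, 25e-6 * eps[0])
        fit = kn.fit_chain_model(t, trace, eps, c0=(25, 0, 0, 0))
        assert fit.rates["k1"] == pytest.approx(0.0, abs=1e-3)
        assert np.allclose(fit.fitted, trace, rtol=1e-3)

    def test_noisy_recovery_median_error(self, species_spectra):
        """1% noise, 20 seeds: median relative error of the final-step rate
        stays below 5%."""
        model = kn.KineticModel((50.0, 20.0, 4.11), (0, 0, 0),
                                c0=(25, 0, 0, 0), reversible=False)
        t = kn.log_times(1e-3, 10.0, 120)
        prof = kn.simulate_chain(model, t)
        mat = kn.synthesize_spectra(prof, t, species_spectra)
        svd = kn.svd_components(mat, center=True)
        lam = kn.select_isolated_wavelength(svd, component=1)
        j = int(np.argmin(np.abs(mat.wavelengths - lam)))
        eps = np.array([species_spectra.eps[s][j] for s in kn.SPECIES])
        clean = mat.absorbance[:, j]
        sigma = 0.01 * (clean.max() - clean.min())
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, sigma, clean.size)
            fit = kn.fit_chain_model(t, noisy, eps, c0=(25, 0, 0, 0),
                                     n_starts=4)
            errors.append(abs(fit.rates["k3"] - 4.11) / 4.11)
        assert np.median(errors) < 0.05

    def test_reversible_fit_of_irreversible_trace_nests(self, species_spectra):
        """Fitting the reversible model to an irreversible-simulated trace
        recovers the same forward rates (reverse rates near zero)."""
        model = kn.KineticModel((20.0, 8.0, 2.0), (0, 0, 0), c0=(25, 0, 0, 0),
                                reversible=False)
        t = kn.log_times(1e-3, 20.0, 120)
        prof = kn.simulate_chain(model, t)
        mat = kn.synthesize_spectra(prof, t, species_spectra)
        j = int(np.argmin(np.abs(mat.wavelengths - 314)))
        eps = np.array([species_spectra.eps[s][j] for s in kn.SPECIES])
        fit = kn.fit_chain_model(
            t, mat.absorbance[:, j], eps, c0=(25, 0, 0, 0),
            free=("k1", "k2", "k3", "k-1", "k-2", "k-3"), n_starts=4)
        assert fit.rates["k3"] == pytest.approx(2.0, rel=0.02)

    def test_nonincreasing_times_rejected(self, species_spectra):
        eps = np.ones(4)
        with pytest.raises(ValueError):
            kn.fit_chain_model(np.array([0.0, 0.0, 1.0]), np.zeros(3), eps)


class TestMichaelisMenten:
    def test_noiseless_exact_recovery(self):
        s = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 140.0])
        vmax, km = 0.03 * 0.5, 12.5
        v = vmax * s / (km + s)
        fit = kn.fit_michaelis_menten(s, v, enzyme_conc=0.5)
        assert fit.km == pytest.approx(12.5, abs=1e-8)
        assert fit.kcat == pytest.approx(0.03, abs=1e-8)

    def test_half_saturation_identity(self):
        s = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 140.0])
        v = 0.6 * s / (9.0 + s)
        fit = kn.fit_michaelis_menten(s, v, enzyme_conc=1.0)
        assert fit.rate(fit.km) == pytest.approx(fit.vmax / 2, rel=1e-12)

    def test_grid_search_oracle(self):
        """The fit matches a dense (K_M, V_max) grid search's optimum within
        grid resolution on 20 random noiseless datasets."""
        rng = np.random.default_rng(2)
        s = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 140.0])
        for _ in range(20):
            km = float(rng.uniform(4, 60))
            vmax = float(rng.uniform(0.01, 2.0))
            v = vmax * s / (km + s)
            fit = kn.fit_michaelis_menten(s, v, enzyme_conc=1.0)
            kms = np.linspace(max(km - 5, 0.5), km + 5, 201)
            vms = np.linspace(vmax * 0.8, vmax * 1.2, 201)
            rss = ((v[None, None, :] - vms[None, :, None] * s /
                    (kms[:, None, None] + s)) ** 2).sum(axis=2)
            i, jj = np.unravel_index(np.argmin(rss), rss.shape)
            assert abs(fit.km - kms[i]) <= (kms[1] - kms[0])
            assert abs(fit.vmax - vms[jj]) <= (vms[1] - vms[0])

    def test_simulation_study_bias_and_coverage(self):
        """2% multiplicative noise, triplicates, 50 seeds: K_M bias < 3% and
        95% CI coverage in [0.9, 1.0]."""
        from uoxcoopt.synthetic import gen_mm_dataset

        km_true, kcat_true = 12.5, 0.03
        estimates, covered = [], 0
        for seed in range(50):
            data, _ = gen_mm_dataset(km=km_true, kcat=kcat_true,
                                     enzyme_conc=0.5, noise_cv=0.02,
                                     replicates=3, seed=seed)
            fit = kn.fit_michaelis_menten(data.substrate_uM,
                                          data.rate_uM_per_s, enzyme_conc=0.5)
            estimates.append(fit.km)
            if abs(fit.km - km_true) <= 1.96 * fit.km_se:
                covered += 1
        bias = abs(np.mean(estimates) - km_true) / km_true
        assert bias < 0.03
        assert 0.9 <= covered / 50 <= 1.0

    def test_all_equal_substrate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kn.fit_michaelis_menten(np.full(5, 10.0), np.ones(5), 1.0)


class TestFox:
    def test_exact_line_recovery(self):
        c = np.array([10.0, 25.0, 50.0, 100.0])
        a = 0.005 * c + 0.04
        curve = kn.fox_standard_curve(c, a)
        assert curve.slope == pytest.approx(0.005, abs=1e-12)
        assert curve.intercept == pytest.approx(0.04, abs=1e-12)
        assert curve.rvalue == pytest.approx(1.0)

    def test_absorbance_at_intercept_maps_to_zero(self):
        curve = kn.fox_standard_curve(np.array([10.0, 100.0]),
                                      np.array([0.09, 0.54]))
        conc, clipped = kn.quantify_h2o2(curve, np.array([curve.intercept]))
        assert conc[0] == pytest.approx(0.0, abs=1e-10)
        assert not clipped[0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.5, 120.0))
    def test_round_trip_inverse_identity(self, c_true):
        curve = kn.fox_standard_curve(np.array([10.0, 25.0, 50.0, 100.0]),
                                      0.005 * np.array([10.0, 25.0, 50.0, 100.0]) + 0.04)
        a = curve.slope * c_true + curve.intercept
        conc, _ = kn.quantify_h2o2(curve, np.array([a]))
        assert conc[0] == pytest.approx(c_true, abs=1e-10)

    def test_negative_prediction_clipped_and_flagged(self):
        curve = kn.fox_standard_curve(np.array([10.0, 100.0]),
                                      np.array([0.09, 0.54]))
        conc, clipped = kn.quantify_h2o2(curve, np.array([0.0]))
        assert conc[0] == 0.0
        assert clipped[0]

    def test_flat_standards_rejected(self):
        curve = kn.FoxCurve(np.array([1.0, 2.0]), np.array([0.1, 0.1]),
                            slope=0.0, intercept=0.1, rvalue=0.0)
        with pytest.raises(ValueError, match="slope"):
            kn.quantify_h2o2(curve, np.array([0.2]))
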