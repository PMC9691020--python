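"""Kinetic schemes: simulation correctness, k_obs extraction, global fitting."""

import numpy as np
import pytest

from srxfret import KineticScheme, SimConfig, compare_schemes, extract_kobs, global_fit_scheme, simulate_scheme
from srxfret.kinetics import SimulationError
from srxfret.synthetic import default_scheme1, gen_binding_transient

from _oracles import expm_trajectory


def _scheme1(**kw):
    base = dict(
        scheme_id="scheme1", k_T=1.9, kp_T=1.9 / 15, k_IHM=5.0, kp_IHM=5.0,
        open_fraction=0.65,
    )
    base.update(kw)
    return KineticScheme(**base)


class TestSchemeValidation:
    def test_alt_must_bind_slower(self):
        with pytest.raises(ValueError):
            KineticScheme(scheme_id="scheme1", k_T=1.0, kp_T=2.0, k_IHM=5.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(scheme_id="scheme2", k_T=-1.0)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            KineticScheme(scheme_id="scheme3", k_T=1.0)

    def test_occupancy_sums_to_one(self):
        s = _scheme1(open_fraction=0.3)
        assert s.initial_occupancy().sum() == pytest.approx(1.0)

    def test_dict_roundtrip(self):
        s = _scheme1()
        assert KineticScheme.from_dict(s.to_dict()) == s


class TestSimulateScheme:
    def test_matches_matrix_exponential(self):
        """Stiff-solver trajectories agree with the exact linear-system solution."""
        grid = np.linspace(0.01, 20.0, 100)
        for scheme in (
            _scheme1(),
            KineticScheme(
                scheme_id="scheme2", k_T=1.9, k_IHM=5.0, k_iso_plus=0.1,
                k_iso_minus=0.05, open_fraction=0.5,
            ),
        ):
            traj = simulate_scheme(scheme, 1.0, grid)
            exact = expm_trajectory(scheme, 1.0, grid)
            np.testing.assert_allclose(traj.occupancy, exact, atol=1e-8)

    def test_occupancy_conserved_at_all_times(self):
        traj = simulate_scheme(_scheme1(), 2.5, np.linspace(0.01, 60, 300))
        np.testing.assert_allclose(traj.occupancy.sum(axis=1), 1.0, atol=1e-8)

    def test_no_ihm_without_transition(self):
        s = KineticScheme(scheme_id="scheme1", k_T=1.0, kp_T=0.1, k_IHM=0.0,
                          kp_IHM=0.0, open_fraction=1.0)
        traj = simulate_scheme(s, 1.0, np.linspace(0.01, 50, 200))
        assert np.all(traj.occupancy_of("IHM") == 0)

    def test_two_step_series_closed_form(self):
        """All-Open start follows the exact A->B->C series solution."""
        k1, k2 = 1.0, 100.0
        s = KineticScheme(scheme_id="scheme1", k_T=k1, kp_T=0.5, k_IHM=k2,
                          kp_IHM=k2, open_fraction=1.0)
        grid = np.linspace(0.1, 10.0, 100)
        traj = simulate_scheme(s, 1.0, grid)
        exact = 1 - (k2 * np.exp(-k1 * grid) - k1 * np.exp(-k2 * grid)) / (k2 - k1)
        np.testing.assert_allclose(traj.f_fret, exact, atol=1e-7)

    def test_fast_ihm_reduces_to_binding_exponential(self):
        """When IHM entry far outpaces binding, f_FRET ~ 1 - exp(-k_T*[ATP]*t)."""
        s = KineticScheme(scheme_id="scheme1", k_T=1.0, kp_T=0.5, k_IHM=1000.0,
                          kp_IHM=1000.0, open_fraction=1.0)
        grid = np.linspace(0.1, 10.0, 100)
        traj = simulate_scheme(s, 1.0, grid)
        np.testing.assert_allclose(traj.f_fret, 1 - np.exp(-grid), atol=1e-3)

    def test_fast_ihm_limit_amplitudes_equal_initial_fractions(self):
        """At k_IHM -> inf the observable is bi-exponential with the apo split."""
        from srxfret.transients import fit_exponentials

        s = _scheme1(k_IHM=1e4, kp_IHM=1e4, open_fraction=0.65)
        cfg = SimConfig(seed=0, noise_sd=0.0, duration=80.0, n_points=2000)
        tr = gen_binding_transient(s, 1.0, cfg)
        fit = fit_exponentials(
            tr, n_components=2, rate_grid=np.logspace(-2, 1, 5)
        )
        np.testing.assert_allclose(fit.fractional_amplitudes, [0.65, 0.35], atol=0.02)
        assert fit.rates[0] == pytest.approx(1.9, rel=0.02)
        assert fit.rates[1] == pytest.approx(1.9 / 15, rel=0.02)

    def test_exact_bimolecular_mode_depletes_atp(self):
        """With heads in excess of ATP the exact mode binds slower than pseudo-first-order."""
        s = _scheme1()
        grid = np.linspace(0.01, 30, 200)
        pfo = simulate_scheme(s, 0.5, grid)
        exact = simulate_scheme(s, 0.5, grid, myosin_uM=0.5, pseudo_first_order=False)
        assert exact.f_fret[-1] < pfo.f_fret[-1]

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_scheme(_scheme1(), 1.0, np.array([1.0, 0.5, 2.0]))


class TestExtractKobs:
    @pytest.fixture()
    def scheme1_transients(self):
        s = _scheme1(k_IHM=1e4, kp_IHM=1e4)
        out = []
        for atp in (0.25, 0.5, 1.0, 1.5, 2.5):
            cfg = SimConfig(
                seed=0, noise_sd=0.0, n_points=1500,
                duration=60.0 / atp if atp < 1 else 60.0,
            )
            out.append(gen_binding_transient(s, atp, cfg))
        return out

    def test_second_order_constant_recovered(self, scheme1_transients):
        """Fast-phase slope recovers the planted Open binding constant."""
        bk = extract_kobs(scheme1_transients)
        assert bk.k_fast_slope == pytest.approx(1.9, rel=0.02)
        assert bk.k_slow_slope == pytest.approx(1.9 / 15, rel=0.05)

    def test_a_fast_matches_initial_open_fraction(self, scheme1_transients):
        bk = extract_kobs(scheme1_transients)
        assert bk.a_fast_mean == pytest.approx(0.65, abs=0.02)

    def test_kobs_linear_in_concentration(self):
        """Doubling [ATP] doubles the observed fast rate (noiseless)."""
        s = _scheme1(k_IHM=1e4, kp_IHM=1e4)
        rates = {}
        for atp in (1.0, 2.0):
            cfg = SimConfig(seed=0, noise_sd=0.0, n_points=1500, duration=60.0)
            tr = gen_binding_transient(s, atp, cfg)
            from srxfret.transients import fit_exponentials

            fit = fit_exponentials(tr, 2, rate_grid=np.logspace(-2, 1, 5))
            rates[atp] = fit.rates[0]
        assert rates[2.0] / rates[1.0] == pytest.approx(2.0, rel=0.02)

    def test_single_concentration_rejected(self, scheme1_transients):
        with pytest.raises(ValueError):
            extract_kobs([scheme1_transients[0]] * 4, atp_uM=[1.0] * 4)

    def test_fast_only_scheme_gives_afast_one(self):
        s = KineticScheme(scheme_id="scheme1", k_T=1.9, kp_T=0.1, k_IHM=1e4,
                          kp_IHM=1e4, open_fraction=1.0)
        trs = [
            gen_binding_transient(
                s, atp, SimConfig(seed=0, noise_sd=0.0, n_points=800, duration=30.0)
            )
            for atp in (0.5, 1.0, 2.0)
        ]
        bk = extract_kobs(trs)
        assert bk.a_fast_mean == pytest.approx(1.0)


class TestGlobalFit:
    def _data(self, scheme, noise=0.0, n_points=400):
        out, concs = [], (0.25, 0.5, 1.0, 1.5, 2.5)
        for i, atp in enumerate(concs):
            cfg = SimConfig(seed=100 + i, noise_sd=noise, n_points=n_points,
                            duration=60.0)
            out.append(gen_binding_transient(scheme, atp, cfg))
        return out

    def test_scheme1_self_consistency_recovery(self):
        """Noiseless Scheme-1 data refit recovers planted constants within 5%."""
        truth = _scheme1()  # k_IHM=5: identifiable on this grid
        data = self._data(truth, n_points=2000)
        start = KineticScheme(
            scheme_id="scheme1", k_T=1.0, kp_T=0.3, k_IHM=10.0, kp_IHM=2.0,
            open_fraction=0.5,
        )
        fit = global_fit_scheme(start, data)
        assert fit.scheme.k_T == pytest.approx(truth.k_T, rel=0.05)
        assert fit.scheme.kp_T == pytest.approx(truth.kp_T, rel=0.05)
        assert fit.scheme.k_IHM == pytest.approx(truth.k_IHM, rel=0.05)
        assert fit.scheme.kp_IHM == pytest.approx(truth.kp_IHM, rel=0.05)
        assert fit.scheme.open_fraction == pytest.approx(0.65, abs=0.01)

    def test_scheme_discrimination_by_aicc(self):
        """Data generated from the isomerisation mechanism prefers Scheme 2."""
        truth2 = KineticScheme(
            scheme_id="scheme2", k_T=1.9, k_IHM=5.0, k_iso_plus=0.08,
            k_iso_minus=0.08, open_fraction=0.5,
        )
        data = self._data(truth2, noise=0.005)
        s1_0 = _scheme1(open_fraction=0.5)
        s2_0 = KineticScheme(
            scheme_id="scheme2", k_T=1.0, k_IHM=10.0, k_iso_plus=0.05,
            k_iso_minus=0.05, open_fraction=0.5,
        )
        cmp = compare_schemes(s1_0, s2_0, data)
        assert cmp["preferred"] == "scheme2"

    def test_scale_factors_recovered_exactly_in_control(self):
        """Zero-noise single-pathway control: per-transient scales are exact."""
        s = KineticScheme(scheme_id="scheme1", k_T=1.0, kp_T=0.5, k_IHM=1e3,
                          kp_IHM=1e3, open_fraction=1.0)
        data = [
            gen_binding_transient(
                s, atp, SimConfig(seed=0, noise_sd=0.0, n_points=300, duration=20.0),
                s0=2.0, delta_s=0.4,
            )
            for atp in (0.5, 1.0, 2.0)
        ]
        fit = global_fit_scheme(s, data, fit_open_fraction=False)
        for s0, ds in fit.scales:
            assert s0 == pytest.approx(2.0, abs=1e-6)
            assert ds == pytest.approx(0.4, abs=1e-5)
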