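"""Exponential fitting, SRX decomposition and salt-profile statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srxfret import (
    SimConfig,
    SRXMeasurement,
    Transient,
    decompose_srx,
    fit_exponentials,
    srx_salt_profile,
)
from srxfret.synthetic import TURNOVER_PARAMS, gen_single_turnover, turnover_measurement
from srxfret.transients import ExpFitResult, with_meta

from _oracles import biexp_grid_oracle


def _planted_transient(params, seed=0, noise=0.0, n_points=2000):
    cfg = SimConfig(seed=seed, noise_sd=noise, n_points=n_points)
    return gen_single_turnover(params, cfg)


class TestFitExponentials:
    def test_noiseless_biexponential_recovery(self, wt20):
        """Planted rates/fractions recovered to high relative accuracy."""
        fit = fit_exponentials(_planted_transient(wt20), n_components=2)
        np.testing.assert_allclose(fit.rates, [0.014, 0.0033], rtol=1e-6)
        np.testing.assert_allclose(fit.fractional_amplitudes, [0.11, 0.89], rtol=1e-6)
        assert fit.f_inf == pytest.approx(0.1, abs=1e-6)

    def test_auto_selects_single_phase_for_monoexponential(self):
        m = SRXMeasurement(drx_rate=0.02, drx_fraction=1.0, srx_rate=0.02, srx_fraction=0.0)
        fit = fit_exponentials(_planted_transient(m), n_components="auto")
        assert fit.n_components == 1

    def test_auto_selects_two_phases_for_biexponential(self, wt20):
        fit = fit_exponentials(_planted_transient(wt20, noise=0.005), n_components="auto")
        assert fit.n_components == 2

    def test_equal_rates_collapse_with_warning(self):
        t = np.geomspace(0.1, 1000, 500)
        y = 0.1 + np.exp(-0.01 * t)
        tr = Transient(time=t, signal=y)
        fit = fit_exponentials(tr, n_components=2)
        assert fit.n_components == 1
        assert "degenerate-rates-collapsed" in fit.warnings

    def test_matches_grid_search_oracle(self, wt20):
        """On noiseless data the optimum agrees with an independent zooming grid search."""
        tr = _planted_transient(wt20)
        fit = fit_exponentials(tr, n_components=2)
        oracle = biexp_grid_oracle(tr.time, tr.signal)
        assert fit.rates[0] == pytest.approx(oracle["k_fast"], rel=1e-4)
        assert fit.rates[1] == pytest.approx(oracle["k_slow"], rel=1e-4)
        assert fit.ss <= oracle["ss"] * (1 + 1e-4) + 1e-12

    def test_standard_errors_scale_with_noise(self, wt20):
        low = fit_exponentials(_planted_transient(wt20, seed=1, noise=0.002), 2)
        high = fit_exponentials(_planted_transient(wt20, seed=1, noise=0.02), 2)
        assert np.all(high.rate_ses > low.rate_ses)

    def test_monotone_sensitivity_to_planted_srx(self):
        """Recovered SRX fraction strictly increases with the planted fraction."""
        recovered = []
        for f_srx in (0.2, 0.4, 0.6, 0.8):
            m = SRXMeasurement(
                drx_rate=0.014, drx_fraction=1 - f_srx, srx_rate=0.0033,
                srx_fraction=f_srx,
            )
            fit = fit_exponentials(_planted_transient(m), n_components=2)
            recovered.append(decompose_srx(fit).srx_fraction)
        assert np.all(np.diff(recovered) > 0)

    @pytest.mark.parametrize("condition", sorted(TURNOVER_PARAMS))
    def test_noisy_recovery_all_conditions(self, condition):
        """Median recovered SRX fraction within 0.02 of planted at 0.5% noise."""
        construct, kcl = condition
        planted = turnover_measurement(construct, kcl)
        fracs = []
        for i in range(50):
            tr = _planted_transient(planted, seed=1000 + i, noise=0.005, n_points=1000)
            fracs.append(decompose_srx(fit_exponentials(tr, 2)).srx_fraction)
        assert abs(np.median(fracs) - planted.srx_fraction) < 0.02

    def test_zero_span_signal_rejected(self):
        t = np.geomspace(0.1, 100, 50)
        with pytest.raises(Exception):
            fit_exponentials(Transient(time=t, signal=np.ones_like(t)))


class TestDecomposeSrx:
    def test_two_phase_decomposition(self):
        fit = ExpFitResult(
            n_components=2, f_inf=0.0, rates=np.array([0.013, 0.0042]),
            amplitudes=np.array([0.21, 0.79]), rate_ses=np.zeros(2),
            amplitude_ses=np.zeros(2), f_inf_se=0.0,
            fractional_amplitudes=np.array([0.21, 0.79]), ss=0.0,
            aicc={2: 0.0}, n_points=100,
        )
        m = decompose_srx(fit)
        assert m.srx_fraction == pytest.approx(0.79)
        assert m.drx_rate == pytest.approx(0.013)
        assert m.srx_rate == pytest.approx(0.0042)

    def test_single_phase_maps_to_pure_drx(self):
        fit = ExpFitResult(
            n_components=1, f_inf=0.0, rates=np.array([0.02]),
            amplitudes=np.array([1.0]), rate_ses=np.zeros(1),
            amplitude_ses=np.zeros(1), f_inf_se=0.0,
            fractional_amplitudes=np.array([1.0]), ss=0.0, aicc={1: 0.0},
            n_points=100,
        )
        m = decompose_srx(fit)
        assert m.drx_fraction == 1.0
        assert m.srx_fraction == 0.0
        assert "single-phase" in m.flags

    def test_even_split_is_preserved(self):
        fit = ExpFitResult(
            n_components=2, f_inf=0.0, rates=np.array([0.02, 0.002]),
            amplitudes=np.array([0.5, 0.5]), rate_ses=np.zeros(2),
            amplitude_ses=np.zeros(2), f_inf_se=0.0,
            fractional_amplitudes=np.array([0.5, 0.5]), ss=0.0,
            aicc={2: 0.0}, n_points=100,
        )
        assert decompose_srx(fit).srx_fraction == 0.5


def _measurement(construct, kcl, f_srx, prep):
    return SRXMeasurement(
        drx_rate=0.014, drx_fraction=1 - f_srx, srx_rate=0.0033, srx_fraction=f_srx,
        meta={"construct": construct, "kcl_mM": kcl, "prep": prep},
    )


class TestSaltProfile:
    def test_group_separation_detected(self, rng):
        """WT vs mutant SRX fractions at 150 mM separate with p < 0.005."""
        ms = []
        for prep in range(3):
            ms.append(_measurement("WT", 150, np.clip(rng.normal(0.13, 0.02), 0, 1), prep))
            ms.append(_measurement("E525K", 150, np.clip(rng.normal(0.79, 0.03), 0, 1), prep))
        prof = srx_salt_profile(ms)
        wt = prof[prof["construct"] == "WT"]["srx_fraction_mean"].iloc[0]
        mut = prof[prof["construct"] == "E525K"]["srx_fraction_mean"].iloc[0]
        assert abs(wt - 0.13) < 0.05 and abs(mut - 0.79) < 0.05
        assert prof["p_value"].iloc[0] < 0.005

    def test_identical_groups_give_null_pvalue(self):
        ms = [
            _measurement(c, 20, 0.5, p) for c in ("WT", "E525K") for p in range(3)
        ]
        prof = srx_salt_profile(ms)
        assert prof["p_value"].iloc[0] > 0.99

    def test_fractions_sum_to_one_in_every_row(self, rng):
        ms = [
            _measurement("WT", kcl, f, p)
            for kcl, f in [(20, 0.89), (50, 0.57), (150, 0.13)]
            for p in range(2)
        ]
        prof = srx_salt_profile(ms)
        total = prof["drx_fraction_mean"] + prof["srx_fraction_mean"]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_single_replicate_skips_sd_and_test(self):
        prof = srx_salt_profile([_measurement("WT", 20, 0.89, 1)])
        assert np.isnan(prof["srx_fraction_sd"].iloc[0])
        assert np.isnan(prof["p_value"].iloc[0])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    f_srx=st.floats(min_value=0.05, max_value=0.95),
    k_fast=st.floats(min_value=0.01, max_value=0.05),
    ratio=st.floats(min_value=4.0, max_value=10.0),
)
def test_property_noiseless_roundtrip(f_srx, k_fast, ratio):
    """Any well-separated planted parameter set round-trips through the fitter."""
    m = SRXMeasurement(
        drx_rate=k_fast, drx_fraction=1 - f_srx, srx_rate=k_fast / ratio,
        srx_fraction=f_srx,
    )
    cfg = SimConfig(seed=0, noise_sd=0.0, n_points=600)
    fit = fit_exponentials(gen_single_turnover(m, cfg), n_components=2)
    rec = decompose_srx(fit)
    assert rec.srx_fraction == pytest.approx(f_srx, abs=1e-4)
    assert rec.drx_rate == pytest.approx(k_fast, rel=1e-3)


def test_with_meta_merges():
    m = _measurement("WT", 20, 0.5, 1)
    m2 = with_meta(m, prep=7)
    assert m2.meta["prep"] == 7 and m2.meta["construct"] == "WT"
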