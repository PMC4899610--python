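"""Rate fitting, flux calibration, derived metrics, table assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clperox.errors import ConfigurationError, DomainError, InsufficientDataError
from clperox.metrics import (
    COMPLETE_INHIBITION,
    INHIBITION_ONGOING,
    RunGroup,
    build_metrics_table,
    chain_propagation_length,
    fit_oxidation_rate,
    inhibition_duration,
    inhibition_efficiency,
    lag_analysis,
    radical_flux,
    replicate_stats,
    round_sig,
    stoichiometric_factor,
)
from clperox.spectra import KineticTrace


def _trace(t, v):
    return KineticTrace(np.asarray(t, float), np.asarray(v, float), species="dienes")


# ---------------------------------------------------------------------------
# fit_oxidation_rate
# ---------------------------------------------------------------------------

class TestFitRate:
    def test_two_point_difference_quotient(self):
        est = fit_oxidation_rate(_trace([0.0, 25.0], [0.0, 8.25e-6]), (0.0, 25.0))
        assert est.rate == pytest.approx(3.3e-7, rel=1e-12)
        assert est.n_points == 2

    def test_constant_trace_zero_rate(self):
        est = fit_oxidation_rate(_trace(np.arange(6) * 5.0, np.full(6, 2e-6)), (0, 25))
        assert est.rate == pytest.approx(0.0, abs=1e-18)

    def test_noiseless_line_recovered_to_machine_precision(self):
        t = np.arange(20) * 5.0
        est = fit_oxidation_rate(_trace(t, 5e-9 * t + 1e-7), (0, 100))
        assert est.rate == pytest.approx(5e-9, rel=1e-12)
        assert est.residual_rms < 1e-20

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_oxidation_rate(_trace([0.0, 50.0], [0.0, 1e-6]), (0.0, 25.0))

    @given(
        c1=st.floats(-1e-6, 1e-5),
        c2=st.floats(-1e-6, 1e-5),
        dt=st.floats(1.0, 100.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ols_equals_difference_quotient_on_two_points(self, c1, c2, dt):
        est = fit_oxidation_rate(_trace([0.0, dt], [c1, c2]), (0.0, dt))
        assert est.rate == pytest.approx((c2 - c1) / dt, rel=1e-9, abs=1e-18)


# ---------------------------------------------------------------------------
# flux / chain length / efficiency / stoichiometry
# ---------------------------------------------------------------------------

class TestFlux:
    def test_reference_calibration(self):
        f = radical_flux(1e-6, 170.0, 2.0)
        assert f.Ri * 1e9 == pytest.approx(11.7647, abs=1e-3)
        assert round_sig(f.Ri * 1e9, 3) == 11.8

    def test_simple_arithmetic(self):
        assert radical_flux(1e-6, 100.0, 1.0).Ri == pytest.approx(1e-8)

    @given(c=st.floats(1e-8, 1e-4))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_linearity_in_concentration(self, c):
        assert radical_flux(2 * c, 170.0, 2.0).Ri == pytest.approx(
            2 * radical_flux(c, 170.0, 2.0).Ri, rel=1e-12
        )

    @pytest.mark.parametrize("conc,dur,n", [(1e-6, 0.0, 2.0), (1e-6, -5.0, 2.0), (0.0, 170.0, 2.0)])
    def test_domain_errors(self, conc, dur, n):
        with pytest.raises(DomainError):
            radical_flux(conc, dur, n)


class TestDerivedRatios:
    def setup_method(self):
        self.flux = radical_flux(1e-6, 170.0, 2.0)
        self.flux_printed = radical_flux(1.18e-6, 100.0, 1.0)  # Ri = 11.8 nM/min exactly

    def test_chain_length_pure_cl(self):
        nu = chain_propagation_length(334e-9, self.flux_printed)
        assert nu == pytest.approx(28.305, abs=0.01)
        assert round_sig(nu, 2) == 28

    def test_chain_length_identity(self):
        assert chain_propagation_length(11.8e-9, self.flux_printed) == pytest.approx(1.0)

    def test_chain_length_inhibited_row(self):
        nu = chain_propagation_length(4.55e-9, self.flux_printed)
        assert round_sig(nu, 2) == pytest.approx(0.39)

    def test_chain_length_negative_rate(self):
        with pytest.raises(DomainError):
            chain_propagation_length(-1e-9, self.flux)

    @pytest.mark.parametrize(
        "unin,inh,expected",
        [(334e-9, 3.28e-9, 102), (334e-9, 10.6e-9, 32), (5e-9, 5e-9, 1)],
    )
    def test_inhibition_efficiency(self, unin, inh, expected):
        assert round(inhibition_efficiency(unin, inh)) == expected

    def test_complete_inhibition_sentinel(self):
        assert inhibition_efficiency(334e-9, 0.0) is COMPLETE_INHIBITION

    def test_stoichiometric_factor_examples(self):
        assert stoichiometric_factor(self.flux_printed, 170.0, 1e-6) == pytest.approx(2.006, abs=0.001)
        assert stoichiometric_factor(self.flux_printed, 0.0, 1e-6) == 0.0
        assert stoichiometric_factor(self.flux_printed, 104.0, 1e-6) == pytest.approx(1.227, abs=0.005)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_scale_invariance(self, scale):
        """Scaling all rates and concentrations leaves the ratios unchanged."""
        f1 = radical_flux(1e-6, 170.0, 2.0)
        f2 = radical_flux(scale * 1e-6, 170.0, 2.0)
        assert chain_propagation_length(scale * 334e-9, f2) == pytest.approx(
            chain_propagation_length(334e-9, f1), rel=1e-9
        )
        assert inhibition_efficiency(scale * 334e-9, scale * 4e-9) == pytest.approx(
            inhibition_efficiency(334e-9, 4e-9), rel=1e-9
        )
        assert stoichiometric_factor(f2, 104.0, scale * 1e-6) == pytest.approx(
            stoichiometric_factor(f1, 104.0, 1e-6), rel=1e-9
        )


# ---------------------------------------------------------------------------
# replicate stats
# ---------------------------------------------------------------------------

class TestReplicateStats:
    def test_identical_values(self):
        s = replicate_stats([5.0, 5.0, 5.0])
        assert (s.mean, s.sd, s.n) == (5.0, 0.0, 3)

    def test_sample_sd(self):
        s = replicate_stats([2.0, 4.0, 6.0])
        assert s.mean == 4.0
        assert s.sd == pytest.approx(2.0)

    def test_single_value_flagged(self):
        s = replicate_stats([3.0])
        assert s.sd == 0.0 and s.low_n

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            replicate_stats([])

    def test_simulated_pure_cl_replicates_center_on_truth(self, panel):
        """Five noisy uninhibited runs average near the configured 330 nM/min."""
        from clperox.spectra import diene_trace

        rates = [
            fit_oxidation_rate(diene_trace(r.series), (0.0, 25.0)).rate * 1e9
            for r in panel.groups()["pure CL"]
        ]
        s = replicate_stats(rates)
        assert abs(s.mean - 330.0) < max(2 * s.sd, 0.05 * 330.0)


# ---------------------------------------------------------------------------
# inhibition duration
# ---------------------------------------------------------------------------

class TestInhibitionDuration:
    def _piecewise(self, kink=100.0, r1=3e-9, r2=330e-9, t_end=200.0, dt=5.0):
        t = np.arange(0.0, t_end + dt / 2, dt)
        v = np.where(t <= kink, r1 * t, r1 * kink + r2 * (t - kink))
        return _trace(t, v)

    def test_piecewise_linear_intersection(self):
        d = inhibition_duration(self._piecewise(), 330e-9, 0.0)
        assert d == pytest.approx(100.0, abs=1.0)

    def test_uninhibited_like_trace_has_zero_lag(self):
        t = np.arange(0.0, 200.0, 5.0)
        d = inhibition_duration(_trace(t, 330e-9 * t), 330e-9, 0.0)
        assert d == 0.0

    def test_ongoing_inhibition_sentinel(self):
        t = np.arange(0.0, 200.0, 5.0)
        d = inhibition_duration(_trace(t, 3e-9 * t), 330e-9, 0.0)
        assert d is INHIBITION_ONGOING

    def test_delayed_addition_offset(self):
        d = inhibition_duration(self._piecewise(kink=130.0), 330e-9, t_addition=30.0)
        assert d == pytest.approx(100.0, abs=1.5)

    def test_simulated_chromanol_lag_matches_analytic(self, chromanol_run):
        """Noiseless n=2, 1 uM, Ri=11.8 nM/min run: lag ~ 2 uM-min/11.8 nM."""
        d = inhibition_duration(chromanol_run.diene_trace, 330e-9, 0.0)
        assert d == pytest.approx(169.5, rel=0.10)

    @pytest.mark.parametrize("n_nominal,aox_class", [(2.0, "chromanol"), (1.0, "plastoquinol")])
    @pytest.mark.parametrize("conc", [0.5e-6, 1e-6, 5e-6])
    def test_lag_grid_matches_analytic(self, n_nominal, aox_class, conc):
        """Across n in {1,2} and [AH] in {0.5,1,5} uM the measured lag
        agrees with n [AH] / Ri within 10% on noiseless output."""
        from clperox.antioxidants import get_antioxidant
        from clperox.simulator import (
            AntioxidantDose,
            RateConstants,
            SimulationConfig,
            predicted_lag,
            simulate,
        )

        lag = predicted_lag(n_nominal, conc, 1.18e-8)
        cfg = SimulationConfig(
            antioxidant=AntioxidantDose(get_antioxidant("alpha-tocopherol"), conc),
            duration_min=10.0 * math.ceil((lag + 120.0) / 10.0),
            noise_sd=0.0,
        )
        res = simulate(cfg, RateConstants.for_class(aox_class))
        d = inhibition_duration(res.diene_trace, 330e-9, 0.0)
        assert d == pytest.approx(lag, rel=0.10)


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

class TestMetricsTable:
    def _flux(self):
        return radical_flux(1.18e-6, 100.0, 1.0)  # Ri = 11.8 nM/min

    def test_single_uninhibited_group(self):
        rows = build_metrics_table(
            [RunGroup("pure CL", [330e-9, 338e-9], uninhibited=True)], self._flux()
        )
        assert len(rows) == 1
        r = rows[0]
        assert r.inhibition_efficiency is None and r.inhibition_duration_min is None
        assert r.chain_length == pytest.approx(round_sig(334e-9 / 1.18e-8 * 1e9 / 1e9, 2))

    def test_missing_uninhibited_group(self):
        with pytest.raises(ConfigurationError):
            build_metrics_table([RunGroup("Q10H2", [4e-9])], self._flux())

    def test_consistency_triangle(self):
        """efficiency x inhibited rate = uninhibited rate; chain x Ri = rate."""
        flux = self._flux()
        groups = [
            RunGroup("pure CL", [334e-9], uninhibited=True),
            RunGroup("Q10H2", [4.55e-9], durations=[104.0], concentration=1e-6),
            RunGroup("decPQH2", [3.28e-9], durations=[48.7], concentration=1e-6),
        ]
        rows = build_metrics_table(groups, flux, rounded=False)
        unin = rows[0].oxidation_rate_nM_min
        for r in rows[1:]:
            assert r.inhibition_efficiency * r.oxidation_rate_nM_min == pytest.approx(unin, rel=1e-9)
            assert r.chain_length * flux.Ri * 1e9 == pytest.approx(r.oxidation_rate_nM_min, rel=1e-9)

    def test_published_rates_reproduce_printed_columns(self):
        """Feeding the printed mean rates reproduces the printed derived cells."""
        from clperox.published import TABLE_ROWS

        flux = radical_flux(1e-6, 170.0, 2.0)
        groups = [RunGroup("Pure CL", [334e-9], uninhibited=True)]
        for name, (rate, _sd, *_rest) in TABLE_ROWS.items():
            if name == "Pure CL":
                continue
            groups.append(RunGroup(name, [rate * 1e-9], concentration=1e-6))
        rows = {r.antioxidant: r for r in build_metrics_table(groups, flux)}
        for name, (_r, _s, chain, eff, *_rest) in TABLE_ROWS.items():
            assert rows[name].chain_length == pytest.approx(chain), name
            if eff is not None:
                assert rows[name].inhibition_efficiency == eff, name

    def test_na_durations_propagate(self):
        rows = build_metrics_table(
            [
                RunGroup("pure CL", [334e-9], uninhibited=True),
                RunGroup("HPMC", [8.62e-9], durations=None, concentration=1e-6),
            ],
            self._flux(),
        )
        assert rows[1].inhibition_duration_min is None
        assert rows[1].stoichiometric_factor is None
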