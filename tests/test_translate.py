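"""Clinical translation: unit bridge, subject simulation, AUEC, scans,
virtual populations."""

import numpy as np
import pytest

import cardiotd as ct


def _q3w(drug, dose_per_m2, horizon=1512.0):
    n_cycles = max(int(horizon // 504.0), 1)
    return ct.build_regimen(drug, dose_per_m2, 1.8, 504.0, n_cycles, horizon=horizon)


class TestUnitBridge:
    def test_zero_and_reference_values(self):
        assert ct.to_micromolar(0.0, 543.52) == 0.0
        assert ct.to_micromolar(1.0, ct.MOLAR_MASS_DOX) == pytest.approx(
            1000.0 / 543.52, rel=1e-12)
        assert ct.to_micromolar(1.0, ct.MOLAR_MASS_DEX) == pytest.approx(
            1000.0 / 268.27, rel=1e-12)

    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            ct.to_micromolar(1.0, 0.0)


class TestAUEC:
    def test_constant_profile_rectangle(self):
        t = np.linspace(0, 504, 2017)
        assert ct.auec(t, np.full_like(t, 100.0), 0, 504) == pytest.approx(50400.0)

    def test_linear_profile_exact_trapezoid(self):
        t = np.linspace(0, 10, 11)
        v = 3.0 * t + 2.0
        assert ct.auec(t, v, 0, 10) == pytest.approx(0.5 * (2 + 32) * 10, rel=1e-12)

    def test_window_outside_profile_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            ct.auec(t, t, 0, 20)
        with pytest.raises(ValueError):
            ct.auec(t, t, 5, 5)

    def test_grid_refinement_convergence(self):
        """Halving the output grid spacing changes AUEC by < 0.01%."""
        regd, regx = _q3w("DOX", 50.0, 504.0), _q3w("DEX", 500.0, 504.0)
        a = {}
        for dt in (0.25, 0.125):
            r = ct.simulate_subject(regd, regx, dt=dt)
            a[dt] = ct.auec(r.times, r.viability, 0, 504)
        assert abs(a[0.125] / a[0.25] - 1) < 1e-4


class TestSubjectSimulation:
    def test_untreated_subject_grows_exponentially(self, td):
        zero_d = ct.build_regimen("DOX", 0.0, 1.8, 504.0, 1, horizon=504.0)
        zero_x = ct.build_regimen("DEX", 0.0, 1.8, 504.0, 1, horizon=504.0)
        res = ct.simulate_subject(zero_d, zero_x)
        np.testing.assert_allclose(res.viability, 100.0 * np.exp(td.kg * res.times),
                                   rtol=1e-6)

    def test_dex_only_regimen_inhibits_growth(self, td):
        zero_d = ct.build_regimen("DOX", 0.0, 1.8, 504.0, 1, horizon=504.0)
        dex = ct.build_regimen("DEX", 500.0, 1.8, 504.0, 1, horizon=504.0)
        res = ct.simulate_subject(zero_d, dex, clamp_net_kill=True)
        control = 100.0 * np.exp(td.kg * res.times)
        assert np.all(res.viability[1:] < control[1:])

    def test_dex_coadministration_protects(self):
        """Full-pipeline check of the headline direction: adding DEX to a
        Q3W DOX regimen raises end-of-treatment viability."""
        dox = _q3w("DOX", 50.0)
        alone = ct.simulate_subject(dox, _q3w("DEX", 0.0))
        combo = ct.simulate_subject(dox, _q3w("DEX", 500.0))
        assert combo.viability[-1] > alone.viability[-1]

    def test_deterministic_rerun(self):
        a = ct.simulate_subject(_q3w("DOX", 50.0, 504.0), _q3w("DEX", 500.0, 504.0))
        b = ct.simulate_subject(_q3w("DOX", 50.0, 504.0), _q3w("DEX", 500.0, 504.0))
        np.testing.assert_array_equal(a.viability, b.viability)


@pytest.fixture(scope="module")
def small_scan():
    return ct.scan_dose_ratios(50.0, (0.0, 10.0, 20.0), n_cycles=1,
                               include_literal=False)


class TestRatioScan:
    def test_ratio_zero_is_exactly_one(self, small_scan):
        row = small_scan.table.loc[small_scan.table.ratio == 0.0]
        assert float(row.auec_ratio.iloc[0]) == 1.0

    def test_protection_exceeds_unity(self, small_scan):
        assert (small_scan.table.loc[small_scan.table.ratio > 0, "auec_ratio"] > 1).all()

    def test_optimum_reported_and_in_grid(self, small_scan):
        assert small_scan.optimum_ratio in set(small_scan.table.ratio)

    def test_kill_chain_input_monotone_in_dex_dose(self, td):
        """The mechanistic monotone property behind the scan: at every time,
        more DEX gives a smaller (clamped) kill-chain input."""
        dox = _q3w("DOX", 50.0, 504.0)
        u = {}
        for ratio in (5.0, 20.0):
            res = ct.simulate_subject(dox, _q3w("DEX", ratio * 50.0, 504.0))
            u[ratio] = np.maximum(
                ct.dox_kill_rate(res.c_dox_uM, td)
                - ct.dex_inhibition_rate(res.c_dex_uM, td), 0.0)
        assert np.all(u[20.0] <= u[5.0] + 1e-15)

    def test_auec_ratio_shift_invariance(self):
        """Delaying every dose by a day rescales both AUECs by the same
        growth factor: the protection ratio is unchanged."""
        offset = 24.0
        dox, dex = _q3w("DOX", 50.0, 504.0), _q3w("DEX", 500.0, 504.0)
        base_d = ct.simulate_subject(dox, _q3w("DEX", 0.0, 504.0))
        base_c = ct.simulate_subject(dox, dex)
        r_base = (ct.auec(base_c.times, base_c.viability, 0, 504)
                  / ct.auec(base_d.times, base_d.viability, 0, 504))
        sd, sx = dox.shifted(offset), dex.shifted(offset)
        zero_shift = ct.build_regimen("DEX", 0.0, 1.8, 504.0, 1,
                                      horizon=504.0 + offset)
        shift_d = ct.simulate_subject(sd, zero_shift)
        shift_c = ct.simulate_subject(sd, sx)
        r_shift = (ct.auec(shift_c.times, shift_c.viability, offset, 504 + offset)
                   / ct.auec(shift_d.times, shift_d.viability, offset, 504 + offset))
        assert r_shift == pytest.approx(r_base, rel=1e-5)


class TestPopulation:
    def test_zero_iiv_collapses_to_typical(self):
        spec = ct.PopulationSpec(n_subjects=4, iiv_cv=0.0, seed=1)
        res = ct.population_simulate(spec, _q3w("DOX", 50.0, 504.0),
                                     _q3w("DEX", 500.0, 504.0))
        typical = ct.simulate_subject(_q3w("DOX", 50.0, 504.0),
                                      _q3w("DEX", 500.0, 504.0))
        for prof in res.profiles:
            np.testing.assert_array_equal(prof, typical.viability)

    def test_sampled_parameter_cv_matches_nominal(self, td):
        spec = ct.PopulationSpec(n_subjects=2000, iiv_cv=0.10, seed=3)
        draws = ct.sample_population_params(spec, td)
        for name in spec.targets:
            cv = draws[name].std(ddof=1) / draws[name].mean()
            assert 0.08 <= cv <= 0.12, name
            # median on the exponential scale equals the typical value
            assert np.median(draws[name]) == pytest.approx(getattr(td, name), rel=0.02)

    def test_same_seed_same_ensemble(self):
        spec = ct.PopulationSpec(n_subjects=3, iiv_cv=0.10, seed=7)
        a = ct.population_simulate(spec, _q3w("DOX", 50.0, 504.0),
                                   _q3w("DEX", 500.0, 504.0))
        b = ct.population_simulate(spec, _q3w("DOX", 50.0, 504.0),
                                   _q3w("DEX", 500.0, 504.0))
        np.testing.assert_array_equal(a.profiles, b.profiles)

    def test_median_profile_near_typical(self):
        """With moderate n the population median profile tracks the typical
        subject within Monte-Carlo error."""
        spec = ct.PopulationSpec(n_subjects=60, iiv_cv=0.10, seed=11)
        dox, dex = _q3w("DOX", 50.0, 504.0), _q3w("DEX", 500.0, 504.0)
        res = ct.population_simulate(spec, dox, dex, dt=1.0)
        typical = ct.simulate_subject(dox, dex, dt=1.0)
        end_ratio = res.quantiles[50][-1] / typical.viability[-1]
        assert 0.9 < end_ratio < 1.1


@pytest.fixture(scope="module")
def table():
    return ct.compare_fractionation()


class TestFractionation:
    def test_four_arms_two_windows(self, table):
        assert set(table.arm) == {"Q3W", "Q3W+DEX", "Q1W", "Q1W+DEX"}
        assert table.window.nunique() == 2

    def test_dex_arms_beat_their_dox_alone_counterparts(self, table):
        full = table[table.window.str.startswith("full")]
        a = full.set_index("arm").auec
        assert a["Q3W+DEX"] > a["Q3W"]
        assert a["Q1W+DEX"] > a["Q1W"]

    def test_nine_week_best_arm_is_flagged(self, table):
        full = table[table.window.str.startswith("full")]
        assert full.loc[full.best, "arm"].size == 1
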