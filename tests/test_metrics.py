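"""Synchrony/participation metrics against analytic and fixture ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibnet.metrics import (
    chi_measure,
    classify_regime,
    fit_chi_infinity,
    fit_critical_noise,
    isi_stats,
    participation_spc,
    population_cycle_peaks,
    vector_length,
)
from inhibnet.netsim import SpikeRaster, smoothed_population_rate
from inhibnet.synthetic import (
    SyncRasterSpec,
    gen_poisson_raster,
    gen_sync_raster,
    gen_voltage_surrogates,
    surrogate_chi_expected,
)


class TestChi:
    def test_identical_traces_give_one(self, rng):
        v = rng.normal(size=(500, 1))
        assert chi_measure(np.repeat(v, 8, axis=1)) == pytest.approx(1.0)

    def test_constant_traces_rejected(self):
        with pytest.raises(ValueError):
            chi_measure(np.ones((100, 5)))

    @pytest.mark.parametrize("N,shared,indep", [(50, 1.0, 1.0), (200, 0.5, 2.0), (800, 2.0, 0.5)])
    def test_surrogates_match_variance_algebra(self, N, shared, indep):
        v = gen_voltage_surrogates(N, 10000.0, shared, indep, seed=3)
        expected = surrogate_chi_expected(N, shared, indep)
        assert chi_measure(v) == pytest.approx(expected, rel=0.02)

    def test_independent_traces_scale_as_inverse_sqrt_n(self):
        v = gen_voltage_surrogates(1000, 5000.0, 0.0, 1.0, seed=4)
        assert chi_measure(v) == pytest.approx(np.sqrt(1.0 / 1000), rel=0.1)

    def test_raw_ratio_is_square_of_chi(self, rng):
        v = rng.normal(size=(400, 20)) + rng.normal(size=(400, 1))
        assert chi_measure(v, sqrt=False) == pytest.approx(chi_measure(v) ** 2)


class TestChiScalingFits:
    def test_exact_recovery_through_model_points(self):
        chi_inf, d = 0.3, 1.7
        pairs = [(n, chi_inf + d / np.sqrt(n)) for n in (800, 1400, 2200, 3000)]
        fit = fit_chi_infinity(pairs)
        assert fit == pytest.approx((chi_inf, d), abs=1e-12)

    def test_floor_at_zero(self):
        pairs = [(n, -0.2 + 1.0 / np.sqrt(n)) for n in (800, 3000)]
        assert fit_chi_infinity(pairs)[0] == 0.0

    def test_surrogate_ensembles_recover_analytic_limit(self):
        shared, indep = 0.6, 1.2
        pairs = []
        for n in (800, 1400, 2200, 3000):
            v = gen_voltage_surrogates(n, 6000.0, shared, indep, seed=n)
            pairs.append((n, chi_measure(v)))
        chi_inf, _ = fit_chi_infinity(pairs)
        analytic = surrogate_chi_expected(10**9, shared, indep)
        assert chi_inf == pytest.approx(analytic, abs=0.03)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_chi_infinity([(800, 0.5)])


class TestCriticalNoiseFit:
    def test_noiseless_square_root_data_exact(self):
        sc, A = 2.0, 0.45
        s = np.linspace(0.1, 3.0, 25)
        chi = A * np.sqrt(np.clip(sc - s, 0, None))
        fit = fit_critical_noise(s, chi)
        assert fit == pytest.approx((sc, A), rel=1e-6)

    def test_all_zero_reports_no_bifurcation(self):
        with pytest.raises(ValueError, match="no bifurcation"):
            fit_critical_noise([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])

    def test_recovery_under_observation_noise(self):
        # Monte-Carlo: sigma_c recovered within 5% bias across replicates
        rng = np.random.default_rng(11)
        sc, A = 1.5, 0.4
        s = np.linspace(0.1, 2.5, 20)
        est = []
        for _ in range(100):
            chi = A * np.sqrt(np.clip(sc - s, 0, None)) + rng.normal(0, 0.01, s.size)
            est.append(fit_critical_noise(s, np.clip(chi, 0, None))[0])
        assert abs(np.mean(est) - sc) / sc < 0.05


class TestParticipation:
    def test_full_participation_gives_one(self):
        r = gen_sync_raster(SyncRasterSpec(N=300, participation=1.0, jitter_ms=0.5, seed=1))
        spc, peaks = participation_spc(r)
        assert spc == pytest.approx(1.0, abs=0.02)
        # periodic volleys: peak spacing within a bin of the true period
        assert np.all(np.abs(np.diff(peaks) - 33.0) <= 1.5)

    @pytest.mark.parametrize("p", [0.2, 0.4, 0.5, 0.6, 0.8, 1.0])
    def test_recovers_fixture_participation(self, p):
        r = gen_sync_raster(SyncRasterSpec(N=500, participation=p, jitter_ms=1.0,
                                           n_cycles=80, seed=17))
        spc, _ = participation_spc(r)
        assert spc == pytest.approx(p, abs=0.03)

    def test_empty_raster_rejected(self):
        r = SpikeRaster(np.array([]), np.array([]), 10, 1000.0)
        with pytest.raises(ValueError):
            participation_spc(r)

    def test_invariance_to_relabeling_and_translation(self, rng):
        r = gen_sync_raster(SyncRasterSpec(N=200, participation=0.7, seed=5))
        spc0, peaks0 = participation_spc(r)
        perm = rng.permutation(r.N)
        r2 = SpikeRaster(perm[r.neuron], r.time, r.N, r.duration)
        assert participation_spc(r2)[0] == pytest.approx(spc0)
        r3 = r.shifted(500.0)
        assert participation_spc(r3)[0] == pytest.approx(spc0, abs=0.02)


class TestVectorLength:
    def test_aligned_spikes_give_unit_length(self):
        peaks = np.arange(0.0, 1000.0, 40.0)
        t = peaks[:-1] + 0.0
        r = SpikeRaster(np.zeros(t.size, dtype=int), t, 1, 1000.0)
        R, _ = vector_length(r, peaks)
        assert R == pytest.approx(1.0)

    def test_uniform_phases_decay_as_inverse_sqrt_n(self, rng):
        # circular statistics: E[R] ~ sqrt(pi)/2 / sqrt(n) for uniform phases
        peaks = np.arange(0.0, 100000.0, 40.0)
        for n in (100, 1000):
            t = rng.uniform(0.0, 99960.0, size=n)
            r = SpikeRaster(np.zeros(n, dtype=int), t, 1, 100000.0)
            R, _ = vector_length(r, peaks)
            assert R < 4.0 / np.sqrt(n)

    def test_jittered_volleys_concentrated(self):
        r = gen_sync_raster(SyncRasterSpec(N=400, participation=0.8, jitter_ms=1.0, seed=2))
        spc, peaks = participation_spc(r)
        R, _ = vector_length(r, peaks)
        assert R > 0.9

    def test_needs_complete_cycle(self):
        r = SpikeRaster(np.array([0]), np.array([5.0]), 1, 10.0)
        with pytest.raises(ValueError):
            vector_length(r, np.array([1.0]))


class TestRegimeClassification:
    @pytest.mark.parametrize("spc,label", [(0.49, "SPO"), (0.58, "SPO"), (0.8, "TO")])
    def test_threshold_rules(self, spc, label):
        assert classify_regime(spc) == label

    def test_pir_requires_subthreshold_current(self):
        trace = np.full(100, 0.1)
        assert classify_regime(1.0, trace, I_AH=0.2625) == "PIR"
        trace[50] = 0.5
        assert classify_regime(1.0, trace, I_AH=0.2625) == "CO"

    def test_co_without_current_trace(self):
        assert classify_regime(0.95) == "CO"


class TestISIStats:
    def test_periodic_trains_have_zero_cv_single_mode(self):
        t = np.tile(np.arange(10.0, 2000.0, 25.0), 5)
        n = np.repeat(np.arange(5), np.arange(10.0, 2000.0, 25.0).size)
        r = SpikeRaster(n, t, 5, 2000.0)
        st_ = isi_stats(r, bin_ms=5.0)
        assert np.all(st_["cv"] < 1e-9)
        assert st_["modes_ms"].size == 1

    def test_poisson_cv_near_one(self):
        r = gen_poisson_raster(50, 20.0, 20000.0, refractory_ms=0.0, seed=9)
        st_ = isi_stats(r)
        assert np.mean(st_["cv"]) == pytest.approx(1.0, abs=0.1)

    def test_cycle_skipping_subharmonic_modes(self, rng):
        # period-T volleys with 50% skipping: ISI modes at T and 2T
        T, n_cycles, N = 30.0, 400, 30
        neurons, times = [], []
        for i in range(N):
            fire = rng.random(n_cycles) < 0.5
            t = (np.nonzero(fire)[0] + 1) * T + rng.normal(0, 0.5, np.sum(fire))
            neurons.append(np.full(t.size, i))
            times.append(t)
        r = SpikeRaster(np.concatenate(neurons), np.concatenate(times), N, (n_cycles + 1) * T)
        st_ = isi_stats(r, bin_ms=10.0, population_period=T)
        flagged = st_["modes_ms"][np.asarray(st_["subharmonic_flags"], dtype=bool)]
        assert any(abs(m - T) <= 10.0 for m in flagged)
        assert any(abs(m - 2 * T) <= 10.0 for m in flagged)


class TestSmoothedRate:
    def test_single_volley_gaussian_bump(self):
        t = np.full(200, 500.0)
        r = SpikeRaster(np.arange(200), t, 200, 1000.0)
        centres, sm = smoothed_population_rate(r)
        assert abs(centres[np.argmax(sm)] - 500.0) <= 1.0
        assert np.sum(sm) == pytest.approx(200.0, rel=1e-6)

    def test_empty_raster_all_zero(self):
        r = SpikeRaster(np.array([]), np.array([]), 10, 500.0)
        _, sm = smoothed_population_rate(r)
        assert np.all(sm == 0.0)
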