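"""Network simulator invariants: coupling realization, noise scaling,
reproducibility, and the heterogeneous-network construction rules."""

import numpy as np
import pytest
from dataclasses import replace

from inhibnet.metrics import chi_measure
from inhibnet.netsim import (
    CONNECT_PROB,
    CONNECT_RADIUS_UM,
    HetNetSpec,
    NetworkConfig,
    build_heterogeneous,
    simulate_heterogeneous,
    simulate_homogeneous,
)
from inhibnet.synapses import PSCKernel


def small_cfg(**kw):
    base = dict(N=60, J=1.0, sigma=0.2, Iext=0.5, t_total=800.0,
                t_transient=200.0, seed=3)
    base.update(kw)
    return NetworkConfig(**base)


class TestHomogeneous:
    def test_uncoupled_noiseless_clones_fully_synchronous(self):
        cfg = small_cfg(J=0.0, sigma=0.0, Iext=0.5, init_v_range=(-60.0, -60.0))
        res = simulate_homogeneous(cfg)
        assert res.raster.n_spikes > 0
        # all spike trains identical -> every neuron spikes at the same times
        per_step = np.unique(res.raster.time, return_counts=True)[1]
        assert np.all(per_step == cfg.N)
        assert chi_measure(res.voltage) == pytest.approx(1.0)

    def test_subthreshold_rest_stays_quiescent(self):
        # below the saddle-node of periodics, from rest, nothing fires
        cfg = small_cfg(J=0.0, sigma=0.0, Iext=0.1, init_v_range=(-62.0, -62.0))
        res = simulate_homogeneous(cfg)
        assert res.raster.n_spikes == 0

    def test_recurrent_input_shared_and_inhibitory(self):
        cfg = small_cfg(sigma=0.3, Iext=0.5, J=2.0)
        res = simulate_homogeneous(cfg)
        # current mode: per-neuron recurrent input is the shared filter output
        # scaled by -J/N, so the population mean equals that exactly
        assert np.allclose(res.recurrent, -(cfg.J / cfg.N) * res.filter_output)
        assert np.all(res.recurrent <= 0.0)

    def test_noise_scaling_of_subthreshold_variance(self):
        # J=0, subthreshold: stationary variance of V grows as sigma^2
        out = []
        for s in (0.05, 0.1, 0.2):
            # Iext = -0.5 deepens the rest state so even the largest sigma
            # stays subthreshold over the run
            cfg = small_cfg(J=0.0, sigma=s, Iext=-0.5, t_total=3000.0,
                            t_transient=1000.0, init_v_range=(-64.05, -64.05))
            res = simulate_homogeneous(cfg)
            assert res.raster.n_spikes == 0
            out.append(np.var(res.voltage, axis=0).mean())
        slope = np.polyfit(np.log([0.05, 0.1, 0.2]), np.log(out), 1)[0]
        assert slope == pytest.approx(2.0, rel=0.10)

    def test_filter_state_equals_kernel_convolution(self):
        # the rise/decay filter pair driven through the latency ring buffer
        # must equal direct convolution of the binned spike train
        dt = 0.05
        cfg = small_cfg(N=40, sigma=0.4, Iext=0.45, J=1.5, dt=dt,
                        t_total=600.0, t_transient=0.0, record_dt=dt)
        res = simulate_homogeneous(cfg)
        n_steps = int(round(cfg.t_total / dt))
        counts = np.zeros(n_steps)
        steps = np.round(res.raster.time / dt).astype(int) - 1
        np.add.at(counts, steps, 1.0)
        kern = cfg.kernel.sample(dt, 200.0)
        s_direct = np.convolve(counts, kern)[:n_steps]
        assert res.filter_output.size == n_steps
        assert np.max(np.abs(res.filter_output - s_direct)) < 1e-6

    def test_seeded_runs_bit_reproducible(self):
        a = simulate_homogeneous(small_cfg())
        b = simulate_homogeneous(small_cfg())
        c = simulate_homogeneous(small_cfg(seed=4))
        assert np.array_equal(a.raster.time, b.raster.time)
        assert np.array_equal(a.raster.neuron, b.raster.neuron)
        assert np.array_equal(a.voltage, b.voltage)
        assert not np.array_equal(a.raster.time, c.raster.time)

    def test_via_conductance_network_runs(self):
        cfg = NetworkConfig(model="via", N=40, J=66.0, sigma=0.16, Iext=0.5,
                            synapse_mode="conductance", t_total=600.0,
                            t_transient=200.0, seed=2, dt=0.02)
        res = simulate_homogeneous(cfg)
        assert 0 < res.raster.mean_rate() < 300.0
        # conductance-mode recurrent current is inhibitory on average
        assert np.mean(res.recurrent) < 0.0

    def test_current_mode_for_via_rejected(self):
        with pytest.raises(ValueError):
            simulate_homogeneous(NetworkConfig(model="via", synapse_mode="current",
                                               N=10, t_total=100.0, t_transient=10.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(t_total=100.0, t_transient=200.0)
        with pytest.raises(ValueError):
            NetworkConfig(N=0)


class TestHeterogeneous:
    def test_construction_rules(self):
        spec = build_heterogeneous(seed=1)
        assert spec.N == 321
        assert np.all(spec.edge_delay >= 0.4) and np.all(spec.edge_delay <= 1.2)
        assert np.all(spec.edge_pre != spec.edge_post)
        d = np.linalg.norm(
            spec.positions[spec.edge_pre] - spec.positions[spec.edge_post], axis=1)
        assert d.max() <= CONNECT_RADIUS_UM
        assert np.all(spec.edge_g > 0)

    def test_connection_probability(self):
        # empirical in-radius connection probability near 36%
        hits, total = 0, 0
        for seed in range(4):
            spec = build_heterogeneous(seed=seed)
            d = np.linalg.norm(
                spec.positions[:, None] - spec.positions[None, :], axis=-1)
            in_r = (d <= CONNECT_RADIUS_UM) & ~np.eye(spec.N, dtype=bool)
            total += in_r.sum()
            hits += spec.edge_pre.size
        p = hits / total
        assert abs(p - CONNECT_PROB) < 3 * np.sqrt(CONNECT_PROB * 0.64 / total)

    def test_conductance_moments(self):
        spec = build_heterogeneous(seed=5, J_scale=1.0)
        assert np.mean(spec.edge_g) == pytest.approx(1.65, rel=0.1)
        assert np.std(spec.edge_g) == pytest.approx(1.56, rel=0.25)

    def test_simulation_deterministic(self):
        spec = build_heterogeneous(seed=2)
        kw = dict(sigma=0.0, Iext=0.5, t_total=400.0, t_transient=100.0,
                  dt=0.02, seed=9)
        a = simulate_heterogeneous(spec, **kw)
        b = simulate_heterogeneous(spec, **kw)
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.neuron, b.neuron)
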