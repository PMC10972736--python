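"""Synthetic rasters and voltage surrogates with known ground truth.

These generators exist so the synchrony/participation metrics and the
finite-size fits can be validated independently of the network simulator:
every fixture carries its analytic ground truth (participation probability,
circular concentration, chi(N)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netsim import SpikeRaster

__all__ = [
    "SyncRasterSpec",
    "gen_sync_raster",
    "gen_poisson_raster",
    "gen_voltage_surrogates",
    "surrogate_chi_expected",
]


@dataclass(frozen=True)
class SyncRasterSpec:
    """Periodic synchronous-volley raster specification.

    Per cycle each neuron spikes with probability ``participation`` at the
    cycle time plus Gaussian jitter of sd ``jitter_ms``, folded modulo the
    period into (-period/2, period/2] so spikes stay in their cycle (in the
    large-jitter limit the folded phases become uniform).  Ground truth: SPC
    equals ``participation``; the phase concentration follows the jitter.
    """

    N: int = 200
    period_ms: float = 33.0
    n_cycles: int = 60
    jitter_ms: float = 1.0
    participation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.period_ms > 0):
            raise ValueError("period must be positive")
        if not (0 < self.participation <= 1):
            raise ValueError("participation must lie in (0, 1]")


def gen_sync_raster(spec: SyncRasterSpec) -> SpikeRaster:
    """Generate a raster of jittered synchronous volleys (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    half = spec.period_ms / 2.0
    neurons = []
    times = []
    for c in range(spec.n_cycles):
        t0 = (c + 0.5) * spec.period_ms
        fire = rng.random(spec.N) < spec.participation
        idx = np.nonzero(fire)[0]
        jit = rng.normal(0.0, spec.jitter_ms, size=idx.size)
        jit = (jit + half) % spec.period_ms - half
        neurons.append(idx)
        times.append(t0 + jit)
    duration = (spec.n_cycles + 0.5) * spec.period_ms
    return SpikeRaster(np.concatenate(neurons), np.concatenate(times), spec.N, duration)


def gen_poisson_raster(
    N: int, rate_hz: float, T_ms: float, refractory_ms: float = 0.0, seed: int = 0
) -> SpikeRaster:
    """Independent (refractory-modified) Poisson spike trains.

    At zero refractory the ISI distribution is exponential (CV ~ 1); a
    refractory period shifts the ISI body without changing its shape.  The
    requested ``rate_hz`` is the post-refractory rate: the exponential part
    uses the hazard needed to keep the overall rate at ``rate_hz``.
    """
    if rate_hz * refractory_ms >= 1000.0:
        raise ValueError("rate * refractory must be < 1 (dead-time saturation)")
    rng = np.random.default_rng(seed)
    mean_isi = 1000.0 / rate_hz
    scale = mean_isi - refractory_ms
    neurons = []
    times = []
    for i in range(N):
        t = 0.0
        tt = []
        while True:
            t += refractory_ms + rng.exponential(scale)
            if t > T_ms:
                break
            tt.append(t)
        neurons.append(np.full(len(tt), i, dtype=np.int64))
        times.append(np.array(tt))
    return SpikeRaster(np.concatenate(neurons), np.concatenate(times), N, T_ms)


def surrogate_chi_expected(N: int, shared_sd: float, indep_sd: float) -> float:
    """Analytic chi(N) for shared-plus-independent voltage surrogates:
    sqrt((s^2 + n^2/N) / (s^2 + n^2))."""
    s2, n2 = shared_sd**2, indep_sd**2
    return float(np.sqrt((s2 + n2 / N) / (s2 + n2)))


def gen_voltage_surrogates(
    N: int,
    T_ms: float,
    shared_sd: float,
    indep_sd: float,
    seed: int = 0,
    *,
    dt_ms: float = 1.0,
    f_hz: float = 30.0,
) -> np.ndarray:
    """Voltage surrogates V_i(t) = s(t) + xi_i(t), shape (n_time, N).

    The shared signal s is a sinusoid-plus-noise mixture standardized to
    variance ``shared_sd**2`` (sinusoid at ``f_hz`` carrying half the shared
    power); xi_i is independent Gaussian noise of sd ``indep_sd``.  Analytic
    ground truth: chi(N) = sqrt((s^2 + n^2/N)/(s^2 + n^2)).
    """
    if shared_sd < 0 or indep_sd < 0 or (shared_sd == 0 and indep_sd == 0):
        raise ValueError("sds must be non-negative and not both zero")
    rng = np.random.default_rng(seed)
    n_time = int(round(T_ms / dt_ms))
    t = np.arange(n_time) * dt_ms
    # sin variance is 1/2 -> weight 1 gives shared variance 0.5 + 0.5 = 1
    shared = shared_sd * (
        np.sin(2 * np.pi * f_hz / 1000.0 * t) + rng.normal(0.0, np.sqrt(0.5), n_time)
    )
    indep = rng.normal(0.0, indep_sd, size=(n_time, N))
    return shared[:, None] + indep
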