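"""Biexponential postsynaptic kernel and its analytic transfer function.

The postsynaptic current elicited by one presynaptic spike is zero for a
latency ``tauL`` and then a difference of exponentials with rise and decay
time constants ``tauR < tauD``:

    s(t) = (e^{-(t-tauL)/tauD} - e^{-(t-tauL)/tauR}) / (tauD - tauR),   t >= tauL

Charge normalization (the 1/(tauD - tauR) factor) makes the kernel integrate
to 1 and is used for current-based synapses; for conductance-based synapses
the kernel is instead scaled so its maximum equals 1 ("peak" mode).

In the frequency domain the kernel is a cascade of a pure delay, two first-
order low-pass filters and (for inhibition) a sign inversion; gain and phase
of that cascade are what the mean-field Hopf predictor combines with the
measured neural transfer function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PSCKernel",
    "ReversalSpec",
    "psc_value",
    "synaptic_gain",
    "synaptic_phase",
    "synapse_only_closure_freq",
]


@dataclass(frozen=True)
class PSCKernel:
    """Biexponential PSC kernel (times in ms)."""

    tauL: float = 1.0
    tauR: float = 1.0
    tauD: float = 6.0
    mode: Literal["charge", "peak"] = "charge"

    def __post_init__(self) -> None:
        if not (self.tauD > self.tauR > 0):
            raise ValueError("require tauD > tauR > 0 (tauD == tauR is degenerate)")
        if self.tauL < 0:
            raise ValueError("latency tauL must be non-negative")
        if self.mode not in ("charge", "peak"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum: tauL + tauR tauD / (tauD - tauR) * ln(tauD/tauR)."""
        return self.tauL + self.tauR * self.tauD / (self.tauD - self.tauR) * math.log(
            self.tauD / self.tauR
        )

    @property
    def peak_value_charge(self) -> float:
        """Maximum of the charge-normalized kernel (the peak/charge proportionality)."""
        tp = self.peak_time - self.tauL
        return (math.exp(-tp / self.tauD) - math.exp(-tp / self.tauR)) / (
            self.tauD - self.tauR
        )

    @property
    def impulse_amplitude(self) -> float:
        """Per-spike increment of the rise/decay filter states realizing this kernel."""
        amp = 1.0 / (self.tauD - self.tauR)
        if self.mode == "peak":
            amp /= self.peak_value_charge
        return amp

    def sample(self, dt: float, t_max: float) -> np.ndarray:
        """Kernel sampled on the grid ``t = 0, dt, ..., < t_max``."""
        t = np.arange(0.0, t_max, dt)
        return psc_value(t, self)


@dataclass(frozen=True)
class ReversalSpec:
    """Synaptic reversal-potential assignment for conductance-based synapses.

    ``hyperpolarizing`` pins E_syn well below the operating voltage (-75 mV),
    ``shunting`` near it (-55 mV); ``uniform`` draws each synapse's E_syn
    uniformly between the two, emulating the experimentally observed spread.
    """

    mode: Literal["hyperpolarizing", "shunting", "uniform"] = "hyperpolarizing"
    E_hyp: float = -75.0
    E_shunt: float = -55.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "hyperpolarizing":
            return np.full(n, self.E_hyp)
        if self.mode == "shunting":
            return np.full(n, self.E_shunt)
        if self.mode == "uniform":
            return rng.uniform(self.E_hyp, self.E_shunt, size=n)
        raise ValueError(f"unknown reversal mode {self.mode!r}")


def psc_value(t: float | np.ndarray, k: PSCKernel = PSCKernel()) -> float | np.ndarray:
    """Kernel value at time(s) t (ms); 0 before the latency."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    late = t >= k.tauL
    tt = t[late] - k.tauL
    val = (np.exp(-tt / k.tauD) - np.exp(-tt / k.tauR)) / (k.tauD - k.tauR)
    if k.mode == "peak":
        val = val / k.peak_value_charge
    out[late] = val
    return out if out.ndim else float(out)


def synaptic_gain(omega: float | np.ndarray, k: PSCKernel = PSCKernel()) -> float | np.ndarray:
    """|H_s(omega)| = 1 / sqrt((1 + omega^2 tauR^2)(1 + omega^2 tauD^2)).

    ``omega`` in rad/ms.  This is the gain of the charge-normalized kernel
    (unit DC gain); a pure delay does not affect it.
    """
    omega = np.asarray(omega, dtype=float)
    g = 1.0 / np.sqrt((1.0 + omega**2 * k.tauR**2) * (1.0 + omega**2 * k.tauD**2))
    return g if g.ndim else float(g)


def synaptic_phase(
    omega: float | np.ndarray,
    k: PSCKernel = PSCKernel(),
    include_inversion: bool = False,
) -> float | np.ndarray:
    """Total synaptic phase in degrees (lags negative), ``omega`` in rad/ms.

    Sum of the latency lag (-omega tauL), the two first-order low-pass lags
    (arctan(-omega tau)), and, when ``include_inversion`` is set, the -180
    degrees from the inhibitory sign flip.
    """
    omega = np.asarray(omega, dtype=float)
    ph = -np.degrees(omega * k.tauL)
    ph = ph + np.degrees(np.arctan(-omega * k.tauR)) + np.degrees(np.arctan(-omega * k.tauD))
    if include_inversion:
        ph = ph - 180.0
    return ph if ph.ndim else float(ph)


def synapse_only_closure_freq(k: PSCKernel = PSCKernel()) -> float:
    """Frequency (Hz) where the synapse-only phase with inversion reaches -360
    degrees, i.e. omega tauL + arctan(omega tauR) + arctan(omega tauD) = pi.

    This is the population frequency a hypothetical zero-phase-lag neuron
    would oscillate at.
    """

    def f(w: float) -> float:
        return w * k.tauL + math.atan(w * k.tauR) + math.atan(w * k.tauD) - math.pi

    w = brentq(f, 1e-9, 1e3)
    return w / (2.0 * math.pi) * 1000.0
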