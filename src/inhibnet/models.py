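"""Single-neuron dynamics and bifurcation analysis for Type 2 (resonator) interneurons.

Two model neurons are provided:

* the quadratic Izhikevich resonator, ``dV/dt = 0.04 V^2 + 5 V + 140 - u + I``,
  ``du/dt = a (b V - u)`` with reset ``V <- c, u <- u + d`` at ``V > vpeak``.
  With ``b > a`` (recovery faster than the voltage nullcline slope at rest) the
  model shows Type 2 excitability: firing onset through a subcritical
  Andronov--Hopf (AH) bifurcation, a saddle-node of periodics (SNP) below it,
  and a discontinuous f--I curve with hysteresis between the two.
* a Hodgkin--Huxley-type single-compartment model of a PV+ fast-spiking
  interneuron ("Via" model) with fast Na, Kv7 and Kv3 delayed-rectifier
  currents and a passive leak.

Units: time in ms throughout.  Izhikevich voltages in mV, currents in
nA/cm^2 with Cm = 1 uF/cm^2 (so current equals dV/dt contribution).  The
conductance-based model uses mV, nS and pF, hence currents in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._integrators import izh_spike_times_from_state, via_spike_times_from_state

__all__ = [
    "IzhikevichParams",
    "GatingParams",
    "ViaParams",
    "BifurcationSummary",
    "izhikevich_deriv",
    "izhikevich_fixed_points",
    "find_hopf_current",
    "find_snp_current",
    "fi_curve",
    "gating_rates",
    "gating_steady_state",
    "via_deriv",
    "via_resting_potential",
    "simulate_single",
]

GATING_NAMES = ("m", "h", "n", "a")


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of the quadratic resonator model.

    ``a`` is the recovery rate (1/ms), ``b`` couples V into the recovery
    variable u, ``c`` is the post-spike reset potential (mV), ``d`` the
    post-spike recovery increment.  ``vpeak`` is the spike-detection cutoff;
    it is not part of the published parameter set and defaults to the
    conventional +30 mV.
    """

    a: float = 0.1
    b: float = 0.26
    c: float = -65.0
    d: float = 0.0
    Cm: float = 1.0
    vpeak: float = 30.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError("a must be positive")
        if not (self.c < self.vpeak):
            raise ValueError("reset potential c must lie below vpeak")


@dataclass(frozen=True)
class GatingParams:
    """Rate-function parameters (theta, sigma1, sigma2 in mV; k1, k2 in 1/ms).

    alpha(V) = k1 (theta - V) / (exp((theta - V)/sigma1) - 1)
    beta(V)  = k2 exp(V / sigma2)
    """

    theta: float
    sigma1: float
    sigma2: float
    k1: float
    k2: float


def _default_gating() -> dict[str, GatingParams]:
    # For h the k1-form rate (sigma1 = -20 < 0) is negative at every V; its
    # magnitude decreases with depolarization and acts as the de-inactivation
    # (opening) rate, while the k2-form rate grows with depolarization and
    # closes the gate.  See ``via_deriv`` for the resulting h dynamics; with
    # any other role assignment h pins at a boundary and the sodium current
    # cannot inactivate.
    return {
        "m": GatingParams(theta=-47.95, sigma1=4.0, sigma2=-13.0, k1=0.25, k2=0.1),
        "h": GatingParams(theta=-49.72, sigma1=-20.0, sigma2=3.5, k1=0.012, k2=0.2),
        "n": GatingParams(theta=11.32, sigma1=12.0, sigma2=-8.5, k1=1.0, k2=0.001),
        "a": GatingParams(theta=42.85, sigma1=12.0, sigma2=-80.0, k1=1.0, k2=0.02),
    }


@dataclass(frozen=True)
class ViaParams:
    """PV+ fast-spiking interneuron model (conductances nS, potentials mV, Cm pF)."""

    Cm: float = 81.4
    gNa: float = 18929.0
    gKv7: float = 58.5
    gKv3: float = 784.5
    gL: float = 13.8
    ENa: float = 50.0
    EK: float = -90.0
    EL: float = -77.8
    gating: dict[str, GatingParams] = field(default_factory=_default_gating)

    def __post_init__(self) -> None:
        for name in ("gNa", "gKv7", "gKv3", "gL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = set(GATING_NAMES) - set(self.gating)
        if missing:
            raise ValueError(f"missing gating entries: {sorted(missing)}")

    def gating_arrays(self) -> tuple[np.ndarray, ...]:
        """Gating table as five float arrays in (m, h, n, a) order, for the kernels."""
        g = [self.gating[x] for x in GATING_NAMES]
        return tuple(
            np.array([getattr(gp, f) for gp in g], dtype=np.float64)
            for f in ("theta", "sigma1", "sigma2", "k1", "k2")
        )


@dataclass(frozen=True)
class BifurcationSummary:
    """Single-neuron excitability landmarks.

    ``I_AH`` is the bias current at the subcritical Andronov--Hopf bifurcation
    (upper threshold for repetitive-firing onset), ``I_SNP`` the saddle-node of
    periodics (lower boundary of sustained firing), ``f_min`` the minimum
    sustained firing rate just above the SNP.  ``I_SNP < I_AH`` delimits the
    bistable band.
    """

    I_AH: float
    I_SNP: float
    f_min: float

    def __post_init__(self) -> None:
        if not (self.I_SNP < self.I_AH):
            raise ValueError("expected I_SNP < I_AH (bistable band)")
        if not (self.f_min > 0):
            raise ValueError("f_min must be positive")

    def to_dict(self) -> dict[str, float]:
        return {"I_AH": self.I_AH, "I_SNP": self.I_SNP, "f_min": self.f_min}


# ---------------------------------------------------------------------------
# Izhikevich model
# ---------------------------------------------------------------------------

def izhikevich_deriv(
    v: float, u: float, I: float, p: IzhikevichParams = IzhikevichParams()
) -> tuple[float, float]:
    """Right-hand side of the resonator ODE (no reset applied)."""
    if not (math.isfinite(v) and math.isfinite(u) and math.isfinite(I)):
        raise ValueError("non-finite state or current")
    dv = (0.04 * v * v + 5.0 * v + 140.0 - u + I) / p.Cm
    du = p.a * (p.b * v - u)
    return dv, du


def izhikevich_fixed_points(
    p: IzhikevichParams, I: float
) -> list[tuple[float, float, str]]:
    """Real fixed points of the subthreshold flow with linear stability labels.

    Fixed points solve ``0.04 V^2 + (5 - b) V + 140 + I = 0`` with ``u = b V``.
    Stability follows from the 2x2 Jacobian (trace ``0.08 V + 5 - a``,
    determinant ``a (b - (0.08 V + 5))``).  Returns an empty list when the
    discriminant is negative (no rest state; mean-driven firing).
    """
    disc = (5.0 - p.b) ** 2 - 4.0 * 0.04 * (140.0 + I)
    if disc < 0:
        return []
    out = []
    roots = (
        [(-(5.0 - p.b)) / (2 * 0.04)]
        if disc == 0
        else sorted(
            ((-(5.0 - p.b) - math.sqrt(disc)) / 0.08, (-(5.0 - p.b) + math.sqrt(disc)) / 0.08)
        )
    )
    for v in roots:
        tr = 0.08 * v + 5.0 - p.a
        det = p.a * (p.b - (0.08 * v + 5.0))
        if disc == 0:
            label = "degenerate"
        elif det < 0:
            label = "saddle"
        elif tr < 0:
            label = "stable"
        else:
            label = "unstable"
        out.append((v, p.b * v, label))
    return out


def find_hopf_current(p: IzhikevichParams = IzhikevichParams()) -> float:
    """Bias current of the Andronov--Hopf bifurcation, in closed form.

    The focus loses stability where the Jacobian trace vanishes,
    ``V* = (a - 5)/0.08``; the corresponding current follows from the
    fixed-point condition.  Raises if the determinant at V* is not positive
    (no Hopf for these parameters).
    """
    vstar = (p.a - 5.0) / 0.08
    det = p.a * (p.b - (0.08 * vstar + 5.0))
    if det <= 0:
        raise ValueError("no Hopf bifurcation: determinant non-positive at trace-zero voltage")
    return -(0.04 * vstar * vstar + 5.0 * vstar + 140.0 - p.b * vstar)


def _spiking_initial_state(p: IzhikevichParams) -> tuple[float, float]:
    """A post-reset spiking initial condition, (c, b*c).

    Starting at the reset potential with the recovery variable on its
    nullcline lies in the basin of the stable spiking orbit all the way down
    to the saddle-node of periodics (checked against an adaptive-step
    event-integrator oracle in the tests), which makes the persistence
    bisection insensitive to the phase at which a prerun is truncated.
    """
    return p.c, p.b * p.c


def find_snp_current(
    p: IzhikevichParams = IzhikevichParams(),
    *,
    tol: float = 1e-4,
    dt: float = 0.01,
    t_transient: float = 500.0,
    t_window: float = 2000.0,
    min_spikes: int = 20,
    bracket: tuple[float, float] = (0.05, 0.26),
) -> float:
    """Saddle-node-of-periodics current by bisection on firing persistence.

    Starting from a spiking initial condition, the SNP is the smallest bias
    current for which repetitive firing persists (>= ``min_spikes`` spikes in
    ``t_window`` ms after a ``t_transient`` ms transient).
    """
    v0, u0 = _spiking_initial_state(p)
    n_steps = int(round((t_transient + t_window) / dt))

    def persists(I: float) -> bool:
        times, _, _ = izh_spike_times_from_state(
            v0, u0, I, p.a, p.b, p.c, p.d, p.Cm, p.vpeak, dt, n_steps
        )
        return int(np.sum(times >= t_transient)) >= min_spikes

    lo, hi = bracket
    if persists(lo) or not persists(hi):
        raise ValueError("bracket failure: endpoints do not straddle the SNP")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if persists(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _rate_from_spikes(times: np.ndarray, t_transient: float, t_window: float) -> float:
    n = int(np.sum(times >= t_transient))
    return n / (t_window / 1000.0)


def fi_curve(
    p: IzhikevichParams,
    I_grid: np.ndarray,
    direction: Literal["up", "down"] = "up",
    *,
    dt: float = 0.01,
    t_transient: float = 500.0,
    t_window: float = 2000.0,
) -> list[tuple[float, float]]:
    """f--I curve by continuation: the final state is carried between grid points.

    The up-sweep starts from rest and exposes the AH onset; the down-sweep
    starts from a spiking state and rides the stable limit cycle down to the
    SNP, exposing the hysteresis loop and the minimum sustained rate.
    Returns ``(I, rate_hz)`` pairs in sweep order.
    """
    I_grid = np.asarray(I_grid, dtype=float)
    if np.any(np.diff(I_grid) <= 0):
        raise ValueError("I grid must be strictly increasing")
    if direction == "up":
        grid = I_grid
        fp = izhikevich_fixed_points(p, grid[0])
        stable = [x for x in fp if x[2] == "stable"]
        v, u = (stable[0][0], stable[0][1]) if stable else (p.c, p.b * p.c)
    elif direction == "down":
        grid = I_grid[::-1]
        v, u = _spiking_initial_state(p)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    n_steps = int(round((t_transient + t_window) / dt))
    out = []
    for I in grid:
        times, v, u = izh_spike_times_from_state(
            v, u, float(I), p.a, p.b, p.c, p.d, p.Cm, p.vpeak, dt, n_steps
        )
        out.append((float(I), _rate_from_spikes(times, t_transient, t_window)))
    return out


def bifurcation_summary(
    p: IzhikevichParams = IzhikevichParams(),
    *,
    dt: float = 0.01,
    grid_step: float = 2e-3,
) -> BifurcationSummary:
    """AH current (closed form), SNP current (bisection) and the minimum
    sustained rate on the falling branch of the f--I hysteresis loop."""
    i_ah = find_hopf_current(p)
    i_snp = find_snp_current(p, dt=dt)
    grid = np.arange(i_snp + grid_step / 2, i_ah + 5 * grid_step, grid_step)
    down = fi_curve(p, grid, "down", dt=dt)
    sustained = [(I, r) for I, r in down if r > 0]
    f_min = min(r for _, r in sustained)
    return BifurcationSummary(I_AH=i_ah, I_SNP=i_snp, f_min=f_min)


# ---------------------------------------------------------------------------
# Via PV+ fast-spiking model
# ---------------------------------------------------------------------------

def gating_rates(name: str, V: float, p: ViaParams = ViaParams()) -> tuple[float, float]:
    """Opening/closing rates (alpha, beta) in 1/ms for gating variable ``name``.

    The removable singularity of alpha at V = theta is evaluated by its limit
    ``k1 * sigma1`` (series expansion of x/(exp(x/sigma)-1)).
    """
    if name not in GATING_NAMES:
        raise ValueError(f"unknown gating variable {name!r}")
    g = p.gating[name]
    x = g.theta - V
    if abs(x) < 1e-8:
        alpha = g.k1 * (g.sigma1 - 0.5 * x)
    else:
        alpha = g.k1 * x / (math.expm1(x / g.sigma1))
    beta = g.k2 * math.exp(V / g.sigma2)
    return alpha, beta


def gating_steady_state(V: float, p: ViaParams = ViaParams()) -> dict[str, float]:
    """Steady-state gating values at clamped voltage V.

    For activation gates (m, n, a) x_inf = alpha/(alpha+beta); for the
    inactivation gate h the opening rate is |alpha| (see ``via_deriv``), so
    h_inf = |alpha|/(|alpha|+beta) — near 1 at rest, near 0 at spike peak.
    """
    out = {}
    for name in GATING_NAMES:
        al, be = gating_rates(name, V, p)
        if name == "h":
            al = abs(al)
        out[name] = al / (al + be)
    return out


def via_deriv(
    state: tuple[float, float, float, float, float],
    I: float,
    p: ViaParams = ViaParams(),
) -> tuple[float, float, float, float, float]:
    """Right-hand side of the PV+ model: (dV, dm, dh, dn, da) with I in pA.

    Membrane currents use the (E - V) driving-force convention:
    INa = gNa m^3 h (ENa - V), IKv7 = gKv7 a^4 (EK - V),
    IKv3 = gKv3 n^4 (EK - V), IL = gL (EL - V).

    Activation gates follow dx/dt = alpha (1-x) - beta x.  The h gate's
    k1-form rate is negative for every V (sigma1 < 0); its magnitude, which
    decays with depolarization, is the de-inactivation rate, and the k2-form
    rate closes the gate: dh/dt = |alpha| (1-h) - beta h.  This is the only
    role assignment under which h rests near 1 and inactivates during the
    spike; any other pins h at a boundary and abolishes repetitive firing.
    """
    V, m, h, n, a = state
    INa = p.gNa * m**3 * h * (p.ENa - V)
    IKv7 = p.gKv7 * a**4 * (p.EK - V)
    IKv3 = p.gKv3 * n**4 * (p.EK - V)
    IL = p.gL * (p.EL - V)
    dV = (INa + IKv7 + IKv3 + IL + I) / p.Cm
    rates = {x: gating_rates(x, V, p) for x in GATING_NAMES}
    dm = rates["m"][0] * (1 - m) - rates["m"][1] * m
    dh = abs(rates["h"][0]) * (1 - h) - rates["h"][1] * h
    dn = rates["n"][0] * (1 - n) - rates["n"][1] * n
    da = rates["a"][0] * (1 - a) - rates["a"][1] * a
    return dV, dm, dh, dn, da


def via_resting_potential(p: ViaParams = ViaParams(), I: float = 0.0) -> float:
    """Resting membrane potential: root of dV/dt with gating at steady state."""
    from scipy.optimize import brentq

    def f(V: float) -> float:
        g = gating_steady_state(V, p)
        return via_deriv((V, g["m"], g["h"], g["n"], g["a"]), I, p)[0]

    # upper bracket stays below the Na activation range, where dV/dt turns
    # positive again
    return brentq(f, -95.0, -60.0, xtol=1e-10)


def simulate_single(
    model: Literal["izhikevich", "via"],
    I: float,
    *,
    t_total: float = 1000.0,
    dt: float = 0.01,
    params: IzhikevichParams | ViaParams | None = None,
    v0: float | None = None,
) -> np.ndarray:
    """Deterministic single-neuron run; returns spike times (ms).

    Convenience wrapper used by the bifurcation analyses and by tests; the
    Izhikevich neuron starts at rest unless ``v0`` is given, the Via neuron at
    its resting potential with steady-state gating.  Via currents are in pA.
    """
    n_steps = int(round(t_total / dt))
    if model == "izhikevich":
        p = params or IzhikevichParams()
        if v0 is None:
            # rest = the stable fixed point when one exists (the reset
            # potential c lies in the spiking orbit's basin, not at rest)
            stable = [x for x in izhikevich_fixed_points(p, I) if x[2] == "stable"]
            v = stable[0][0] if stable else p.c
        else:
            v = v0
        times, _, _ = izh_spike_times_from_state(
            v, p.b * v, I, p.a, p.b, p.c, p.d, p.Cm, p.vpeak, dt, n_steps
        )
        return times
    elif model == "via":
        p = params or ViaParams()
        v = via_resting_potential(p) if v0 is None else v0
        g = gating_steady_state(v, p)
        theta, s1, s2, k1, k2 = p.gating_arrays()
        times = via_spike_times_from_state(
            v, g["m"], g["h"], g["n"], g["a"], I,
            p.Cm, p.gNa, p.gKv7, p.gKv3, p.gL, p.ENa, p.EK, p.EL,
            theta, s1, s2, k1, k2, dt, n_steps,
        )
        return times
    raise ValueError(f"unknown model {model!r}")
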