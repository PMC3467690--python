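"""Leaky integrate-and-fire neurons with alpha-function synapses.

The membrane potential follows

    tau_m dV/dt = -V + S_f,        if V >= theta: spike and reset V = 0

where the synaptic drive S_f is the output of a two-stage low-pass cascade
(the "alpha synapse": rise time tau_r, fall time tau_f) driven by the
weighted spike input I:

    tau_r dS_r/dt = -S_r + I
    tau_f dS_f/dt = -S_f + S_r

Spikes are binary ones lasting a single integration step dt, so a spike
through a synapse of weight w contributes I = w for exactly one step
(input area w*dt).  Each stage has unit DC gain.  Integration is forward
Euler with dt = 0.1 ms by default.

Because all synapses of a class share the same kinetics, the per-synapse
filters are aggregated per (neuron, channel group); by linearity this is
exactly equivalent to filtering each synapse separately and summing.  Three
channel groups exist: feed-forward excitation, lateral excitation, and
inhibition (which enters the membrane equation with a negative sign).

:func:`psp_closed_form` gives the exact continuous-time response of the
cascade to a single spike, used as an independent oracle for the Euler
integrator and for calibrating the static inhibitory-loop weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "NeuronState",
    "step",
    "psp_closed_form",
    "psp_peak",
    "weight_for_peak",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane parameters (times in ms)."""

    tau_m: float = 10.0
    theta: float = 1.0
    v_reset: float = 0.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.dt <= 0:
            raise ValueError("tau_m and dt must be positive")
        if self.dt > self.tau_m / 2:
            raise ValueError("dt must be small compared to tau_m")

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SynapseKinetics:
    """Alpha-synapse time constants (ms)."""

    tau_r: float = 1.0
    tau_f: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_r <= 0 or self.tau_f <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_r == self.tau_f:
            raise ValueError("tau_r and tau_f must differ")


@dataclass
class NeuronState:
    """State of a group of neurons with per-channel synaptic filters.

    ``s_r`` and ``s_f`` have shape (n_channels, n_neurons); channel signs
    determine how each channel enters the membrane equation (+1 excitatory,
    -1 inhibitory).
    """

    v: np.ndarray
    s_r: np.ndarray
    s_f: np.ndarray
    fired: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int, n_channels: int = 3) -> "NeuronState":
        return cls(
            v=np.zeros(n_neurons),
            s_r=np.zeros((n_channels, n_neurons)),
            s_f=np.zeros((n_channels, n_neurons)),
            fired=np.zeros(n_neurons, dtype=bool),
        )


def step(state: NeuronState, drive: np.ndarray, params: NeuronParams,
         kinetics: SynapseKinetics, channel_signs: np.ndarray | None = None) -> np.ndarray:
    """Advance the group by one Euler step.

    ``drive`` has shape (n_channels, n_neurons): the summed weighted binary
    spike input per channel for this step.  Order within the step: the
    incoming spikes drive S_r, the filters are integrated, then V, then the
    threshold is applied (spiking neurons are reset to ``v_reset``).
    Returns the boolean array of neurons that fired.
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ValueError("non-finite synaptic input")
    if channel_signs is None:
        channel_signs = np.ones(state.s_r.shape[0])
    dt = params.dt
    state.s_r += dt / kinetics.tau_r * (-state.s_r + drive)
    state.s_f += dt / kinetics.tau_f * (-state.s_f + state.s_r)
    total = channel_signs @ state.s_f
    state.v += dt / params.tau_m * (-state.v + total)
    fired = state.v >= params.theta
    state.v[fired] = params.v_reset
    state.fired = fired
    return fired


# ---------------------------------------------------------------------------
# analytic oracle


def _cascade_coefficients(taus: np.ndarray) -> np.ndarray:
    """Partial-fraction coefficients of the unit-DC-gain exponential cascade.

    The impulse response of prod_i 1/(1 + s tau_i) is
    h(t) = sum_i c_i exp(-t/tau_i) with c_i = tau_i^(n-2) / prod_{j!=i}(tau_i - tau_j).
    """
    taus = np.asarray(taus, dtype=float)
    n = taus.size
    if np.unique(taus).size != n:
        raise ValueError("cascade time constants must be pairwise distinct")
    c = np.empty(n)
    for i in range(n):
        others = np.delete(taus, i)
        c[i] = taus[i] ** (n - 2) / np.prod(taus[i] - others)
    return c


def psp_closed_form(t, w: float, kinetics: SynapseKinetics,
                    params: NeuronParams) -> np.ndarray:
    """Membrane response to one binary spike of weight ``w``.

    A binary spike is a rectangular input of height ``w`` lasting one step
    ``dt``, i.e. an impulse of area ``w*dt`` into the S_r stage (exact up to
    O(dt), the same order as the Euler integrator it serves as oracle for).
    Returns V(t) of the three-stage cascade S_r -> S_f -> V for t >= 0.
    """
    t = np.asarray(t, dtype=float)
    taus = np.array([kinetics.tau_r, kinetics.tau_f, params.tau_m])
    c = _cascade_coefficients(taus)
    h = np.where(t[..., None] >= 0, np.exp(-t[..., None] / taus), 0.0) @ c
    return w * params.dt * np.where(t >= 0, h, 0.0)


def psp_peak(kinetics: SynapseKinetics, params: NeuronParams) -> tuple[float, float]:
    """(peak time ms, peak amplitude per unit weight) of the single-spike PSP."""
    from scipy.optimize import minimize_scalar

    horizon = 6 * max(kinetics.tau_r, kinetics.tau_f, params.tau_m)
    res = minimize_scalar(lambda t: -psp_closed_form(np.array(t), 1.0, kinetics, params),
                          bounds=(0.0, horizon), method="bounded")
    return float(res.x), float(-res.fun)


def weight_for_peak(target: float, kinetics: SynapseKinetics, params: NeuronParams) -> float:
    """Synaptic weight whose single-spike PSP peaks at ``target`` potential.

    Used to set the static loop weights of the winner-takes-all circuit from
    a behavioral requirement (e.g. "one excitatory spike must drive the
    inhibitory neuron past threshold at its PSP peak").
    """
    _, peak = psp_peak(kinetics, params)
    return target / peak
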