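"""Additive exponential STDP, weight bounds, and lateral weight normalization.

A pre/post spike pair separated by tau = t_post - t_pre changes the synapse
by

    f(tau) = A_p * exp(-tau / tau_p)   if tau >= 0   (potentiation)
    f(tau) = A_d * exp( tau / tau_d)   if tau <  0   (depression)

with tau_p = tau_d = 20 ms.  Depression dominates in the integral
(|A_d| tau_d = 1.05 A_p tau_p), so uncorrelated Poisson pre/post activity
depresses a synapse on average; only inputs that repeatedly precede the
postsynaptic spike gain weight.

Two pairing schemes are supported (cf. the standard trace realizations):

* ``all_to_all`` — every pre/post pair contributes; realized online with
  exponentially decaying pre and post traces.
* ``nearest_neighbor`` — each postsynaptic spike pairs with the *single*
  presynaptic spike closest to it in time: the last pre spike at or before
  the post (potentiation), unless a pre spike arrives sooner after it
  (depression).  "After" candidates must arrive no later than the next
  postsynaptic spike, so every pairing is resolved by the following pre or
  post event.  Ties (equal distance, or a pre coincident with the post)
  potentiate.  One pairing per post spike keeps the depression/potentiation
  window-integral ratio at the designed 1.05 independent of input rates; a
  scheme that pairs every pre spike with the most recent post turns out to
  over-weight depression at Poisson input rates of tens of Hz (the mean gap
  to the last pre is shorter than the STDP window, the gap to the last post
  is not), which drains all weights and precludes learning.

Weights are hard-clipped to [0, W_max] per synapse class.  Lateral weights
are additionally normalized so that the total lateral excitation converging
on a neuron never exceeds W^L_max: whenever the incoming sum exceeds the
bound, the vector is rescaled proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "STDPParams",
    "WeightSet",
    "OnlineStdp",
    "stdp_window",
    "compute_wmax_ff",
    "compute_learning_rates",
    "pair_sum_oracle",
    "normalize_lateral",
    "init_weights",
]

Mode = Literal["nearest_neighbor", "all_to_all"]


@dataclass(frozen=True)
class STDPParams:
    """STDP window parameters (times in ms, amplitudes in weight units)."""

    a_p: float
    a_d: float
    tau_p: float = 20.0
    tau_d: float = 20.0
    mode: Mode = "nearest_neighbor"

    def __post_init__(self) -> None:
        if self.a_p < 0 or self.a_d > 0:
            raise ValueError("expect a_p >= 0 and a_d <= 0")
        if self.tau_p <= 0 or self.tau_d <= 0:
            raise ValueError("time constants must be positive")
        if self.mode not in ("nearest_neighbor", "all_to_all"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def with_(self, **kw) -> "STDPParams":
        return replace(self, **kw)


def stdp_window(tau, a_p: float, a_d: float, tau_p: float = 20.0,
                tau_d: float = 20.0) -> np.ndarray:
    """The pairwise update f(tau) for tau = t_post - t_pre (ms)."""
    tau = np.asarray(tau, dtype=float)
    return np.where(tau >= 0, a_p * np.exp(-tau / tau_p), a_d * np.exp(tau / tau_d))


def compute_wmax_ff(theta: float, tau_m: float, mean_rate_hz: float, dt: float,
                    a_const: float, n_input: int,
                    form: Literal["product", "additive"] = "product") -> float:
    """Maximum feed-forward weight W^P_max for Poisson afferents.

    The bound is built from the drive balance of the leaky integrator: with
    afferent rate ``<r>`` (spikes/ms) and binary spikes lasting one step
    ``dt``, the factor theta / (tau_m * <r> * dt) converts the firing
    threshold into per-spike weight units (halving dt halves the impact of
    each binary spike, hence the explicit dt).  The constant ``a_const``
    (A = 20 by default) modulates the overall synaptic strength, and the
    result is shared over the ``n_input`` afferents that carry the pattern:

        product form:   W^P_max = [theta / (tau_m * <r> * dt)] * A / n_input
        additive form:  W^P_max = [theta / (tau_m * <r> * dt) + A] / n_input

    The product form is the package default: it puts the trained network in
    the regime where pattern afferents saturated at W^P_max reliably drive
    their neuron past threshold while pruned random inputs cause only few
    occasional spikes, and it lets untrained networks fire noise-driven,
    which is what bootstraps learning.  The additive form (an alternative
    reading of the same bound) yields a ~9x smaller bound under which the
    network is silent; it is kept selectable for comparison.

    ``mean_rate_hz`` is the average afferent rate in Hz (64 in the default
    stimulus); all times are in ms.
    """
    rate_per_ms = mean_rate_hz * 1e-3
    if theta <= 0 or tau_m <= 0 or rate_per_ms <= 0 or dt <= 0 or n_input <= 0:
        raise ValueError("all arguments must be positive")
    base = theta / (tau_m * rate_per_ms * dt)
    if form == "product":
        return base * a_const / n_input
    if form == "additive":
        return (base + a_const) / n_input
    raise ValueError(f"unknown form {form!r}")


def compute_learning_rates(w_max: float, tau_p: float = 20.0, tau_d: float = 20.0,
                           depression_bias: float = 1.05,
                           rate_per_pair: float = 0.002) -> tuple[float, float]:
    """Learning rates tied to the weight bound of the synapse class.

    A_p = rate_per_pair * W_max; A_d = -A_p * (tau_p / tau_d) * depression_bias,
    so depression outweighs potentiation in the window integral by the bias
    factor.  The bias must exceed the *causal* potentiation excess of the
    closed loop (spikes are caused by their immediately preceding inputs, so
    pre-before-post pairs are over-represented even for pure noise); only
    then do noise-driven synapses depress and unselective neurons fall
    silent instead of parking at threshold.
    """
    if w_max <= 0:
        raise ValueError("w_max must be positive")
    a_p = rate_per_pair * w_max
    a_d = -a_p * (tau_p / tau_d) * depression_bias
    return a_p, a_d


# ---------------------------------------------------------------------------
# online trace implementation (single synapse; the simulation kernel
# replicates this logic vectorized over synapse populations)


class OnlineStdp:
    """Event-driven STDP bookkeeping for one synapse.

    Call :meth:`on_pre` / :meth:`on_post` with non-decreasing times; each
    returns the weight change applied at that event.  A pre and post spike
    at the same time count as a tau = 0 pair (potentiation branch): process
    the pre event before the post event.

    In nearest-neighbor mode a post spike's pairing cannot be decided until
    it is known whether a closer pre spike follows, so its weight change is
    returned by the event that resolves it (the next pre or post spike);
    call :meth:`flush` at the end of the train to resolve a final pending
    post.  The simulation kernel uses the identical bookkeeping.
    """

    def __init__(self, params: STDPParams):
        self.p = params
        self.pre_trace = 0.0
        self.post_trace = 0.0
        self.t_last_pre = -np.inf
        self.t_last_post = -np.inf
        self._pending_post = None   # (t_post, gap_before) awaiting resolution

    def _window(self, gap: float, potentiate: bool) -> float:
        p = self.p
        if potentiate:
            return p.a_p * np.exp(-gap / p.tau_p) if np.isfinite(gap) else 0.0
        return p.a_d * np.exp(-gap / p.tau_d)

    def on_pre(self, t: float) -> float:
        p = self.p
        dw = 0.0
        if p.mode == "all_to_all":
            if np.isfinite(self.t_last_post):
                dw = p.a_d * self.post_trace * np.exp(-(t - self.t_last_post) / p.tau_d)
            if np.isfinite(self.t_last_pre):
                self.pre_trace *= np.exp(-(t - self.t_last_pre) / p.tau_p)
            self.pre_trace += 1.0
        else:
            if self._pending_post is not None:
                t_post, gap_b = self._pending_post
                gap_a = t - t_post
                dw = self._window(gap_a, False) if gap_a < gap_b else self._window(gap_b, True)
                self._pending_post = None
        self.t_last_pre = t
        return dw

    def on_post(self, t: float) -> float:
        p = self.p
        dw = 0.0
        if p.mode == "all_to_all":
            if np.isfinite(self.t_last_pre):
                dw = p.a_p * self.pre_trace * np.exp(-(t - self.t_last_pre) / p.tau_p)
            if np.isfinite(self.t_last_post):
                self.post_trace *= np.exp(-(t - self.t_last_post) / p.tau_d)
            self.post_trace += 1.0
        else:
            if self._pending_post is not None:
                # no pre since the previous post: its closest pre is behind it
                _, gap_b = self._pending_post
                dw = self._window(gap_b, True)
            self._pending_post = (t, t - self.t_last_pre)
        self.t_last_post = t
        return dw

    def flush(self) -> float:
        """Resolve a pending nearest-neighbor pairing at the end of a train."""
        if self.p.mode != "all_to_all" and self._pending_post is not None:
            _, gap_b = self._pending_post
            self._pending_post = None
            return self._window(gap_b, True)
        return 0.0


def pair_sum_oracle(pre_times, post_times, params: STDPParams) -> float:
    """Brute-force total weight change over explicit spike lists.

    Independent of the trace/pending bookkeeping: enumerates spike pairs
    directly.  In ``all_to_all`` mode every (pre, post) pair contributes
    (pre at or before post potentiates, pre after post depresses).  In
    ``nearest_neighbor`` mode each post spike pairs with the single closest
    pre spike: the last pre at or before it, or the first pre after it if
    strictly closer and arriving no later than the next post spike.
    """
    p = params
    pre = np.sort(np.asarray(pre_times, dtype=float))
    post = np.sort(np.asarray(post_times, dtype=float))
    total = 0.0
    if p.mode == "all_to_all":
        for tp in post:
            earlier = pre[pre <= tp]
            total += p.a_p * np.sum(np.exp(-(tp - earlier) / p.tau_p))
        for tq in pre:
            earlier = post[post < tq]
            total += p.a_d * np.sum(np.exp(-(tq - earlier) / p.tau_d))
        return float(total)
    for i, tp in enumerate(post):
        before = pre[pre <= tp]
        gap_b = tp - before[-1] if before.size else np.inf
        t_next = post[i + 1] if i + 1 < post.size else np.inf
        after = pre[(pre > tp) & (pre <= t_next)]
        gap_a = after[0] - tp if after.size else np.inf
        if gap_a < gap_b:
            total += p.a_d * np.exp(-gap_a / p.tau_d)
        elif np.isfinite(gap_b):
            total += p.a_p * np.exp(-gap_b / p.tau_p)
    return float(total)


# ---------------------------------------------------------------------------
# weights


@dataclass
class WeightSet:
    """Feed-forward and lateral weight matrices with their bounds.

    ``w_ff[a, n]`` connects afferent ``a`` to excitatory neuron ``n``;
    ``w_lat[m, n]`` connects excitatory neuron ``m`` to ``n`` (diagonal
    fixed at zero).
    """

    w_ff: np.ndarray
    w_lat: np.ndarray
    w_ff_max: float
    w_lat_max: float

    def copy(self) -> "WeightSet":
        return WeightSet(self.w_ff.copy(), self.w_lat.copy(), self.w_ff_max, self.w_lat_max)

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.w_ff < -atol) or np.any(self.w_ff > self.w_ff_max + atol):
            raise ValueError("feed-forward weights out of [0, W^P_max]")
        if np.any(self.w_lat < -atol) or np.any(self.w_lat > self.w_lat_max + atol):
            raise ValueError("lateral weights out of [0, W^L_max]")
        if np.any(np.abs(np.diag(self.w_lat)) > 0):
            raise ValueError("lateral diagonal must stay zero")
        if np.any(self.w_lat.sum(axis=0) > self.w_lat_max * (1 + 1e-9) + atol):
            raise ValueError("incoming lateral sums exceed W^L_max")

    def incoming_lateral_sums(self) -> np.ndarray:
        return self.w_lat.sum(axis=0)

    def to_csv(self, ff_path, lat_path, threshold: float = 0.0) -> None:
        """Long-format CSV export: (afferent_id|src_id, neuron_id, weight),
        keeping entries above ``threshold``."""
        import pandas as pd

        a, n = np.nonzero(self.w_ff > threshold)
        pd.DataFrame({"afferent_id": a, "neuron_id": n,
                      "weight": self.w_ff[a, n]}).to_csv(ff_path, index=False)
        s, d = np.nonzero(self.w_lat > threshold)
        pd.DataFrame({"src_id": s, "neuron_id": d,
                      "weight": self.w_lat[s, d]}).to_csv(lat_path, index=False)

    @classmethod
    def from_csv(cls, ff_path, lat_path, n_afferents: int, n_excitatory: int,
                 w_ff_max: float, w_lat_max: float) -> "WeightSet":
        import pandas as pd

        w_ff = np.zeros((n_afferents, n_excitatory))
        df = pd.read_csv(ff_path)
        w_ff[df.afferent_id, df.neuron_id] = df.weight
        w_lat = np.zeros((n_excitatory, n_excitatory))
        dl = pd.read_csv(lat_path)
        w_lat[dl.src_id, dl.neuron_id] = dl.weight
        return cls(w_ff, w_lat, w_ff_max, w_lat_max)


def normalize_lateral(w_incoming: np.ndarray, w_lat_max: float) -> np.ndarray:
    """Rescale an incoming lateral weight vector to sum at most W^L_max.

    If the sum exceeds the bound the vector is scaled proportionally (ratios
    preserved, zeros stay zero); otherwise it is returned unchanged.
    """
    w = np.asarray(w_incoming, dtype=float)
    if np.any(w < 0):
        raise ValueError("lateral weights must be non-negative")
    s = w.sum()
    if s > w_lat_max:
        return w * (w_lat_max / s)
    return w.copy()


def init_weights(rng: np.random.Generator, n_afferents: int, n_excitatory: int,
                 w_ff_max: float, w_lat_max: float) -> WeightSet:
    """Independent uniform initial weights.

    Feed-forward weights are uniform on (0, W^P_max]; lateral weights are
    uniform on (0, W^L_max / N] with a zero diagonal, so every initial
    incoming lateral sum is strictly below the bound.
    """
    if w_ff_max <= 0 or w_lat_max <= 0:
        raise ValueError("weight bounds must be positive")
    w_ff = (1.0 - rng.random((n_afferents, n_excitatory))) * w_ff_max
    w_lat = (1.0 - rng.random((n_excitatory, n_excitatory))) * (w_lat_max / n_excitatory)
    np.fill_diagonal(w_lat, 0.0)
    return WeightSet(w_ff, w_lat, w_ff_max, w_lat_max)
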