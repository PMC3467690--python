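"""Network-level protocols: training, testing, multi-pattern and speed variants.

The network is N (default 20) excitatory LIF neurons, all-to-all laterally
connected with plastic synapses, plus one inhibitory neuron wired to and
from every excitatory cell with static weights.  Any excitatory spike
drives the inhibitory neuron past threshold; its spike transiently
hyperpolarizes the whole excitatory population — a soft winner-takes-all
that enforces sparse, one-at-a-time responses.

Training presents the frozen-pattern stimulus for a fixed duration
(default 200 s) with STDP active on the feed-forward and lateral synapses
throughout.  Testing presents the stored pattern a number of times in
fresh carrier noise, by default with plasticity frozen, optionally with
the lateral synapses severed (the recurrent-input control used to decide
whether a *sequence* — and not merely the pattern — has been learnt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np

from ._kernel import simulate, ERR_OK, ERR_NONFINITE, ERR_OVERFLOW
from .dynamics import NeuronParams, SynapseKinetics, weight_for_peak
from .plasticity import (STDPParams, WeightSet, compute_learning_rates,
                         compute_wmax_ff, init_weights)
from .stimulus import (FrozenPattern, PresentationSchedule, StimulusConfig,
                       generate_pattern)

__all__ = [
    "NetworkConfig",
    "SimulationRecord",
    "TestResult",
    "run_training",
    "run_test",
    "run_multi_pattern_training",
    "run_concatenation_training",
    "run_speed_variation_test",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of a network experiment.

    The static winner-takes-all loop weights and the feed-forward weight
    bound are derived quantities unless overridden: ``w_ei`` is set so that
    a single excitatory spike drives the inhibitory neuron to
    ``w_ei_peak_factor * theta`` at the peak of its PSP (the peak factor
    also controls how fast the loop responds), and each inhibitory spike
    hyperpolarizes every excitatory membrane instantaneously by
    ``w_ie_kick_factor * theta`` (recovery over tau_m gives the few-ms
    suppression of the winner-takes-all competition).
    """

    n_excitatory: int = 20
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    stdp_mode: str = "nearest_neighbor"
    tau_p: float = 20.0
    tau_d: float = 20.0
    w_lat_max: float = 50.0
    a_const: float = 20.0
    wmax_form: str = "product"
    ff_rate_scale: float = 5.0
    lateral_rate_scale: float = 20.0
    depression_bias: float = 1.4
    w_ff_max: float | None = 0.45
    w_ei: float | None = None
    w_ie: float | None = None
    w_ei_peak_factor: float = 1.5
    w_ie_kick_factor: float = 0.6
    train_duration: float = 200_000.0
    snapshot_interval: float = 1000.0
    checkpoint_interval: float = 5000.0
    shared_noise: bool = False
    response_margin: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_excitatory < 2:
            raise ValueError("need at least 2 excitatory neurons")
        if self.neuron.dt != self.stimulus.dt:
            raise ValueError("neuron.dt and stimulus.dt must agree")
        if self.train_duration < 0:
            raise ValueError("train_duration must be non-negative")

    # ---- derived parameters

    @property
    def dt(self) -> float:
        return self.neuron.dt

    def ff_bound(self) -> float:
        if self.w_ff_max is not None:
            return self.w_ff_max
        return compute_wmax_ff(self.neuron.theta, self.neuron.tau_m,
                               self.stimulus.mean_rate, self.dt,
                               self.a_const, self.stimulus.n_pattern_afferents,
                               form=self.wmax_form)

    def loop_weights(self) -> tuple[float, float]:
        """(w_ei, w_ie): excitatory->inhibitory synaptic weight and the
        per-inhibitory-spike membrane kick on excitatory neurons."""
        w_unit = weight_for_peak(self.neuron.theta, self.kinetics, self.neuron)
        w_ei = self.w_ei if self.w_ei is not None else self.w_ei_peak_factor * w_unit
        w_ie = self.w_ie if self.w_ie is not None else self.w_ie_kick_factor * self.neuron.theta
        return w_ei, w_ie

    def stdp_ff(self) -> STDPParams:
        a_p, a_d = compute_learning_rates(self.ff_bound(), self.tau_p, self.tau_d,
                                          self.depression_bias)
        s = self.ff_rate_scale
        return STDPParams(a_p * s, a_d * s, self.tau_p, self.tau_d, self.stdp_mode)

    def stdp_lat(self) -> STDPParams:
        a_p, a_d = compute_learning_rates(self.w_lat_max, self.tau_p, self.tau_d,
                                          self.depression_bias)
        s = self.lateral_rate_scale
        return STDPParams(a_p * s, a_d * s, self.tau_p, self.tau_d, self.stdp_mode)

    def with_(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)

    def scaled_down(self) -> "NetworkConfig":
        """Preset for quick runs: 500 afferents (250 pattern), 50 s training.

        The feed-forward bound is rescaled inversely with the number of
        pattern afferents so the summed segment drive stays comparable.
        """
        factor = self.stimulus.n_pattern_afferents / 250
        return self.with_(
            stimulus=self.stimulus.with_(n_afferents_total=500, n_pattern_afferents=250),
            train_duration=50_000.0,
            w_ff_max=self.ff_bound() * factor,
        )


def _sub_seed(*parts: int) -> int:
    """Derive an independent 31-bit kernel seed from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def _rng(*parts: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(parts)))


_NEVER = np.int64(-(1 << 60))


@dataclass
class _Traces:
    tr_pre: np.ndarray
    tl_pre: np.ndarray
    res_ff: np.ndarray
    tr_post_p: np.ndarray
    tr_post_d: np.ndarray
    tl_post: np.ndarray
    res_lat: np.ndarray

    @classmethod
    def zeros(cls, n_aff: int, n_exc: int) -> "_Traces":
        return cls(np.zeros((n_aff, n_exc)),
                   np.full((n_aff, n_exc), _NEVER, dtype=np.int64),
                   np.full((n_aff, n_exc), _NEVER, dtype=np.int64),
                   np.zeros(n_exc), np.zeros(n_exc),
                   np.full(n_exc, _NEVER, dtype=np.int64),
                   np.full((n_exc, n_exc), _NEVER, dtype=np.int64))


@dataclass
class SimulationRecord:
    """Everything produced by one training run.

    ``spike_neurons``/``spike_steps`` hold the output raster (excitatory ids
    ``0..N-1``; the inhibitory neuron is id ``N``).  ``snapshots_lat`` and
    ``snapshots_ffsum`` sample the lateral matrix and per-neuron summed
    feed-forward weight once per ``snapshot_interval``; ``ck_ff``/``ck_lat``
    are full weight checkpoints used for time-resolved evaluation.
    """

    config: NetworkConfig
    patterns: list
    schedule: PresentationSchedule
    spike_neurons: np.ndarray
    spike_steps: np.ndarray
    weights: WeightSet
    snapshots_lat: np.ndarray
    snapshots_ffsum: np.ndarray
    snapshot_times_ms: np.ndarray
    ck_ff: np.ndarray
    ck_lat: np.ndarray
    ck_times_ms: np.ndarray
    duration: float
    seed: int

    @property
    def dt(self) -> float:
        return self.config.dt

    @property
    def n_excitatory(self) -> int:
        return self.config.n_excitatory

    def excitatory_spikes(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.spike_neurons < self.n_excitatory
        return self.spike_neurons[m], self.spike_steps[m] * self.dt

    def inhibitory_spike_times(self) -> np.ndarray:
        return self.spike_steps[self.spike_neurons == self.n_excitatory] * self.dt

    def output_rates(self) -> np.ndarray:
        """Mean rate (Hz) of each excitatory neuron over the whole run."""
        n, _ = self.excitatory_spikes()
        if self.duration == 0:
            return np.zeros(self.n_excitatory)
        return np.bincount(n, minlength=self.n_excitatory) / (self.duration * 1e-3)

    def weights_at(self, time_ms: float) -> WeightSet:
        """Weight checkpoint closest to (at or before) ``time_ms``."""
        if self.ck_times_ms.size == 0:
            return self.weights
        idx = int(np.searchsorted(self.ck_times_ms, time_ms + 1e-9) - 1)
        if idx < 0:
            raise ValueError(f"no checkpoint at or before {time_ms} ms")
        return WeightSet(self.ck_ff[idx].copy(), self.ck_lat[idx].copy(),
                         self.weights.w_ff_max, self.weights.w_lat_max)

    def per_second_summary(self):
        """Structured log: one row per snapshot interval with spike counts
        and weight-sum summaries (the raw material of convergence plots)."""
        import pandas as pd

        times = self.snapshot_times_ms
        n, t = self.excitatory_spikes()
        ti = self.inhibitory_spike_times()
        edges = np.concatenate(([0.0], times))
        return pd.DataFrame({
            "time_ms": times,
            "exc_spikes": np.histogram(t, bins=edges)[0],
            "inh_spikes": np.histogram(ti, bins=edges)[0],
            "lateral_sum": self.snapshots_lat.sum(axis=(1, 2)),
            "ff_sum": self.snapshots_ffsum.sum(axis=1),
        })

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        from .config import config_to_dict

        (d / "config.json").write_text(json.dumps(config_to_dict(self.config), indent=2))
        (d / "schedule.json").write_text(self.schedule.to_json())
        for i, p in enumerate(self.patterns):
            (d / f"pattern_{i}.json").write_text(p.to_json())
        np.savez_compressed(
            d / "arrays.npz",
            spike_neurons=self.spike_neurons, spike_steps=self.spike_steps,
            w_ff=self.weights.w_ff, w_lat=self.weights.w_lat,
            snapshots_lat=self.snapshots_lat, snapshots_ffsum=self.snapshots_ffsum,
            snapshot_times_ms=self.snapshot_times_ms,
            ck_ff=self.ck_ff, ck_lat=self.ck_lat, ck_times_ms=self.ck_times_ms,
        )
        meta = {"duration": self.duration, "seed": self.seed,
                "w_ff_max": self.weights.w_ff_max, "w_lat_max": self.weights.w_lat_max,
                "n_patterns": len(self.patterns)}
        (d / "meta.json").write_text(json.dumps(meta, indent=2))
        import pandas as pd

        n, t = self.excitatory_spikes()
        pd.DataFrame({"neuron": n, "time_ms": t}).to_csv(d / "output_spikes.csv", index=False)
        self.per_second_summary().to_csv(d / "per_second_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SimulationRecord":
        d = Path(directory)
        from .config import config_from_dict

        cfg = config_from_dict(json.loads((d / "config.json").read_text()))
        meta = json.loads((d / "meta.json").read_text())
        schedule = PresentationSchedule.from_json((d / "schedule.json").read_text())
        patterns = [FrozenPattern.from_json((d / f"pattern_{i}.json").read_text())
                    for i in range(meta["n_patterns"])]
        z = np.load(d / "arrays.npz")
        weights = WeightSet(z["w_ff"], z["w_lat"], meta["w_ff_max"], meta["w_lat_max"])
        return cls(cfg, patterns, schedule, z["spike_neurons"], z["spike_steps"], weights,
                   z["snapshots_lat"], z["snapshots_ffsum"], z["snapshot_times_ms"],
                   z["ck_ff"], z["ck_lat"], z["ck_times_ms"], meta["duration"], meta["seed"])


@dataclass
class TestResult:
    """Output of a test phase: spikes aligned to the presentation onsets.

    ``v_trace`` (optional) holds membrane potentials sampled every
    ``v_stride`` steps, one column per excitatory neuron plus the
    inhibitory neuron last.
    """

    config: NetworkConfig
    pattern: FrozenPattern
    onset_steps: np.ndarray
    spike_neurons: np.ndarray
    spike_steps: np.ndarray
    lateral_enabled: bool
    n_steps: int
    v_trace: np.ndarray | None = None
    v_stride: int = 0

    def membrane_to_csv(self, path) -> None:
        """Export the sampled membrane traces as (time_ms, neuron_id, v)."""
        if self.v_trace is None:
            raise ValueError("test was run without membrane recording")
        import pandas as pd

        n_rec, n_cols = self.v_trace.shape
        t = np.repeat(np.arange(n_rec) * self.v_stride * self.dt, n_cols)
        pd.DataFrame({"time_ms": t,
                      "neuron_id": np.tile(np.arange(n_cols), n_rec),
                      "v": self.v_trace.ravel()}).to_csv(path, index=False)

    @property
    def dt(self) -> float:
        return self.config.dt

    @property
    def n_excitatory(self) -> int:
        return self.config.n_excitatory

    @property
    def n_presentations(self) -> int:
        return int(self.onset_steps.size)

    @property
    def pattern_duration(self) -> float:
        return self.pattern.n_steps * self.dt

    def presentation_spikes(self, margin_ms: float | None = None):
        """Per presentation: (excitatory neuron ids, spike times in ms
        relative to onset) within [0, pattern_duration + margin)."""
        margin = self.config.response_margin if margin_ms is None else margin_ms
        win = self.pattern.n_steps + int(round(margin / self.dt))
        exc = self.spike_neurons < self.n_excitatory
        neurons = self.spike_neurons[exc]
        steps = self.spike_steps[exc]
        out = []
        for on in self.onset_steps:
            m = (steps >= on) & (steps < on + win)
            out.append((neurons[m].copy(), (steps[m] - on) * self.dt))
        return out


# ---------------------------------------------------------------------------
# protocol implementations


def _pattern_events(patterns, schedule: PresentationSchedule):
    """Absolute-step frozen-pattern spike events for the whole run."""
    steps, affs = [], []
    for on, pid in zip(schedule.onset_steps, schedule.pattern_ids):
        p = patterns[int(pid)]
        steps.append(p.steps + on)
        affs.append(p.afferents)
    if not steps:
        return np.empty(0, np.int64), np.empty(0, np.int32)
    return np.concatenate(steps), np.concatenate(affs).astype(np.int32)


def _run_kernel(cfg: NetworkConfig, patterns, schedule, weights: WeightSet,
                traces: _Traces, kernel_seed: int, n_steps: int, *,
                plastic: bool, lateral_enabled: bool,
                theta_override: float | None = None,
                snap_interval_steps: int = 0, ck_interval_steps: int = 0,
                v_stride: int = 0):
    st = cfg.stimulus
    dt = cfg.dt
    pat_step, pat_aff = _pattern_events(patterns, schedule)
    order = np.argsort(pat_step, kind="stable")
    pat_step, pat_aff = pat_step[order], pat_aff[order]
    in_pres = np.zeros(n_steps, dtype=np.uint8)
    for on in schedule.onset_steps:
        in_pres[on:on + schedule.pattern_steps] = 1

    p_full = (st.carrier_rate + st.background_rate) * 1e-3 * dt
    p_bg = st.background_rate * 1e-3 * dt

    ff = cfg.stdp_ff()
    lat = cfg.stdp_lat()
    w_ei, w_ie = cfg.loop_weights()
    theta = cfg.neuron.theta if theta_override is None else theta_override

    cap = int(n_steps * dt * 1e-3 * (cfg.n_excitatory + 1) * 400) + 100_000
    out_step = np.empty(cap, dtype=np.int64)
    out_neuron = np.empty(cap, dtype=np.int32)

    n_snap = n_steps // snap_interval_steps if snap_interval_steps else 0
    snap_lat = np.zeros((n_snap, cfg.n_excitatory, cfg.n_excitatory))
    snap_ffsum = np.zeros((n_snap, cfg.n_excitatory))
    n_ck = n_steps // ck_interval_steps if ck_interval_steps else 0
    ck_ff = np.zeros((n_ck, st.n_afferents_total, cfg.n_excitatory))
    ck_lat = np.zeros((n_ck, cfg.n_excitatory, cfg.n_excitatory))
    n_v = (n_steps + v_stride - 1) // v_stride if v_stride else 0
    v_trace = np.zeros((n_v, cfg.n_excitatory + 1), dtype=np.float32)

    n_out, err = simulate(
        kernel_seed, n_steps, dt,
        cfg.n_excitatory, st.n_afferents_total, st.n_pattern_afferents,
        in_pres, pat_step, pat_aff,
        p_full, p_bg, cfg.shared_noise,
        cfg.neuron.tau_m, theta, cfg.neuron.v_reset,
        cfg.kinetics.tau_r, cfg.kinetics.tau_f,
        weights.w_ff, weights.w_lat, w_ei, w_ie,
        weights.w_ff_max, weights.w_lat_max,
        plastic, lateral_enabled,
        ff.a_p, ff.a_d, lat.a_p, lat.a_d,
        cfg.tau_p, cfg.tau_d,
        cfg.stdp_mode == "all_to_all",
        traces.tr_pre, traces.tl_pre, traces.res_ff,
        traces.tr_post_p, traces.tr_post_d, traces.tl_post, traces.res_lat,
        out_step, out_neuron,
        snap_interval_steps, snap_lat, snap_ffsum,
        ck_interval_steps, ck_ff, ck_lat,
        v_stride, v_trace,
    )
    if err == ERR_NONFINITE:
        raise RuntimeError("numerical blow-up: non-finite membrane potential")
    if err == ERR_OVERFLOW:
        raise RuntimeError("spike buffer overflow: runaway firing "
                           f"({n_out} spikes in {n_steps * dt / 1000:.1f} s)")
    return (out_neuron[:n_out].copy(), out_step[:n_out].copy(),
            snap_lat, snap_ffsum, ck_ff, ck_lat, v_trace)


def run_training(cfg: NetworkConfig, *, patterns=None, schedule=None,
                 initial_weights: WeightSet | None = None,
                 duration: float | None = None,
                 seed_salt: int = 0) -> SimulationRecord:
    """Train a fresh network on the frozen-pattern stimulus.

    Identical seeds give identical records.  ``patterns``/``schedule``/
    ``initial_weights`` allow continuing or customizing a run (used by the
    multi-pattern and concatenation protocols).
    """
    duration = cfg.train_duration if duration is None else duration
    st = cfg.stimulus.with_(total_duration=duration)
    n_steps = st.n_steps

    if patterns is None:
        patterns = [generate_pattern(st, _rng(cfg.seed, 1, seed_salt))]
    if schedule is None and n_steps > 0:
        schedule = build_training_schedule(st, len(patterns), cfg.seed, seed_salt)
    elif schedule is None:
        schedule = PresentationSchedule(np.empty(0, np.int64), st.pattern_steps,
                                        max(n_steps, 1), st.dt)
    if initial_weights is None:
        initial_weights = init_weights(_rng(cfg.seed, 3, seed_salt),
                                       st.n_afferents_total, cfg.n_excitatory,
                                       cfg.ff_bound(), cfg.w_lat_max)
    weights = initial_weights.copy()
    traces = _Traces.zeros(st.n_afferents_total, cfg.n_excitatory)
    snap_steps = int(round(cfg.snapshot_interval / cfg.dt))
    ck_steps = int(round(cfg.checkpoint_interval / cfg.dt))

    if n_steps == 0:
        empty = np.empty(0)
        return SimulationRecord(
            cfg, patterns, schedule, np.empty(0, np.int32), np.empty(0, np.int64),
            weights, empty.reshape(0, cfg.n_excitatory, cfg.n_excitatory),
            empty.reshape(0, cfg.n_excitatory), np.empty(0),
            empty.reshape(0, st.n_afferents_total, cfg.n_excitatory),
            empty.reshape(0, cfg.n_excitatory, cfg.n_excitatory), np.empty(0),
            0.0, cfg.seed)

    kernel_seed = _sub_seed(cfg.seed, 4, seed_salt)
    (neurons, steps, snap_lat, snap_ffsum, ck_ff, ck_lat, _) = _run_kernel(
        cfg, patterns, schedule, weights, traces, kernel_seed, n_steps,
        plastic=True, lateral_enabled=True,
        snap_interval_steps=snap_steps, ck_interval_steps=ck_steps)

    snap_times = (np.arange(1, snap_lat.shape[0] + 1) * snap_steps) * cfg.dt
    ck_times = (np.arange(1, ck_ff.shape[0] + 1) * ck_steps) * cfg.dt
    weights.validate()
    return SimulationRecord(cfg, patterns, schedule, neurons, steps, weights,
                            snap_lat, snap_ffsum, snap_times, ck_ff, ck_lat,
                            ck_times, duration, cfg.seed)


def build_training_schedule(st: StimulusConfig, n_patterns: int,
                            seed: int, seed_salt: int = 0) -> PresentationSchedule:
    from .stimulus import build_schedule

    return build_schedule(st, _rng(seed, 2, seed_salt), n_patterns=n_patterns)


def _test_schedule(cfg: NetworkConfig, pattern: FrozenPattern, n_presentations: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    st = cfg.stimulus
    dt = cfg.dt
    onsets = []
    t = int(round(st.min_gap / dt)) + int(round(rng.exponential(st.mean_extra_gap) / dt))
    for _ in range(n_presentations):
        onsets.append(t)
        gap = st.min_gap + (rng.exponential(st.mean_extra_gap) if st.mean_extra_gap > 0 else 0.0)
        t += pattern.n_steps + int(round(gap / dt))
    tail = int(round((cfg.response_margin + 50.0) / dt))
    n_steps = onsets[-1] + pattern.n_steps + tail
    return np.asarray(onsets, dtype=np.int64), n_steps


def run_test(record: SimulationRecord, n_presentations: int = 10, *,
             plasticity_frozen: bool = True, lateral_enabled: bool = True,
             pattern: FrozenPattern | None = None, pattern_id: int = 0,
             theta_override: float | None = None,
             weights: WeightSet | None = None,
             seed: int | None = None,
             membrane_stride: int = 0) -> TestResult:
    """Present the stored frozen pattern repeatedly in fresh carrier noise.

    ``lateral_enabled=False`` severs the recurrent synapses at test time
    (weights untouched).  ``pattern`` substitutes a probe pattern (reversed,
    time-scaled, ...); ``weights`` substitutes a checkpoint.
    """
    cfg = record.config
    pat = record.patterns[pattern_id] if pattern is None else pattern
    w = (weights if weights is not None else record.weights).copy()
    if not lateral_enabled:
        w.w_lat = np.zeros_like(w.w_lat)
    seed = record.seed if seed is None else seed
    salt = 5 if lateral_enabled else 6
    rng = _rng(seed, 100 + salt, n_presentations, pat.n_steps)
    onset_steps, n_steps = _test_schedule(cfg, pat, n_presentations, rng)
    schedule = PresentationSchedule(onset_steps, pat.n_steps, n_steps, cfg.dt)
    traces = _Traces.zeros(cfg.stimulus.n_afferents_total, cfg.n_excitatory)
    kernel_seed = _sub_seed(seed, 200 + salt, n_presentations, pat.n_steps)
    neurons, steps, _, _, _, _, v_trace = _run_kernel(
        cfg, [pat], schedule, w, traces, kernel_seed, n_steps,
        plastic=not plasticity_frozen, lateral_enabled=lateral_enabled,
        theta_override=theta_override, v_stride=membrane_stride)
    return TestResult(cfg, pat, onset_steps, neurons, steps, lateral_enabled, n_steps,
                      v_trace if membrane_stride else None, membrane_stride)


def run_multi_pattern_training(cfg: NetworkConfig, n_patterns: int = 2) -> SimulationRecord:
    """Train on several distinct frozen patterns, randomly interleaved and
    never overlapping in time."""
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    st = cfg.stimulus.with_(total_duration=cfg.train_duration)
    patterns = [generate_pattern(st, _rng(cfg.seed, 1, i)) for i in range(n_patterns)]
    return run_training(cfg, patterns=patterns)


def run_concatenation_training(record: SimulationRecord, *,
                               duration: float = 100_000.0,
                               order: tuple[int, int] = (1, 0),
                               gap_between: float = 0.0,
                               seed_salt: int = 9) -> SimulationRecord:
    """Phase-2 training: repeatedly present two stored patterns back to back.

    Default order (1, 0) presents pattern two immediately followed by
    pattern one, so the tail of chain 2 and the head of chain 1 fall inside
    one STDP window and lateral plasticity can stitch the chains together.
    Starts from the trained weights of ``record``.
    """
    cfg = record.config.with_(train_duration=duration)
    if len(record.patterns) < 2:
        raise ValueError("concatenation needs a record trained on two patterns")
    if duration == 0:
        return run_training(cfg, patterns=record.patterns,
                            initial_weights=record.weights, duration=0.0,
                            seed_salt=seed_salt)
    st = cfg.stimulus.with_(total_duration=duration)
    dt = st.dt
    rng = _rng(cfg.seed, 7, seed_salt)
    pat_steps = record.patterns[0].n_steps
    gap_steps = int(round(gap_between / dt))
    onsets, ids = [], []
    t = int(round(st.min_gap / dt))
    while True:
        t += int(round(rng.exponential(st.mean_extra_gap) / dt)) if st.mean_extra_gap > 0 else 0
        end = t + 2 * pat_steps + gap_steps
        if end > st.n_steps:
            break
        onsets.extend([t, t + pat_steps + gap_steps])
        ids.extend(order)
        t = end + int(round(st.min_gap / dt))
    schedule = PresentationSchedule(np.asarray(onsets, np.int64), pat_steps,
                                    st.n_steps, dt, np.asarray(ids, np.int32))
    return run_training(cfg, patterns=record.patterns, schedule=schedule,
                        initial_weights=record.weights, duration=duration,
                        seed_salt=seed_salt)


def run_speed_variation_test(record: SimulationRecord, speed_factor: float, *,
                             theta_override: float | None = None,
                             n_presentations: int = 10,
                             pattern_id: int = 0, seed: int | None = None) -> dict:
    """Probe recognition of the trained pattern replayed at a different speed.

    The frozen pattern's spike times are scaled by 1/speed_factor
    (``speed_factor > 1`` means faster playback).  Recognition of a
    presentation requires every member of the learnt chain — established
    from an unscaled reference test — to fire, in particular the accepting
    (last) neuron.  Returns per-presentation outcomes and summary rates.
    """
    from .analysis import chain_members_and_order, compute_reliability

    baseline = run_test(record, n_presentations, pattern_id=pattern_id, seed=seed)
    base_rel = compute_reliability(baseline)
    members, order = chain_members_and_order(base_rel)
    if len(members) == 0:
        raise ValueError("no reliable chain in the reference test; train first")
    last = order[-1]

    probe_pat = record.patterns[pattern_id].time_scaled(speed_factor)
    probe = run_test(record, n_presentations, pattern=probe_pat,
                     theta_override=theta_override, seed=seed)
    recognized = []
    accepting_fired = []
    for neurons, _times in probe.presentation_spikes():
        fired = set(neurons.tolist())
        recognized.append(all(m in fired for m in members))
        accepting_fired.append(last in fired)
    return {
        "speed_factor": speed_factor,
        "theta": record.config.neuron.theta if theta_override is None else theta_override,
        "members": sorted(int(m) for m in members),
        "accepting_neuron": int(last),
        "recognized": recognized,
        "recognition_rate": float(np.mean(recognized)),
        "accepting_fire_rate": float(np.mean(accepting_fired)),
        "baseline_recognition_rate": float(np.mean([
            all(m in set(ns.tolist()) for m in members)
            for ns, _ in baseline.presentation_spikes()])),
    }
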