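"""Network protocols: determinism, bounds, kernel STDP vs reference bookkeeping."""

import numpy as np
import pytest

from synchain import NetworkConfig, run_test, run_training
from synchain.network import run_concatenation_training, run_multi_pattern_training
from synchain.plasticity import OnlineStdp


def test_zero_duration_run_returns_initial_state(tiny_net_cfg):
    rec = run_training(tiny_net_cfg.with_(train_duration=0.0))
    assert rec.spike_neurons.size == 0
    rec.weights.validate()
    assert rec.weights.w_ff.mean() == pytest.approx(tiny_net_cfg.ff_bound() / 2, rel=0.05)


def test_training_is_deterministic(tiny_net_cfg):
    a = run_training(tiny_net_cfg)
    b = run_training(tiny_net_cfg)
    assert np.array_equal(a.spike_steps, b.spike_steps)
    assert np.array_equal(a.spike_neurons, b.spike_neurons)
    assert np.array_equal(a.weights.w_ff, b.weights.w_ff)
    assert np.array_equal(a.weights.w_lat, b.weights.w_lat)


def test_different_seeds_differ(tiny_net_cfg):
    a = run_training(tiny_net_cfg)
    b = run_training(tiny_net_cfg.with_(seed=tiny_net_cfg.seed + 1))
    assert not np.array_equal(a.weights.w_ff, b.weights.w_ff)


def test_weight_bounds_preserved_through_training(mini_record):
    mini_record.weights.validate()
    # every checkpoint along the way respects the bounds too
    for k in range(mini_record.ck_ff.shape[0]):
        w = mini_record.weights_at(float(mini_record.ck_times_ms[k]))
        w.validate()


def test_excitatory_spikes_trigger_inhibitory_response(mini_record):
    """The WTA loop works: inhibitory spikes follow excitatory activity."""
    n, t = mini_record.excitatory_spikes()
    ti = mini_record.inhibitory_spike_times()
    assert t.size > 0 and ti.size > 0
    nxt = np.searchsorted(ti, t)
    ok = nxt < ti.size
    delay = ti[nxt[ok]] - t[ok]
    # large majority of excitatory spikes are followed by inhibition within 5 ms
    assert np.mean(delay <= 5.0) > 0.9


def test_test_phase_preserves_weights_and_pattern(mini_record):
    before = mini_record.weights.w_ff.copy()
    tr = run_test(mini_record, 5)
    assert np.array_equal(mini_record.weights.w_ff, before)
    assert tr.n_presentations == 5
    assert np.array_equal(tr.pattern.steps, mini_record.patterns[0].steps)
    # alignment windows lie inside the simulated span
    assert tr.onset_steps.max() + tr.pattern.n_steps < tr.n_steps


def test_run_test_deterministic_given_seed(mini_record):
    a = run_test(mini_record, 5, seed=99)
    b = run_test(mini_record, 5, seed=99)
    assert np.array_equal(a.spike_steps, b.spike_steps)


def test_severed_lateral_test_leaves_record_weights(mini_record):
    before = mini_record.weights.w_lat.copy()
    run_test(mini_record, 3, lateral_enabled=False)
    assert np.array_equal(mini_record.weights.w_lat, before)


def test_multi_pattern_schedule_never_overlaps(tiny_net_cfg):
    rec = run_multi_pattern_training(tiny_net_cfg.with_(train_duration=5_000.0), 2)
    assert len(rec.patterns) == 2
    assert set(rec.schedule.pattern_ids.tolist()) <= {0, 1}
    assert np.all(rec.schedule.gaps() >= 0)


def test_concatenation_zero_duration_is_identity(tiny_net_cfg):
    rec = run_multi_pattern_training(tiny_net_cfg.with_(train_duration=3_000.0), 2)
    rec2 = run_concatenation_training(rec, duration=0.0)
    assert np.array_equal(rec2.weights.w_lat, rec.weights.w_lat)
    assert np.array_equal(rec2.weights.w_ff, rec.weights.w_ff)


def test_concatenation_schedule_pairs_back_to_back(tiny_net_cfg):
    rec = run_multi_pattern_training(tiny_net_cfg.with_(train_duration=3_000.0), 2)
    rec2 = run_concatenation_training(rec, duration=5_000.0)
    ids = rec2.schedule.pattern_ids
    onsets = rec2.schedule.onset_steps
    assert ids.size >= 2 and ids.size % 2 == 0
    # pairs are (second pattern, first pattern) with no gap inside the pair
    pat_steps = rec2.schedule.pattern_steps
    assert np.all(ids[0::2] == 1) and np.all(ids[1::2] == 0)
    assert np.all(onsets[1::2] - onsets[0::2] == pat_steps)


def test_record_save_load_roundtrip(tmp_path, mini_record):
    mini_record.save(tmp_path / "rec")
    from synchain.network import SimulationRecord

    back = SimulationRecord.load(tmp_path / "rec")
    assert np.array_equal(back.spike_steps, mini_record.spike_steps)
    assert np.array_equal(back.weights.w_ff, mini_record.weights.w_ff)
    assert back.config == mini_record.config
    assert np.array_equal(back.patterns[0].steps, mini_record.patterns[0].steps)


# ---------------------------------------------------------------------------
# kernel STDP against the per-synapse reference bookkeeping


def _noiseless_setup(mode):
    """Silent-gap stimulus: pre-generated pattern, zero carrier/background, so
    every presynaptic spike is known to the test."""
    from synchain.plasticity import WeightSet
    from synchain.stimulus import StimulusConfig, generate_pattern

    gen_cfg = StimulusConfig(n_afferents_total=40, n_pattern_afferents=40,
                             pattern_duration=400.0, total_duration=4_000.0)
    pat = generate_pattern(gen_cfg, np.random.default_rng(33))
    base = NetworkConfig()
    cfg = base.with_(
        n_excitatory=3,
        stimulus=gen_cfg.with_(carrier_rate=0.0, background_rate=0.0),
        stdp_mode=mode,
        w_ff_max=10.0,
        w_lat_max=1e6,             # normalization never triggers
        lateral_rate_scale=5e-7,   # keep lateral amplitudes small
        ff_rate_scale=1.0,
        w_ie=0.3,
        train_duration=4_000.0,
        seed=21,
    )
    rng = np.random.default_rng(34)
    w_ff = rng.uniform(3.0, 8.0, (40, 3))
    w_lat = rng.uniform(0.0, 2.0, (3, 3))
    np.fill_diagonal(w_lat, 0.0)
    ws0 = WeightSet(w_ff, w_lat, cfg.ff_bound(), cfg.w_lat_max)
    rec = run_training(cfg, patterns=[pat], initial_weights=ws0)
    assert rec.excitatory_spikes()[0].size > 0, "dead network: test needs spikes"
    return cfg, rec, ws0


def _replay(events, params, dt):
    """Replay in integer step units (taus rescaled) so that equal-distance
    ties resolve exactly as in the compiled kernel."""
    p = params.with_(tau_p=params.tau_p / dt, tau_d=params.tau_d / dt)
    o = OnlineStdp(p)
    return sum(o.on_pre(t) if k == 0 else o.on_post(t) for t, k in events)


@pytest.mark.parametrize("mode", ["nearest_neighbor", "all_to_all"])
def test_kernel_ff_plasticity_matches_online_reference(mode):
    """Feed-forward weight changes in the compiled loop equal the event-driven
    reference applied to the recorded spike trains.

    Pending nearest-neighbor pairings left unresolved at the end of the run
    are likewise unresolved in the reference (no flush).
    """
    cfg, rec, ws0 = _noiseless_setup(mode)
    p = cfg.stdp_ff()
    pat = rec.patterns[0]
    pre_by_aff = {a: [] for a in range(40)}
    for on in rec.schedule.onset_steps:
        for s, a in zip(pat.steps, pat.afferents):
            pre_by_aff[int(a)].append(int(on) + int(s))
    n_spk, t_spk = rec.excitatory_spikes()
    for n in range(3):
        post = sorted((t_spk[n_spk == n] / cfg.dt).round().astype(int).tolist())
        for a in range(0, 40, 7):
            events = sorted([(t, 0) for t in pre_by_aff[a]] + [(t, 1) for t in post])
            delta = _replay(events, p, cfg.dt)
            want = np.clip(ws0.w_ff[a, n] + delta, 0.0, cfg.ff_bound())
            assert rec.weights.w_ff[a, n] == pytest.approx(want, abs=1e-9), (a, n)


def test_kernel_lateral_plasticity_matches_online_reference():
    cfg, rec, ws0 = _noiseless_setup("nearest_neighbor")
    p = cfg.stdp_lat()
    n_spk, t_spk = rec.excitatory_spikes()
    spikes = {n: sorted((t_spk[n_spk == n] / cfg.dt).round().astype(int).tolist())
              for n in range(3)}
    checked = 0
    for m in range(3):
        for n in range(3):
            if m == n or (set(spikes[m]) & set(spikes[n])):
                continue  # coincident spikes resolve in kernel index order
            events = sorted([(t, 0) for t in spikes[m]] + [(t, 1) for t in spikes[n]])
            delta = _replay(events, p, cfg.dt)
            want = max(ws0.w_lat[m, n] + delta, 0.0)
            assert rec.weights.w_lat[m, n] == pytest.approx(want, abs=1e-9), (m, n)
            checked += 1
    assert checked > 0


def test_weightset_csv_roundtrip(tmp_path, mini_record):
    ws = mini_record.weights
    ws.to_csv(tmp_path / "ff.csv", tmp_path / "lat.csv")
    from synchain.plasticity import WeightSet

    back = WeightSet.from_csv(tmp_path / "ff.csv", tmp_path / "lat.csv",
                              *ws.w_ff.shape, ws.w_ff_max, ws.w_lat_max)
    assert np.allclose(back.w_ff, ws.w_ff)
    assert np.allclose(back.w_lat, ws.w_lat)


def test_membrane_trace_recording(tmp_path, mini_record):
    tr = run_test(mini_record, 2, membrane_stride=10)
    assert tr.v_trace is not None
    assert tr.v_trace.shape[1] == mini_record.n_excitatory + 1
    assert np.isfinite(tr.v_trace).all()
    tr.membrane_to_csv(tmp_path / "v.csv")
    assert (tmp_path / "v.csv").stat().st_size > 0


def test_speed_variation_identity_at_unit_factor(mini_record):
    """Replaying the pattern at its trained speed reproduces the baseline
    recognition exactly (same noise realization under the same seed)."""
    from synchain.network import run_speed_variation_test

    out = run_speed_variation_test(mini_record, 1.0, seed=5)
    assert out["recognition_rate"] == out["baseline_recognition_rate"]
    assert out["accepting_neuron"] in out["members"]
    assert len(out["recognized"]) == 10
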