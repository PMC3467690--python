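"""Learning criteria and chain-graph extraction on constructed inputs."""

import networkx as nx
import numpy as np
import pytest

from synchain.analysis import (ReliabilityTable, assess_pattern_learnt,
                               assess_sequence_learnt, chain_members_and_order,
                               compute_reliability, detect_cycles,
                               edge_directness_vs_strength, extract_chain_graph)
from synchain.network import NetworkConfig
from synchain.network import TestResult as _Result
from synchain.stimulus import FrozenPattern


def _result(per_presentation, n_exc=6, pat_ms=50.0, dt=0.1):
    """Build a TestResult from explicit per-presentation spike lists."""
    base = NetworkConfig()
    cfg = base.with_(n_excitatory=n_exc)
    pat_steps = int(pat_ms / dt)
    onset_gap = pat_steps + 2000
    onsets, neurons, steps = [], [], []
    for i, spikes in enumerate(per_presentation):
        on = 1000 + i * onset_gap
        onsets.append(on)
        for nid, t in spikes:
            neurons.append(nid)
            steps.append(on + int(round(t / dt)))
    n_steps = onsets[-1] + onset_gap
    pattern = FrozenPattern(np.empty(0, np.int64), np.empty(0, np.int32),
                            pat_steps, cfg.stimulus.n_pattern_afferents, dt)
    order = np.argsort(steps, kind="stable")
    return _Result(cfg, pattern, np.asarray(onsets, np.int64),
                      np.asarray(neurons, np.int32)[order],
                      np.asarray(steps, np.int64)[order], True, n_steps)


def test_reliability_counts_presence_not_spike_count():
    pres = [[(0, 10.0), (0, 30.0), (1, 20.0)],   # neuron 0 spikes twice: counts once
            [(0, 11.0)],
            [(1, 22.0)],
            [(0, 9.0), (1, 21.0)]]
    tab = compute_reliability(_result(pres))
    assert tab.p_fire[0] == pytest.approx(0.75)
    assert tab.p_fire[1] == pytest.approx(0.75)
    assert tab.p_fire[2] == 0.0
    assert tab.latency_median[0] == pytest.approx(10.0)
    assert tab.latency_median[1] == pytest.approx(21.0)


def test_reliability_window_excludes_late_spikes():
    pres = [[(0, 69.9)], [(0, 71.0)]]   # window = 50 + 20 ms margin
    tab = compute_reliability(_result(pres))
    assert tab.p_fire[0] == pytest.approx(0.5)


def test_membership_threshold_is_inclusive_at_one_half():
    pres = [[(0, 10.0)] if i < 5 else [] for i in range(10)]
    pres = [p + ([(1, 20.0)] if i < 4 else []) for i, p in enumerate(pres)]
    tab = compute_reliability(_result(pres))
    members, learnt = assess_pattern_learnt(tab)
    assert learnt and members.tolist() == [0]      # 0.5 in, 0.4 out


def test_pattern_not_learnt_when_nothing_reliable():
    tab = compute_reliability(_result([[], [], [(2, 5.0)], []]))
    members, learnt = assess_pattern_learnt(tab)
    assert not learnt and members.size == 0


def _chain_tables(order_ok=True, off_extra=False):
    """on-test: neurons 0,1,2 fire at 10/25/40 ms; off-test: only neuron 0."""
    pres_on = []
    rotations = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    for i in range(10):
        if order_ok:
            rot = rotations[0]
        else:
            # rotate the firing order so no single order reaches 50%
            rot = rotations[0] if i < 4 else rotations[1] if i < 7 else rotations[2]
        trio = [(rot[0], 10.0), (rot[1], 25.0), (rot[2], 40.0)]
        pres_on.append(trio)
    on = compute_reliability(_result(pres_on))
    off_spikes = [[(0, 10.0)] + ([(1, 25.0)] if off_extra else []) for _ in range(10)]
    off = compute_reliability(_result(off_spikes))
    return on, off


def test_sequence_learnt_positive_case():
    on, off = _chain_tables()
    ok, canonical = assess_sequence_learnt(on, off)
    assert ok
    assert canonical.tolist() == [0, 1, 2]


def test_sequence_fails_if_second_neuron_survives_severing():
    on, off = _chain_tables(off_extra=True)
    ok, _ = assess_sequence_learnt(on, off)
    assert not ok


def test_sequence_fails_without_consistent_order():
    on, off = _chain_tables(order_ok=False)
    ok, _ = assess_sequence_learnt(on, off)
    assert not ok


def test_sequence_implies_pattern():
    """sequence_learnt => pattern_learnt for arbitrary random tables."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = 5
        p_on = rng.random(n)
        p_off = rng.random(n) * p_on
        lat = rng.uniform(5, 60, n)
        tab_on = ReliabilityTable(p_on, lat, lat * 0.1, lat, 10, [{}] * 10)
        tab_off = ReliabilityTable(p_off, lat, lat * 0.1, lat, 10, [{}] * 10)
        seq, _ = assess_sequence_learnt(tab_on, tab_off)
        pat = assess_pattern_learnt(tab_on)[1]
        assert (not seq) or pat


def test_extract_chain_graph_linear():
    w = np.zeros((5, 5))
    w[0, 1] = 30.0
    w[1, 2] = 25.0
    chain = extract_chain_graph(w, np.array([0, 1, 2]), w_lat_max=50.0)
    assert chain.start_nodes == [0]
    assert chain.accepting_nodes == [2]
    assert len(chain.edges) == 2
    assert chain.order_violations == []
    assert detect_cycles(chain) == []


def test_chain_graph_edge_threshold_filters_weak_edges():
    w = np.zeros((3, 3))
    w[0, 1] = 30.0
    w[1, 2] = 5.0     # below 0.2 * 50
    chain = extract_chain_graph(w, np.array([0, 1, 2]), w_lat_max=50.0)
    assert [(u, v) for u, v, _ in chain.edges] == [(0, 1)]
    # 2 has no incoming edge from an earlier member: also a start node
    assert set(chain.start_nodes) == {0, 2}


def test_detect_cycles_reports_loop():
    g = nx.DiGraph()
    g.add_weighted_edges_from([(0, 1, 20.0), (1, 2, 20.0), (2, 0, 20.0)])
    from synchain.analysis import ChainGraph

    chain = ChainGraph(g, np.array([0, 1, 2]), [0], [2], 10.0)
    cycles = detect_cycles(chain)
    assert len(cycles) == 1 and sorted(cycles[0]) == [0, 1, 2]


def test_edge_directness_statistic():
    w = np.zeros((4, 4))
    w[0, 1] = 10.0
    w[0, 2] = 4.0      # 1-step beats 2-step: respected
    w[1, 2] = 12.0
    chain = extract_chain_graph(w, np.array([0, 1, 2]), edge_threshold=1.0)
    out = edge_directness_vs_strength(chain)
    assert out["defined"] and out["fraction_respected"] == 1.0 and out["n_pairs"] == 1


def test_edge_directness_undefined_for_single_edge():
    w = np.zeros((3, 3))
    w[0, 1] = 20.0
    chain = extract_chain_graph(w, np.array([0, 1]), edge_threshold=1.0)
    assert not edge_directness_vs_strength(chain)["defined"]


def test_components_split_into_separate_chains():
    w = np.zeros((6, 6))
    w[0, 1] = 30.0
    w[3, 4] = 30.0
    chain = extract_chain_graph(w, np.array([0, 3, 1, 4]), w_lat_max=50.0)
    comps = chain.components()
    assert len(comps) == 2
    accepts = sorted(c.accepting_nodes[0] for c in comps if c.accepting_nodes)
    assert accepts == [1, 4]


def test_canonical_order_sorted_by_median_latency():
    pres = [[(2, 5.0), (0, 20.0), (1, 35.0)] for _ in range(6)]
    tab = compute_reliability(_result(pres))
    _, order = chain_members_and_order(tab)
    assert order.tolist() == [2, 0, 1]


def test_empty_test_result_rejected():
    with pytest.raises(ValueError):
        compute_reliability(_make_empty())


def _make_empty():
    base = NetworkConfig()
    pattern = FrozenPattern(np.empty(0, np.int64), np.empty(0, np.int32), 500, 1000, 0.1)
    return _Result(base, pattern, np.empty(0, np.int64), np.empty(0, np.int32),
                      np.empty(0, np.int64), True, 1000)
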