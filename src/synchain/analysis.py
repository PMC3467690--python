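"""Learning and recognition criteria, and chain-graph extraction.

Two graded notions of success are applied to a trained network:

* **Pattern learnt** — a fixed set of neurons responds reliably to segments
  of the frozen pattern: a neuron belongs to the chain if it fires in at
  least 50% of test presentations (inside the response window).
* **Sequence learnt** — the pattern is learnt, *and* with the lateral
  synapses severed at most the first neuron of the chain remains reliable
  (every later neuron needs the recurrent drive of its predecessors), *and*
  with lateral synapses intact the members fire in a fixed order.

A *sequence is recognized* in a single presentation when every member of
the learnt chain fires, in particular the last (accepting) neuron — the
finite-automaton accepting state signalling that the complete pattern was
seen.

The recognizer structure itself is read out of the trained lateral weight
matrix as a directed graph over the chain members: edges are lateral
synapses strengthened above a threshold (default 20% of W^L_max — the
trained lateral weights are strongly bimodal, so the exact cutoff hardly
matters), annotated with start and accepting nodes, and expected to respect
the temporal order of the canonical firing sequence and to be acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import networkx as nx
import numpy as np
import pandas as pd

from .network import NetworkConfig, SimulationRecord, TestResult, run_test, run_training

__all__ = [
    "ReliabilityTable",
    "ChainGraph",
    "EvaluationReport",
    "compute_reliability",
    "assess_pattern_learnt",
    "assess_sequence_learnt",
    "chain_members_and_order",
    "extract_chain_graph",
    "detect_cycles",
    "edge_directness_vs_strength",
    "evaluate_record",
    "time_to_sequence_learnt",
    "sweep_wlmax",
]

RELIABILITY_THRESHOLD = 0.5


@dataclass
class ReliabilityTable:
    """Per-neuron response statistics over repeated pattern presentations.

    ``p_fire`` is the fraction of presentations with at least one spike in
    the response window (multiple spikes count once); latencies are first
    spike times (ms) from pattern onset, over presentations with a response.
    """

    p_fire: np.ndarray
    latency_mean: np.ndarray
    latency_std: np.ndarray
    latency_median: np.ndarray
    n_presentations: int
    first_spikes: list  # per presentation: dict neuron -> first-spike latency (ms)

    def members(self, threshold: float = RELIABILITY_THRESHOLD) -> np.ndarray:
        return np.flatnonzero(self.p_fire >= threshold)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron": np.arange(self.p_fire.size),
            "p_fire": self.p_fire,
            "latency_mean_ms": self.latency_mean,
            "latency_std_ms": self.latency_std,
            "latency_median_ms": self.latency_median,
        })


def compute_reliability(test: TestResult, margin_ms: float | None = None) -> ReliabilityTable:
    """Firing probability and first-spike latency statistics per neuron."""
    pres = test.presentation_spikes(margin_ms)
    if len(pres) == 0:
        raise ValueError("no presentations in test result")
    n = test.n_excitatory
    count = np.zeros(n)
    lat: list[list[float]] = [[] for _ in range(n)]
    first_spikes = []
    for neurons, times in pres:
        d: dict[int, float] = {}
        for i in np.argsort(times, kind="stable"):
            nid = int(neurons[i])
            if nid not in d:
                d[nid] = float(times[i])
        first_spikes.append(d)
        for nid, t0 in d.items():
            count[nid] += 1
            lat[nid].append(t0)
    p_fire = count / len(pres)
    mean = np.full(n, np.nan)
    std = np.full(n, np.nan)
    med = np.full(n, np.nan)
    for i in range(n):
        if lat[i]:
            mean[i] = float(np.mean(lat[i]))
            std[i] = float(np.std(lat[i]))
            med[i] = float(np.median(lat[i]))
    return ReliabilityTable(p_fire, mean, std, med, len(pres), first_spikes)


def assess_pattern_learnt(table: ReliabilityTable,
                          threshold: float = RELIABILITY_THRESHOLD) -> tuple[np.ndarray, bool]:
    """Chain members (reliability >= 50%) and whether the pattern is learnt.

    The pattern counts as learnt if the member set is non-empty — a fixed
    set of neurons responding reliably to segments of the pattern.
    """
    members = table.members(threshold)
    return members, members.size > 0


def chain_members_and_order(table: ReliabilityTable,
                            threshold: float = RELIABILITY_THRESHOLD) -> tuple[np.ndarray, np.ndarray]:
    """Members plus the canonical firing order (sorted by median first-spike
    latency; ties broken by neuron id)."""
    members = table.members(threshold)
    order = members[np.lexsort((members, table.latency_median[members]))]
    return members, order


def _order_consistency(table: ReliabilityTable, canonical: np.ndarray) -> float:
    """Fraction of presentations whose firing order (restricted to members
    that fired) matches the canonical order."""
    rank = {int(n): i for i, n in enumerate(canonical)}
    ok = 0
    for d in table.first_spikes:
        fired = [(t, rank[n]) for n, t in d.items() if n in rank]
        fired.sort()
        ranks = [r for _, r in fired]
        ok += ranks == sorted(ranks)
    return ok / max(len(table.first_spikes), 1)


def assess_sequence_learnt(on_table: ReliabilityTable, off_table: ReliabilityTable,
                           threshold: float = RELIABILITY_THRESHOLD,
                           order_threshold: float = 0.5) -> tuple[bool, np.ndarray]:
    """Sequence-learnt criterion.

    True iff (a) the pattern is learnt with lateral synapses intact, (b) in
    the severed-lateral test at most the first canonical neuron stays
    reliable, and (c) members fire in the canonical order in at least
    ``order_threshold`` of the presentations.  Returns (learnt, canonical
    order).  Implies pattern-learnt by construction.
    """
    members, pattern_ok = assess_pattern_learnt(on_table, threshold)
    _, canonical = chain_members_and_order(on_table, threshold)
    if not pattern_ok:
        return False, canonical
    off_reliable = set(off_table.members(threshold).tolist())
    allowed = {int(canonical[0])}
    if not off_reliable <= allowed:
        return False, canonical
    if _order_consistency(on_table, canonical) < order_threshold:
        return False, canonical
    return True, canonical


@dataclass
class ChainGraph:
    """Directed graph of strengthened lateral synapses among chain members."""

    graph: nx.DiGraph
    canonical_order: np.ndarray
    start_nodes: list
    accepting_nodes: list
    edge_threshold: float
    order_violations: list = field(default_factory=list)

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def components(self) -> list:
        """Weakly connected components = separate chains, each a ChainGraph."""
        out = []
        for comp in nx.weakly_connected_components(self.graph):
            sub = self.graph.subgraph(comp).copy()
            canon = np.asarray([n for n in self.canonical_order if n in comp])
            out.append(_annotate(sub, canon, self.edge_threshold))
        return out

    def to_edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["src", "dst", "weight"])

    def to_dot(self) -> str:
        lines = ["digraph chain {"]
        for n in self.nodes:
            shape = "doublecircle" if n in self.accepting_nodes else "circle"
            lines.append(f'  {n} [shape={shape}];')
        for u, v, w in self.edges:
            lines.append(f'  {u} -> {v} [label="{w:.1f}"];')
        lines.append("}")
        return "\n".join(lines)


def _annotate(g: nx.DiGraph, canonical: np.ndarray, threshold: float) -> ChainGraph:
    pos = {int(n): i for i, n in enumerate(canonical)}
    violations = [(u, v) for u, v in g.edges if pos.get(u, -1) >= pos.get(v, -1)]
    start, accepting = [], []
    for n in g.nodes:
        succ_later = any(pos.get(m, -1) > pos.get(n, -1) for m in g.successors(n))
        pred_earlier = any(pos.get(m, 1 << 30) < pos.get(n, 1 << 30) for m in g.predecessors(n))
        if not succ_later:
            accepting.append(n)
        if not pred_earlier:
            start.append(n)
    return ChainGraph(g, canonical, sorted(start), sorted(accepting), threshold, violations)


def extract_chain_graph(w_lat: np.ndarray, canonical_order: np.ndarray,
                        edge_threshold: float | None = None,
                        w_lat_max: float = 50.0) -> ChainGraph:
    """Read the learnt recognizer out of the lateral weight matrix.

    Nodes are the chain members (canonical order); edges are lateral weights
    above ``edge_threshold`` (default 0.2 * W^L_max) between members.
    Accepting nodes have no outgoing edge to a later member; start nodes
    have no incoming edge from an earlier member.
    """
    thr = 0.2 * w_lat_max if edge_threshold is None else edge_threshold
    g = nx.DiGraph()
    members = [int(n) for n in canonical_order]
    g.add_nodes_from(members)
    for u in members:
        for v in members:
            if u != v and w_lat[u, v] > thr:
                g.add_edge(u, v, weight=float(w_lat[u, v]))
    return _annotate(g, np.asarray(members), thr)


def detect_cycles(chain: ChainGraph) -> list:
    """Directed cycles in the chain graph (expected empty for
    stimulus-driven training)."""
    return list(nx.simple_cycles(chain.graph))


def edge_directness_vs_strength(chain: ChainGraph) -> dict:
    """Do more direct lateral connections carry stronger synapses?

    For every node with edges to both its 1-step and 2-step canonical
    successors (generally: to two successors at different canonical
    distances), check that the shorter hop has the larger weight.  Returns
    the fraction of comparable pairs respecting directness; ``defined`` is
    False when fewer than two outgoing edges are comparable anywhere.
    """
    pos = {int(n): i for i, n in enumerate(chain.canonical_order)}
    respected = 0
    total = 0
    for u in chain.graph.nodes:
        out = [(pos[v] - pos[u], d["weight"])
               for v, d in chain.graph[u].items() if pos.get(v, -1) > pos.get(u, -1)]
        out.sort()
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                if out[i][0] < out[j][0]:
                    total += 1
                    respected += out[i][1] > out[j][1]
    if total == 0:
        return {"defined": False, "fraction_respected": np.nan, "n_pairs": 0}
    return {"defined": True, "fraction_respected": respected / total, "n_pairs": total}


@dataclass
class EvaluationReport:
    """Aggregate verdict on one trained network (one pattern)."""

    pattern_learnt: bool
    sequence_learnt: bool
    members: list
    canonical_order: list
    chain_length: int
    first_neuron_latency_ms: float
    recognition_rate: float
    order_consistency: float
    off_reliable: list
    accepting_nodes: list
    start_nodes: list
    n_presentations: int

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, default=lambda o: o.tolist() if isinstance(o, np.ndarray) else o,
                          indent=2)


def evaluate_record(record: SimulationRecord, n_presentations: int = 10, *,
                    weights=None, pattern_id: int = 0,
                    seed: int | None = None,
                    edge_threshold: float | None = None) -> tuple[EvaluationReport, ChainGraph]:
    """Full post-training evaluation: lateral-on and severed-lateral tests,
    both learning criteria, and the extracted chain graph."""
    on = run_test(record, n_presentations, lateral_enabled=True, weights=weights,
                  pattern_id=pattern_id, seed=seed)
    off = run_test(record, n_presentations, lateral_enabled=False, weights=weights,
                   pattern_id=pattern_id, seed=seed)
    on_tab = compute_reliability(on)
    off_tab = compute_reliability(off)
    members, pattern_ok = assess_pattern_learnt(on_tab)
    seq_ok, canonical = assess_sequence_learnt(on_tab, off_tab)
    w = (weights if weights is not None else record.weights)
    chain = extract_chain_graph(w.w_lat, canonical, edge_threshold, w.w_lat_max)
    recognized = [all(int(m) in d for m in members) for d in on_tab.first_spikes]
    first_lat = float(on_tab.latency_median[canonical[0]]) if canonical.size else np.nan
    report = EvaluationReport(
        pattern_learnt=bool(pattern_ok),
        sequence_learnt=bool(seq_ok),
        members=[int(m) for m in members],
        canonical_order=[int(m) for m in canonical],
        chain_length=int(members.size),
        first_neuron_latency_ms=first_lat,
        recognition_rate=float(np.mean(recognized)) if members.size else 0.0,
        order_consistency=_order_consistency(on_tab, canonical),
        off_reliable=[int(m) for m in off_tab.members()],
        accepting_nodes=chain.accepting_nodes,
        start_nodes=chain.start_nodes,
        n_presentations=n_presentations,
    )
    return report, chain


PROBE_TIMES_MS = (5_000.0, 10_000.0, 15_000.0, 20_000.0, 30_000.0,
                  50_000.0, 100_000.0, 200_000.0)


def time_to_sequence_learnt(record: SimulationRecord, n_presentations: int = 10,
                            seed: int | None = None,
                            probe_times_ms=PROBE_TIMES_MS) -> float:
    """Earliest probed weight checkpoint (ms of simulated training) at which
    the sequence-learnt criterion holds; NaN if never.

    Probes a coarse grid of checkpoints (nearest stored checkpoint at or
    before each probe time) rather than every checkpoint: each probe costs
    two full test simulations.
    """
    seen = set()
    for t in probe_times_ms:
        t = min(float(t), float(record.duration))
        if t <= 0 or record.ck_times_ms.size == 0:
            continue
        idx = int(np.searchsorted(record.ck_times_ms, t + 1e-9) - 1)
        if idx < 0 or idx in seen:
            continue
        seen.add(idx)
        w = record.weights_at(float(record.ck_times_ms[idx]))
        report, _ = evaluate_record(record, n_presentations, weights=w, seed=seed)
        if report.sequence_learnt:
            return float(record.ck_times_ms[idx])
    return float("nan")


def sweep_wlmax(cfg: NetworkConfig, wlmax_values, n_seeds: int = 3,
                n_presentations: int = 10) -> pd.DataFrame:
    """Dependence of chain neurons on their predecessors, as a function of
    the lateral weight budget W^L_max.

    For each value, trains fresh networks and reports the percentage of
    chain members that remain reliable with the lateral synapses severed
    (mean and std over seeds).  Stronger lateral budgets make neurons more
    dependent on recurrent input, so the curve decreases.
    """
    rows = []
    for wl in wlmax_values:
        pcts = []
        for s in range(n_seeds):
            c = cfg.with_(w_lat_max=float(wl), seed=cfg.seed + 1000 * s)
            rec = run_training(c)
            on = compute_reliability(run_test(rec, n_presentations, lateral_enabled=True))
            off = compute_reliability(run_test(rec, n_presentations, lateral_enabled=False))
            members = on.members()
            if members.size == 0:
                continue
            off_ok = np.intersect1d(members, off.members())
            pcts.append(100.0 * off_ok.size / members.size)
        rows.append({"wlmax": float(wl),
                     "mean_pct_without_lateral": float(np.mean(pcts)) if pcts else np.nan,
                     "std_pct": float(np.std(pcts)) if pcts else np.nan,
                     "n_seeds": len(pcts)})
    return pd.DataFrame(rows)
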