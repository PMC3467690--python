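"""Reproducible experiment drivers: multi-seed trials and aggregate reports.

Each experiment trains fresh networks over independent seeds (each trial's
random streams derive from ``(master_seed, trial_index)``, so aggregate
results do not depend on execution order), evaluates the learning and
recognition criteria, and aggregates success rates, chain lengths and
latency statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .analysis import (evaluate_record, sweep_wlmax, time_to_sequence_learnt,
                       extract_chain_graph, detect_cycles, compute_reliability)
from .network import (NetworkConfig, run_training, run_multi_pattern_training,
                      run_concatenation_training, run_speed_variation_test, run_test)

__all__ = ["ExperimentSuiteConfig", "run_suite", "run_training_trials", "make_fixture"]

EXPERIMENT_IDS = ("train-nn", "train-a2a", "sweep", "two-pattern", "concat", "speed")


@dataclass
class ExperimentSuiteConfig:
    experiment: str = "train-nn"
    n_seeds: int = 10
    scaled_down: bool = False
    output_dir: str | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    #: extra knobs per experiment
    wlmax_values: tuple = (5.0, 15.0, 30.0, 50.0, 55.0)
    speed_factors: tuple = (0.98, 1.0, 1.02, 1.1, 2.0)
    n_presentations: int = 10

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"valid ids: {', '.join(EXPERIMENT_IDS)}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    def base_network(self) -> NetworkConfig:
        return self.network.scaled_down() if self.scaled_down else self.network


def run_training_trials(cfg: NetworkConfig, n_seeds: int, *, mode: str | None = None,
                        n_presentations: int = 10, with_time_to_learn: bool = False):
    """Train ``n_seeds`` independent networks and evaluate each.

    Returns (per-trial DataFrame, list of (record, report, chain)).
    """
    rows, detail = [], []
    if mode is not None:
        cfg = cfg.with_(stdp_mode=mode)
    for i in range(n_seeds):
        c = cfg.with_(seed=cfg.seed + 7919 * i)
        rec = run_training(c)
        report, chain = evaluate_record(rec, n_presentations)
        t_learn = time_to_sequence_learnt(rec, n_presentations) if with_time_to_learn else np.nan
        rows.append({
            "seed": c.seed,
            "pattern_learnt": report.pattern_learnt,
            "sequence_learnt": report.sequence_learnt,
            "chain_length": report.chain_length,
            "first_latency_ms": report.first_neuron_latency_ms,
            "recognition_rate": report.recognition_rate,
            "order_consistency": report.order_consistency,
            "n_off_reliable": len(report.off_reliable),
            "n_cycles": len(detect_cycles(chain)),
            "time_to_sequence_ms": t_learn,
        })
        detail.append((rec, report, chain))
    return pd.DataFrame(rows), detail


def _summary_from_trials(df: pd.DataFrame) -> dict:
    ok = df[df.pattern_learnt]
    return {
        "n_trials": int(len(df)),
        "pattern_success_rate": float(df.pattern_learnt.mean()),
        "sequence_success_rate": float(df.sequence_learnt.mean()),
        "mean_chain_length": float(ok.chain_length.mean()) if len(ok) else float("nan"),
        "mean_first_latency_ms": float(ok.first_latency_ms.mean()) if len(ok) else float("nan"),
        "median_time_to_sequence_ms": float(df[df.sequence_learnt].time_to_sequence_ms.median())
        if df.sequence_learnt.any() else float("nan"),
        "total_cycles": int(df.n_cycles.sum()),
    }


def run_suite(cfg: ExperimentSuiteConfig) -> dict:
    """Run the named experiment over ``n_seeds`` trials and aggregate."""
    net = cfg.base_network()
    out: dict = {"experiment": cfg.experiment, "n_seeds": cfg.n_seeds,
                 "scaled_down": cfg.scaled_down}

    if cfg.experiment in ("train-nn", "train-a2a"):
        mode = "nearest_neighbor" if cfg.experiment == "train-nn" else "all_to_all"
        df, _ = run_training_trials(net, cfg.n_seeds, mode=mode,
                                    n_presentations=cfg.n_presentations,
                                    with_time_to_learn=True)
        out.update(_summary_from_trials(df))
        out["trials"] = df.to_dict("records")
    elif cfg.experiment == "sweep":
        df = sweep_wlmax(net, cfg.wlmax_values, cfg.n_seeds, cfg.n_presentations)
        out["sweep"] = df.to_dict("records")
    elif cfg.experiment == "two-pattern":
        rows = []
        for i in range(cfg.n_seeds):
            c = net.with_(seed=net.seed + 7919 * i)
            rec = run_multi_pattern_training(c, 2)
            learnt = []
            for pid in (0, 1):
                rep, _ = evaluate_record(rec, cfg.n_presentations, pattern_id=pid)
                learnt.append(rep.pattern_learnt)
            rows.append({"seed": c.seed, "pattern0_learnt": learnt[0],
                         "pattern1_learnt": learnt[1], "both": all(learnt)})
        df = pd.DataFrame(rows)
        out["both_learnt_rate"] = float(df.both.mean())
        out["trials"] = df.to_dict("records")
    elif cfg.experiment == "concat":
        rows = []
        for i in range(cfg.n_seeds):
            c = net.with_(seed=net.seed + 7919 * i)
            rec = run_multi_pattern_training(c, 2)
            rec2 = run_concatenation_training(rec)
            linked = _tail_head_link(rec, rec2, cfg.n_presentations)
            rows.append({"seed": c.seed, **linked})
        df = pd.DataFrame(rows)
        out["link_rate"] = float(df.linked.mean())
        out["trials"] = df.to_dict("records")
    elif cfg.experiment == "speed":
        c = net
        rec = run_training(c)
        out["speed"] = [run_speed_variation_test(rec, f) for f in cfg.speed_factors]

    if cfg.output_dir:
        d = Path(cfg.output_dir)
        d.mkdir(parents=True, exist_ok=True)
        (d / f"{cfg.experiment}_summary.json").write_text(json.dumps(out, indent=2, default=str))
    return out


def _tail_head_link(rec_phase1, rec_phase2, n_presentations: int) -> dict:
    """Did phase-2 training connect the tail of chain 2 to the head of chain 1?"""
    from .analysis import chain_members_and_order

    members, orders = [], []
    for pid in (0, 1):
        tab = compute_reliability(run_test(rec_phase2, n_presentations, pattern_id=pid))
        m, o = chain_members_and_order(tab)
        members.append(set(int(x) for x in m))
        orders.append(o)
    w = rec_phase2.weights
    thr = 0.2 * w.w_lat_max
    linked = False
    strongest = 0.0
    # edges from late chain-2 members into early chain-1 members
    tail = [int(x) for x in orders[1][-max(1, len(orders[1]) // 2):]]
    head = [int(x) for x in orders[0][:max(1, len(orders[0]) // 2 + 1)]]
    for u in tail:
        for v in head:
            if u != v:
                strongest = max(strongest, float(w.w_lat[u, v]))
                if w.w_lat[u, v] > thr:
                    linked = True
    sub0 = compute_reliability(run_test(rec_phase2, n_presentations, pattern_id=0)).members()
    return {"linked": linked, "strongest_link": strongest,
            "chain1_len": len(members[0]), "chain2_len": len(members[1]),
            "sub_chain_recognized": bool(sub0.size > 0)}


def make_fixture(seed: int = 0) -> "object":
    """Miniature deterministic training record for unit tests.

    5 excitatory neurons, 200 afferents (100 carrying a 50-ms pattern),
    10 s of training; runs in a couple of seconds.
    """
    cfg = NetworkConfig(
        n_excitatory=5,
        stimulus=NetworkConfig().stimulus.with_(
            n_afferents_total=200, n_pattern_afferents=100),
        w_ff_max=0.45 * 10,   # 100 pattern afferents instead of 1000
        train_duration=10_000.0,
        checkpoint_interval=5_000.0,
        seed=seed,
    )
    return run_training(cfg)
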