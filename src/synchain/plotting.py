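"""Basic figures: response rasters, lateral-weight trajectories, sweep curves."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_test_raster", "plot_lateral_trajectories", "plot_sweep_curve"]


def plot_test_raster(test, ax=None, margin_ms: float | None = None):
    """Cumulative output spikes over repeated presentations, aligned to onset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for neurons, times in test.presentation_spikes(margin_ms):
        ax.plot(times, neurons, "k.", ms=4)
    ax.axvspan(0, test.pattern_duration, color="0.9", zorder=0)
    ax.set_xlabel("time from pattern onset (ms)")
    ax.set_ylabel("neuron")
    ax.set_ylim(-0.5, test.n_excitatory - 0.5)
    return ax


def plot_lateral_trajectories(record, n_synapses: int = 10, ax=None, rng=None):
    """Lateral weight time courses for a sample of synapses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    snaps = record.snapshots_lat
    t = record.snapshot_times_ms / 1000.0
    final = snaps[-1]
    order = np.argsort(final.ravel())[::-1]
    rng = np.random.default_rng(0) if rng is None else rng
    pick = np.concatenate([order[:n_synapses // 2],
                           rng.choice(order[n_synapses // 2:], n_synapses // 2, replace=False)])
    for idx in pick:
        i, j = np.unravel_index(idx, final.shape)
        ax.plot(t, snaps[:, i, j], lw=0.8)
    ax.set_xlabel("training time (s)")
    ax.set_ylabel("lateral weight")
    return ax


def plot_sweep_curve(sweep_df, ax=None):
    """Percentage of chain members responsive without lateral input vs W^L_max."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(sweep_df.wlmax, sweep_df.mean_pct_without_lateral,
                yerr=sweep_df.std_pct, marker="o")
    ax.set_xlabel(r"$W^L_{max}$")
    ax.set_ylabel("% members responsive without lateral input")
    ax.set_ylim(0, 105)
    return ax
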