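"""Stimulus generator: frozen pattern, schedule, rendering, labeling."""

import numpy as np
import pytest

from synchain.stimulus import (LABEL_PATTERN, SchedulingError, StimulusConfig,
                               build_schedule, generate_pattern, label_noise_fraction,
                               render_stimulus, SpikeRaster)


def test_pattern_spike_count_matches_poisson_mean(rng):
    cfg = StimulusConfig()
    pat = generate_pattern(cfg, rng)
    expected = 1000 * 0.054 * 50        # afferents * rate/ms * duration
    sigma = np.sqrt(expected)
    assert abs(pat.n_spikes - expected) < 3 * sigma
    assert pat.steps.min() >= 0 and pat.steps.max() < cfg.pattern_steps


def test_zero_duration_pattern_is_empty(rng):
    cfg = StimulusConfig(pattern_duration=0.0)
    assert generate_pattern(cfg, rng).n_spikes == 0


def test_pattern_generation_is_deterministic():
    cfg = StimulusConfig(seed=3)
    a = generate_pattern(cfg, np.random.default_rng(3))
    b = generate_pattern(cfg, np.random.default_rng(3))
    assert np.array_equal(a.steps, b.steps) and np.array_equal(a.afferents, b.afferents)


def test_schedule_gaps_and_duty_cycle(rng):
    cfg = StimulusConfig(total_duration=100_000.0)
    sch = build_schedule(cfg, rng)
    assert sch.n_presentations > 0
    assert np.all(sch.gaps() >= cfg.min_gap - 1e-9)
    assert sch.duty_cycle() <= 0.5


def test_schedule_presentation_count_bound(rng):
    # with min_gap 50 and pattern 50 at most 1000/(50+50) = 10 fit in 1 s
    cfg = StimulusConfig(total_duration=1_000.0, mean_extra_gap=0.0)
    sch = build_schedule(cfg, rng)
    assert 0 < sch.n_presentations <= 10


def test_unschedulable_duration_raises(rng):
    with pytest.raises(SchedulingError):
        build_schedule(StimulusConfig(total_duration=80.0), rng)


@pytest.fixture(scope="module")
def rendered():
    cfg = StimulusConfig(total_duration=60_000.0, seed=11)
    rng = np.random.default_rng(11)
    pat = generate_pattern(cfg, rng)
    sch = build_schedule(cfg, rng)
    return cfg, pat, sch, render_stimulus(pat, sch, cfg, rng)


def test_rendered_rates_near_64hz(rendered):
    cfg, _, _, raster = rendered
    rates = raster.rates_hz()
    # per-afferent binomial: 64 Hz over 60 s -> sigma ~ 8 Hz; test the mean of each half
    for half in (rates[:1000], rates[1000:]):
        assert abs(half.mean() - 64.0) < 1.0


def test_rendered_pattern_windows_contain_exact_pattern(rendered):
    cfg, pat, sch, raster = rendered
    want = set(zip(pat.afferents.tolist(), pat.steps.tolist()))
    m = raster.labels == LABEL_PATTERN
    for on in sch.onset_steps[:5]:
        in_win = m & (raster.steps >= on) & (raster.steps < on + pat.n_steps)
        got = set(zip(raster.sources[in_win].tolist(), (raster.steps[in_win] - on).tolist()))
        # every pattern spike present (a coincident background spike keeps the
        # pattern label, so got == want exactly)
        assert got == want


def test_at_most_one_spike_per_source_and_bin(rendered):
    _, _, _, raster = rendered
    key = raster.sources.astype(np.int64) * raster.n_steps + raster.steps
    assert np.unique(key).size == key.size


def test_noise_fraction_of_default_stimulus(rendered):
    _, _, _, raster = rendered
    frac = label_noise_fraction(raster)
    assert frac >= 0.75
    assert frac < 1.0


def test_noise_fraction_requires_labels():
    r = SpikeRaster(np.array([0]), np.array([1]), 2, 10, 0.1, labels=None)
    with pytest.raises(ValueError):
        label_noise_fraction(r)


def test_noise_fraction_counts():
    r = SpikeRaster(np.zeros(4, int), np.arange(4), 1, 10, 0.1,
                    labels=np.array([0, 1, 2, 1], dtype=np.int8))
    assert label_noise_fraction(r) == 0.75


def test_reversed_and_scaled_pattern_transforms(rng):
    cfg = StimulusConfig()
    pat = generate_pattern(cfg, rng)
    rev = pat.reversed()
    assert rev.n_spikes == pat.n_spikes
    assert np.array_equal(np.sort(rev.steps), np.sort(pat.n_steps - 1 - pat.steps))
    fast = pat.time_scaled(2.0)
    assert fast.n_steps == pat.n_steps // 2
    assert fast.n_spikes <= pat.n_spikes
    same = pat.time_scaled(1.0)
    assert same.n_spikes == pat.n_spikes


def test_render_is_reproducible(small_stim_cfg):
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(9)
        pat = generate_pattern(small_stim_cfg, rng)
        sch = build_schedule(small_stim_cfg, rng)
        outs.append(render_stimulus(pat, sch, small_stim_cfg, rng))
    assert np.array_equal(outs[0].steps, outs[1].steps)
    assert np.array_equal(outs[0].sources, outs[1].sources)
    assert np.array_equal(outs[0].labels, outs[1].labels)
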