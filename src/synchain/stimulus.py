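"""Afferent spike input: a frozen spatio-temporal pattern embedded in Poisson noise.

The stimulus drives a small competitive network of spiking neurons.  It
consists of 2000 afferents.  Half of them (the *pattern half*) alternate
between a fixed ("frozen") 50-ms spatio-temporal spike pattern, re-inserted
unchanged at random times, and fresh Poisson spiking at the carrier rate.
The other half (the *noise half*) carry independent Poisson trains at the
carrier rate throughout.  A low-rate Poisson background is superposed on
every afferent at all times, including during pattern presentations.

Because the frozen pattern is itself drawn from a Poisson process at the
carrier rate, the stimulus is statistically stationary: nothing in the
first-order statistics distinguishes pattern epochs from noise epochs.
Recognition therefore has to rely on the repeating spatio-temporal
structure, not on rate cues.

All times are in milliseconds; rates are in Hz.  Spikes are binary events
on a discrete grid of width ``dt`` (at most one spike per source per bin,
half-open bins ``[t, t + dt)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np

__all__ = [
    "StimulusConfig",
    "FrozenPattern",
    "PresentationSchedule",
    "SpikeRaster",
    "SchedulingError",
    "LABEL_PATTERN",
    "LABEL_CARRIER",
    "LABEL_BACKGROUND",
    "LABEL_NAMES",
    "generate_pattern",
    "build_schedule",
    "render_stimulus",
    "label_noise_fraction",
]

LABEL_PATTERN = 0
LABEL_CARRIER = 1
LABEL_BACKGROUND = 2
LABEL_NAMES = {LABEL_PATTERN: "pattern", LABEL_CARRIER: "carrier", LABEL_BACKGROUND: "background"}


class SchedulingError(ValueError):
    """Raised when no presentation schedule fits the requested duration."""


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the afferent input.

    Attributes
    ----------
    n_afferents_total:
        Total number of afferent lines seen by every excitatory neuron.
    n_pattern_afferents:
        Size of the pattern half (the lines on which the frozen pattern is
        inserted).  The remaining lines form the noise half.
    carrier_rate:
        Poisson rate (Hz) of the carrier signal; the frozen pattern is drawn
        at this rate too, so pattern and carrier are statistically identical.
    background_rate:
        Rate (Hz) of the additional Poisson background present on all
        afferents at all times.
    pattern_duration:
        Length (ms) of the frozen pattern.
    min_gap:
        Minimum stretch (ms) of pure carrier between the end of one
        presentation and the next onset.
    mean_extra_gap:
        Mean (ms) of the exponential excess added on top of ``min_gap``;
        the inter-presentation gap is ``min_gap + Exponential(mean_extra_gap)``.
    total_duration:
        Length (ms) of the rendered stimulus.
    dt:
        Time bin (ms).
    seed:
        Seed for the stimulus random stream.
    """

    n_afferents_total: int = 2000
    n_pattern_afferents: int = 1000
    carrier_rate: float = 54.0
    background_rate: float = 10.0
    pattern_duration: float = 50.0
    min_gap: float = 50.0
    mean_extra_gap: float = 50.0
    total_duration: float = 200_000.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_pattern_afferents <= self.n_afferents_total):
            raise ValueError("n_pattern_afferents must be in [0, n_afferents_total]")
        if self.pattern_duration < 0 or self.min_gap < 0 or self.mean_extra_gap < 0:
            raise ValueError("durations must be non-negative")
        if self.carrier_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.total_duration / self.dt))

    @property
    def pattern_steps(self) -> int:
        return int(round(self.pattern_duration / self.dt))

    @property
    def mean_rate(self) -> float:
        """Long-run per-afferent rate (Hz): carrier plus background."""
        return self.carrier_rate + self.background_rate

    def with_(self, **kw) -> "StimulusConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class FrozenPattern:
    """A fixed spatio-temporal spike template on the pattern half.

    ``steps`` and ``afferents`` are parallel arrays sorted by time step;
    afferent indices are relative to the pattern half (``0 .. n_afferents-1``)
    and time steps lie in ``[0, n_steps)``.
    """

    steps: np.ndarray
    afferents: np.ndarray
    n_steps: int
    n_afferents: int
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.ascontiguousarray(self.steps, dtype=np.int64))
        object.__setattr__(self, "afferents", np.ascontiguousarray(self.afferents, dtype=np.int32))
        self.steps.setflags(write=False)
        self.afferents.setflags(write=False)
        if self.steps.size and (self.steps.min() < 0 or self.steps.max() >= self.n_steps):
            raise ValueError("pattern spike steps outside [0, n_steps)")

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.steps * self.dt

    @property
    def n_spikes(self) -> int:
        return int(self.steps.size)

    def reversed(self) -> "FrozenPattern":
        """Time-mirrored copy of the pattern (used for control presentations)."""
        steps = self.n_steps - 1 - self.steps[::-1]
        return FrozenPattern(steps, self.afferents[::-1], self.n_steps, self.n_afferents, self.dt)

    def time_scaled(self, speed_factor: float) -> "FrozenPattern":
        """Pattern replayed at ``speed_factor`` times the original speed.

        ``speed_factor > 1`` compresses the pattern (faster playback).
        """
        if speed_factor <= 0:
            raise ValueError("speed_factor must be positive")
        n_steps = max(1, int(round(self.n_steps / speed_factor)))
        steps = np.minimum((self.steps / speed_factor).round().astype(np.int64), n_steps - 1)
        # collapse collisions created by rounding
        key = steps * self.n_afferents + self.afferents
        _, keep = np.unique(key, return_index=True)
        keep.sort()
        order = np.argsort(steps[keep], kind="stable")
        return FrozenPattern(steps[keep][order], self.afferents[keep][order],
                             n_steps, self.n_afferents, self.dt)

    def to_json(self) -> str:
        return json.dumps({
            "n_steps": self.n_steps, "n_afferents": self.n_afferents, "dt": self.dt,
            "steps": self.steps.tolist(), "afferents": self.afferents.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "FrozenPattern":
        d = json.loads(text)
        return cls(np.asarray(d["steps"]), np.asarray(d["afferents"]),
                   d["n_steps"], d["n_afferents"], d["dt"])


@dataclass(frozen=True)
class PresentationSchedule:
    """Onset steps of the pattern presentations within a stimulus.

    ``pattern_ids`` allows interleaving several frozen patterns (all of the
    same duration grid); a single-pattern schedule uses id 0 throughout.
    """

    onset_steps: np.ndarray
    pattern_steps: int
    n_steps: int
    dt: float
    pattern_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "onset_steps",
                           np.ascontiguousarray(self.onset_steps, dtype=np.int64))
        if self.pattern_ids is None:
            object.__setattr__(self, "pattern_ids",
                               np.zeros(self.onset_steps.size, dtype=np.int32))
        else:
            object.__setattr__(self, "pattern_ids",
                               np.ascontiguousarray(self.pattern_ids, dtype=np.int32))
        if self.pattern_ids.size != self.onset_steps.size:
            raise ValueError("pattern_ids and onset_steps must have equal length")
        if np.any(np.diff(self.onset_steps) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_presentations(self) -> int:
        return int(self.onset_steps.size)

    @property
    def onsets(self) -> np.ndarray:
        """Onset times in ms."""
        return self.onset_steps * self.dt

    def gaps(self) -> np.ndarray:
        """Noise stretches (ms) between consecutive presentations."""
        return (self.onset_steps[1:] - self.onset_steps[:-1] - self.pattern_steps) * self.dt

    def duty_cycle(self) -> float:
        """Fraction of total time covered by pattern presentations."""
        return self.n_presentations * self.pattern_steps / self.n_steps

    def in_presentation_mask(self) -> np.ndarray:
        """Boolean per time step: inside a presentation window."""
        mask = np.zeros(self.n_steps, dtype=bool)
        for on in self.onset_steps:
            mask[on:on + self.pattern_steps] = True
        return mask

    def to_json(self) -> str:
        return json.dumps({
            "onset_steps": self.onset_steps.tolist(), "pattern_steps": self.pattern_steps,
            "n_steps": self.n_steps, "dt": self.dt, "pattern_ids": self.pattern_ids.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PresentationSchedule":
        d = json.loads(text)
        return cls(np.asarray(d["onset_steps"]), d["pattern_steps"], d["n_steps"], d["dt"],
                   np.asarray(d["pattern_ids"]))


@dataclass
class SpikeRaster:
    """Event list of binary spikes: parallel arrays of source id and time step.

    ``labels`` (optional) tags each event as pattern, carrier, or background.
    Events are sorted by (step, source).
    """

    sources: np.ndarray
    steps: np.ndarray
    n_sources: int
    n_steps: int
    dt: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sources = np.ascontiguousarray(self.sources, dtype=np.int32)
        self.steps = np.ascontiguousarray(self.steps, dtype=np.int64)
        if self.labels is not None:
            self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)

    @property
    def times(self) -> np.ndarray:
        return self.steps * self.dt

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def n_spikes(self) -> int:
        return int(self.steps.size)

    def rates_hz(self) -> np.ndarray:
        """Empirical per-source firing rate over the whole raster (Hz)."""
        counts = np.bincount(self.sources, minlength=self.n_sources)
        return counts / (self.duration * 1e-3)

    def to_dataframe(self):
        import pandas as pd

        d = {"source_id": self.sources, "time_ms": self.times}
        if self.labels is not None:
            d["label"] = np.array([LABEL_NAMES[l] for l in self.labels])
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generation


def _bernoulli_process(rng: np.random.Generator, n_sources: int, n_steps: int,
                       p: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a per-bin Bernoulli(p) spike process for ``n_sources`` lines.

    The sources are laid end to end on one long line of ``n_sources*n_steps``
    bins; by memorylessness the geometric inter-spike gaps of that single
    stream restrict to exact Bernoulli processes on every source.  Returns
    (sources, steps), unsorted in time but sorted by source.
    """
    if p <= 0 or n_sources == 0 or n_steps == 0:
        return (np.empty(0, np.int32), np.empty(0, np.int64))
    if p >= 1:
        src = np.repeat(np.arange(n_sources, dtype=np.int32), n_steps)
        stp = np.tile(np.arange(n_steps, dtype=np.int64), n_sources)
        return src, stp
    total = n_sources * n_steps
    mean = total * p
    positions = []
    last = -1  # position of previous spike on the long line
    while last < total:
        n_draw = int(mean - (last + 1) * p + 6 * np.sqrt(mean) + 100)
        gaps = rng.geometric(p, size=n_draw)
        pos = last + np.cumsum(gaps)
        positions.append(pos)
        last = int(pos[-1])
    pos = np.concatenate(positions)
    pos = pos[pos < total]
    return (pos // n_steps).astype(np.int32), (pos % n_steps).astype(np.int64)


def generate_pattern(cfg: StimulusConfig, rng: np.random.Generator) -> FrozenPattern:
    """Draw the frozen pattern: independent Poisson trains at the carrier rate.

    The pattern is generated once per experiment and then re-inserted
    unchanged at every presentation.
    """
    p = cfg.carrier_rate * 1e-3 * cfg.dt
    src, stp = _bernoulli_process(rng, cfg.n_pattern_afferents, cfg.pattern_steps, p)
    order = np.lexsort((src, stp))
    return FrozenPattern(stp[order], src[order], cfg.pattern_steps,
                         cfg.n_pattern_afferents, cfg.dt)


def build_schedule(cfg: StimulusConfig, rng: np.random.Generator,
                   n_patterns: int = 1) -> PresentationSchedule:
    """Place pattern presentations at random times with gaps >= ``min_gap``.

    Gaps are ``min_gap + Exponential(mean_extra_gap)``, which keeps the
    pattern duty cycle near 1/3 for the default 50-ms pattern so that the
    pattern recurs often enough for potentiation to beat the depression bias.
    With several patterns, each presentation draws its pattern id uniformly
    (presentations never overlap).
    """
    pat_steps = cfg.pattern_steps
    if cfg.n_steps <= pat_steps + int(round(cfg.min_gap / cfg.dt)):
        raise SchedulingError(
            f"total_duration={cfg.total_duration} ms cannot fit a "
            f"{cfg.pattern_duration} ms pattern plus a {cfg.min_gap} ms gap")
    onsets = []
    t = 0
    while True:
        gap_ms = cfg.min_gap + (rng.exponential(cfg.mean_extra_gap) if cfg.mean_extra_gap > 0 else 0.0)
        t += int(round(gap_ms / cfg.dt))
        if t + pat_steps > cfg.n_steps:
            break
        onsets.append(t)
        t += pat_steps
    ids = rng.integers(0, n_patterns, size=len(onsets)).astype(np.int32)
    return PresentationSchedule(np.asarray(onsets, dtype=np.int64), pat_steps,
                                cfg.n_steps, cfg.dt, ids)


def _dedupe(sources, steps, labels, n_steps):
    """Collapse simultaneous spikes on one source to a single binary spike.

    Priority pattern > carrier > background: a background spike coinciding
    with a pattern spike is physically the same binary event; it keeps the
    pattern label.
    """
    key = sources.astype(np.int64) * n_steps + steps
    order = np.lexsort((labels, key))
    key = key[order]
    keep = np.ones(key.size, dtype=bool)
    keep[1:] = key[1:] != key[:-1]
    idx = order[keep]
    return sources[idx], steps[idx], labels[idx]


def render_stimulus(pattern: FrozenPattern, schedule: PresentationSchedule,
                    cfg: StimulusConfig, rng: np.random.Generator,
                    patterns: list[FrozenPattern] | None = None) -> SpikeRaster:
    """Render one full labeled afferent raster.

    Pattern half (sources ``0 .. n_pattern_afferents-1``): frozen-pattern
    spikes during presentations, carrier-rate Poisson between presentations,
    background-rate Poisson throughout.  Noise half: carrier+background-rate
    Poisson throughout.  ``patterns`` overrides the single ``pattern`` when
    the schedule interleaves several ids.
    """
    n_pat = cfg.n_pattern_afferents
    n_noise = cfg.n_afferents_total - n_pat
    n_steps = cfg.n_steps
    dt = cfg.dt
    pats = patterns if patterns is not None else [pattern]

    all_src, all_stp, all_lab = [], [], []

    # pattern-half carrier: full-duration process, restricted to the gaps
    p_carrier = cfg.carrier_rate * 1e-3 * dt
    src, stp = _bernoulli_process(rng, n_pat, n_steps, p_carrier)
    mask = schedule.in_presentation_mask()
    keep = ~mask[stp]
    all_src.append(src[keep])
    all_stp.append(stp[keep])
    all_lab.append(np.full(int(keep.sum()), LABEL_CARRIER, np.int8))

    # frozen pattern insertions
    for on, pid in zip(schedule.onset_steps, schedule.pattern_ids):
        pat = pats[int(pid)]
        all_src.append(pat.afferents.astype(np.int32))
        all_stp.append(pat.steps + on)
        all_lab.append(np.full(pat.n_spikes, LABEL_PATTERN, np.int8))

    # noise half: carrier at all times
    src, stp = _bernoulli_process(rng, n_noise, n_steps, p_carrier)
    all_src.append(src + n_pat)
    all_stp.append(stp)
    all_lab.append(np.full(src.size, LABEL_CARRIER, np.int8))

    # background on every afferent at all times
    p_bg = cfg.background_rate * 1e-3 * dt
    src, stp = _bernoulli_process(rng, cfg.n_afferents_total, n_steps, p_bg)
    all_src.append(src)
    all_stp.append(stp)
    all_lab.append(np.full(src.size, LABEL_BACKGROUND, np.int8))

    sources = np.concatenate(all_src)
    steps = np.concatenate(all_stp)
    labels = np.concatenate(all_lab)
    sources, steps, labels = _dedupe(sources, steps, labels, n_steps)
    order = np.lexsort((sources, steps))
    return SpikeRaster(sources[order], steps[order], cfg.n_afferents_total,
                       n_steps, dt, labels[order])


def label_noise_fraction(raster: SpikeRaster) -> float:
    """Fraction of spikes that are noise (carrier or background) rather than
    frozen-pattern spikes."""
    if raster.labels is None:
        raise ValueError("raster has no labels")
    if raster.n_spikes == 0:
        return 1.0
    return float(np.mean(raster.labels != LABEL_PATTERN))
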