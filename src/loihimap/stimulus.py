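"""Stimulus classes: frozen external spike trains and Poisson generators.

Three drive modes are used throughout the validation studies: a constant
bias current (carried by ``PhysicalLIFParams.I_bias``), a small frozen set
of external spike trains, and seeded homogeneous Poisson spike trains that
can be frozen to disk and replayed identically on both backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrainSet", "PoissonSpec", "frozen_spike_fixture", "generate_poisson"]


@dataclass
class SpikeTrainSet:
    """Per-source afferent spike trains.

    ``trains`` maps a source id to a sorted array of spike times (ms);
    ``weights`` optionally maps a source id to its synaptic weight (pA per
    spike).  A missing weight means "use the neuron's default w_syn".
    """

    trains: dict[int, np.ndarray]
    weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for source, times in self.trains.items():
            t = np.asarray(times, dtype=float)
            if t.size and t.min() < 0:
                raise ValueError(f"source {source}: spike times must be non-negative")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"source {source}: spike times must be sorted")
            clean[int(source)] = t
        self.trains = clean

    @property
    def sources(self) -> list[int]:
        return sorted(self.trains)

    def times_of(self, source: int) -> np.ndarray:
        return self.trains[source]

    def weight_of(self, source: int) -> float | None:
        return self.weights.get(source)

    @property
    def n_events(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def all_times(self) -> np.ndarray:
        """All event times pooled across sources, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.trains.values())))


@dataclass(frozen=True)
class PoissonSpec:
    """Homogeneous Poisson spike generator specification."""

    n_sources: int
    rate: float        # Hz
    duration: float    # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def frozen_spike_fixture() -> SpikeTrainSet:
    """The frozen five-source spike-train fixture used for the worked
    spike-driven validation: eleven events generated once from 5 Hz Poisson
    sources over 500 ms and then fixed, so both backends replay the
    identical stimulus."""
    return SpikeTrainSet(
        trains={
            0: np.array([446.0]),
            1: np.array([355.0]),
            2: np.array([53.0, 258.0, 300.0, 424.0, 457.0]),
            3: np.array([88.0, 466.0]),
            4: np.array([100.0, 212.0]),
        }
    )


def generate_poisson(spec: PoissonSpec) -> SpikeTrainSet:
    """Draw one frozen realization of homogeneous Poisson spike trains.

    Event times per source are the cumulative sums of Exponential(rate)
    inter-event intervals, truncated at the duration.  The same seed always
    produces the same set.
    """
    rng = np.random.default_rng(spec.seed)
    trains: dict[int, np.ndarray] = {}
    for source in range(spec.n_sources):
        if spec.rate == 0:
            trains[source] = np.empty(0)
            continue
        mean_isi_ms = 1000.0 / spec.rate
        # draw enough intervals to overshoot the window w.h.p., then truncate
        n_draw = max(8, int(2 * spec.duration / mean_isi_ms + 10))
        times = np.cumsum(rng.exponential(mean_isi_ms, size=n_draw))
        while times.size and times[-1] < spec.duration:
            times = np.concatenate(
                [times, times[-1] + np.cumsum(rng.exponential(mean_isi_ms, size=n_draw))]
            )
        trains[source] = times[times < spec.duration]
    return SpikeTrainSet(trains=trains)
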