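"""Synthetic spike trains and traces with known ground truth.

These generators emulate the structural features the analysis operators
consume — bursts of short-ISI spikes separated by long gaps, a prescribed
anticipation-vs-ISI relationship between a master and a slave train, and
sampled membrane-like traces with one bump per spike — so every downstream
operator can be tested against an exact construction without integrating
the network.  They make no attempt to be statistically faithful surrogates
of the chaotic dynamics.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .spikes import BurstSegmentation, SpikeTrain

__all__ = [
    "BurstModel",
    "AnticipationProfile",
    "make_burst_train",
    "make_master_slave_pair",
    "make_trace_from_train",
]


@dataclass(frozen=True)
class BurstModel:
    """Bursting spike-train recipe: per-burst ISI profile, gaps and jitter.

    ``intra_isis`` is the sequence of ISIs inside one burst (so each burst
    has ``len(intra_isis) + 1`` spikes); a profile that first shrinks then
    grows mimics the intra-burst adaptation of the chaotic dynamics, and the
    defaults match its scales (intra-burst ISIs of tens of time units,
    inter-burst gaps near 80).  The inter-burst gap must exceed every
    intra-burst ISI.  Jitter is uniform on ``[-jitter, +jitter]`` per spike.

    For a slave train derived from this one to be recoverable by
    nearest-spike matching, every ISI must exceed twice the anticipation
    imposed on it.
    """

    n_bursts: int = 5
    intra_isis: tuple[float, ...] = (20.0, 15.0, 12.0, 15.0, 20.0)
    inter_burst_gap: float = 80.0
    jitter: float = 0.0
    seed: int = 0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bursts < 1:
            raise ValueError("need at least one burst")
        if any(i <= 0 for i in self.intra_isis):
            raise ValueError("intra-burst ISIs must be positive")
        if self.intra_isis and self.inter_burst_gap <= max(self.intra_isis):
            raise ValueError("inter-burst gap must exceed every intra-burst ISI")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def make_burst_train(
    model: BurstModel, neuron_id: str = "fixture"
) -> tuple[SpikeTrain, BurstSegmentation]:
    """Realize a :class:`BurstModel`, returning the train and the
    ground-truth burst boundaries.

    Deterministic given the model (including its seed).  Jitter is kept small
    relative to the ISIs by the model's invariants, so the constructed
    boundaries remain recoverable by ISI-threshold segmentation.
    """
    rng = np.random.default_rng(model.seed)
    spikes_per_burst = len(model.intra_isis) + 1
    times = []
    bursts = []
    t = model.t0
    for b in range(model.n_bursts):
        start = len(times)
        times.append(t)
        for isi in model.intra_isis:
            t += isi
            times.append(t)
        bursts.append((start, len(times)))
        t += model.inter_burst_gap
    times = np.asarray(times)
    if model.jitter > 0:
        times = times + rng.uniform(-model.jitter, model.jitter, size=len(times))
        times.sort()
    train = SpikeTrain(neuron_id, times)
    seg = BurstSegmentation(
        bursts=tuple(bursts),
        isi_threshold=(max(model.intra_isis) + model.inter_burst_gap) / 2
        if model.intra_isis
        else model.inter_burst_gap / 2,
    )
    return train, seg


@dataclass(frozen=True)
class AnticipationProfile:
    """Step function mapping preceding-ISI ranges to anticipation values.

    ``steps`` is a sequence of (isi_low, isi_high, anticipation) with
    disjoint half-open ranges [low, high).  ``first_spike`` is the
    anticipation assigned to the first master spike, which has no preceding
    ISI.
    """

    steps: tuple[tuple[float, float, float], ...]
    first_spike: float = 0.0

    def __post_init__(self) -> None:
        s = sorted(self.steps)
        for (l1, h1, _), (l2, h2, _) in zip(s, s[1:]):
            if h1 > l2:
                raise ValueError("profile ISI ranges must be disjoint")
        for lo, hi, a in self.steps:
            if not (np.isfinite(a) and np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError("profile values must be finite")
            if hi <= lo:
                raise ValueError("each range needs high > low")

    @classmethod
    def constant(cls, anticipation: float) -> "AnticipationProfile":
        return cls(
            steps=((0.0, np.finfo(float).max, anticipation),),
            first_spike=anticipation,
        )

    def __call__(self, isi: float) -> float:
        for lo, hi, a in self.steps:
            if lo <= isi < hi:
                return a
        raise ValueError(f"preceding ISI {isi} not covered by the profile")


def make_master_slave_pair(
    master: SpikeTrain, profile: AnticipationProfile
) -> SpikeTrain:
    """Slave train whose anticipation follows ``profile`` exactly.

    Each slave spike is the corresponding master spike shifted earlier by
    the profile value at the master spike's preceding ISI; the first spike
    uses ``profile.first_spike``.  Raises if the profile does not cover some
    preceding ISI or if the shifts would reorder the spikes.
    """
    tm = master.times
    ants = np.empty(len(tm))
    if len(tm) == 0:
        return SpikeTrain("slave-fixture", tm.copy())
    ants[0] = profile.first_spike
    for i in range(1, len(tm)):
        ants[i] = profile(tm[i] - tm[i - 1])
    ts = tm - ants
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("profile shifts would reorder the slave spikes")
    return SpikeTrain("slave-fixture", ts)


def make_trace_from_train(
    train: SpikeTrain,
    baseline: float = -1.0,
    peak: float = 2.0,
    sigma: float = 0.1,
    dt: float = 0.01,
    pad: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled series with one Gaussian bump per spike, peaking at the spike.

    The default bump (sigma 0.1 on a -1 baseline, peak 2) mimics the
    membrane variable's spike and rest levels.  Bumps must not overlap:
    every ISI must exceed 6 sigma, otherwise neighbouring bumps would shift
    each other's maxima and the train would not be recoverable.
    """
    isis = train.isis()
    if len(isis) and isis.min() <= 6 * sigma:
        raise ValueError(
            f"bumps overlap: min ISI {isis.min():.4g} <= 6 sigma = {6 * sigma:.4g}"
        )
    if len(train) == 0:
        t = np.arange(0.0, 2 * pad + dt / 2, dt)
        return t, np.full_like(t, baseline)
    t_lo = train.times[0] - pad
    t_hi = train.times[-1] + pad
    t = t_lo + dt * np.arange(int(round((t_hi - t_lo) / dt)) + 1)
    x = np.full_like(t, baseline)
    amp = peak - baseline
    for ts in train.times:
        m = np.abs(t - ts) < 8 * sigma
        x[m] += amp * np.exp(-0.5 * ((t[m] - ts) / sigma) ** 2)
    return t, x
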