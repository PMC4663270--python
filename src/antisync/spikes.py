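"""Spike detection, ISI statistics, master-slave matching and bursts.

A spike time is the time of a local maximum of the fast variable ``x``.  Per-
spike anticipation is ``t_master - t_slave`` for the nearest slave spike, so
positive anticipation means the slave fired first.  The anticipation-vs-ISI
table attributes to each matched slave spike its *preceding* interspike
interval; under this convention the highest-ISI spikes are the ones that open
a burst after a silent gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "ISIHistogram",
    "BurstSegmentation",
    "AnticipationClusters",
    "detect_spikes",
    "interspike_intervals",
    "match_and_anticipate",
    "isi_histogram",
    "segment_bursts",
    "anticipation_vs_isi",
    "principal_clusters",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike-maximum times of one neuron."""

    neuron_id: str
    times: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def isis(self) -> np.ndarray:
        return interspike_intervals(self)

    def shifted(self, delta: float) -> "SpikeTrain":
        return SpikeTrain(self.neuron_id, self.times + delta, self.threshold)

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame({"neuron_id": self.neuron_id, "time": self.times}).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "SpikeTrain":
        df = pd.read_csv(path_or_buf)
        nid = str(df["neuron_id"].iloc[0]) if len(df) else "unknown"
        return cls(neuron_id=nid, times=df["time"].to_numpy())


@dataclass(frozen=True)
class ISIHistogram:
    """Counts of ISIs over half-open bins [edge_i, edge_{i+1})."""

    edges: np.ndarray
    counts: np.ndarray

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame(
            {
                "edge_low": self.edges[:-1],
                "edge_high": self.edges[1:],
                "count": self.counts,
            }
        ).to_csv(path_or_buf, index=False)


@dataclass(frozen=True)
class BurstSegmentation:
    """Bursts as half-open index ranges [start, stop) into a spike train."""

    bursts: tuple[tuple[int, int], ...]
    isi_threshold: float
    degenerate: bool = False  # set when 'auto' found no bimodal ISI split

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def sizes(self) -> np.ndarray:
        return np.array([b - a for a, b in self.bursts])


def detect_spikes(
    t: np.ndarray,
    x: np.ndarray,
    threshold: float = 0.0,
    refine: bool = True,
    neuron_id: str = "",
) -> SpikeTrain:
    """Spike times as strict local maxima of ``x`` above ``threshold``.

    The default threshold 0 separates HR action potentials (peaks near +2)
    from the subthreshold oscillation (near -1).  With ``refine`` a parabola
    through the three samples around each grid maximum places the spike time
    between samples; anticipation down to a few hundredths of a time unit is
    only a handful of 0.01 samples, so sub-grid placement matters.
    Maxima at the first or last sample are excluded.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("t and x must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise ValueError("series must be finite")
    if len(t) < 3:
        return SpikeTrain(neuron_id, np.empty(0), threshold)
    dts = np.diff(t)
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9 * max(1.0, abs(dt))):
        raise ValueError("time grid must be uniform")

    mid = x[1:-1]
    is_max = (mid > x[:-2]) & (mid > x[2:]) & (mid > threshold)
    idx = np.nonzero(is_max)[0] + 1
    if not refine or len(idx) == 0:
        return SpikeTrain(neuron_id, t[idx], threshold)

    # vertex of the parabola through (x[i-1], x[i], x[i+1])
    denom = x[idx - 1] - 2.0 * x[idx] + x[idx + 1]  # < 0 at a strict maximum
    offset = 0.5 * (x[idx - 1] - x[idx + 1]) / denom
    times = t[idx] + offset * dt
    return SpikeTrain(neuron_id, times, threshold)


def interspike_intervals(train: SpikeTrain) -> np.ndarray:
    """Consecutive spike-time differences; empty for fewer than two spikes."""
    if len(train) < 2:
        return np.empty(0)
    return np.diff(train.times)


def match_and_anticipate(master: SpikeTrain, slave: SpikeTrain) -> pd.DataFrame:
    """Pair every master spike with the nearest slave spike.

    Returns a DataFrame with columns master_time, slave_time, anticipation
    (= master_time - slave_time; positive when the slave leads) and
    preceding_isi (the slave spike's preceding ISI; NaN for its first spike).

    Each slave spike appears at most once: if two master spikes claim the
    same slave spike, the closer pair wins and the other master spike is
    dropped.  When a master spike is equidistant from two slave spikes the
    earlier slave spike wins.
    """
    if len(master) == 0 or len(slave) == 0:
        raise ValueError(
            f"both trains must be non-empty (master has {len(master)}, "
            f"slave has {len(slave)} spikes)"
        )
    tm = master.times
    ts = slave.times
    # nearest slave index for each master spike; ties -> earlier slave
    right = np.searchsorted(ts, tm)
    left = np.clip(right - 1, 0, len(ts) - 1)
    right = np.clip(right, 0, len(ts) - 1)
    d_left = np.abs(tm - ts[left])
    d_right = np.abs(ts[right] - tm)
    j = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)

    # one master per slave spike: keep the closest claim (ties -> earlier master)
    keep = {}
    for i in range(len(tm)):
        jj = j[i]
        if jj not in keep or dist[i] < dist[keep[jj]]:
            keep[jj] = i
    kept = sorted(keep.values())

    slave_isi = np.full(len(ts), np.nan)
    if len(ts) > 1:
        slave_isi[1:] = np.diff(ts)

    jk = j[kept]
    return pd.DataFrame(
        {
            "master_time": tm[kept],
            "slave_time": ts[jk],
            "anticipation": tm[kept] - ts[jk],
            "preceding_isi": slave_isi[jk],
        }
    )


def isi_histogram(isis: np.ndarray, edges: np.ndarray) -> ISIHistogram:
    """Histogram of ISIs over half-open bins [edge_i, edge_{i+1})."""
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    isis = np.asarray(isis, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    if len(isis):
        which = np.searchsorted(edges, isis, side="right") - 1
        ok = (which >= 0) & (which < len(counts)) & (isis < edges[-1])
        np.add.at(counts, which[ok], 1)
    return ISIHistogram(edges=edges, counts=counts)


def _best_1d_two_split(values: np.ndarray) -> tuple[float, float] | None:
    """Exact 2-means on sorted 1-D data: centers minimizing within-cluster SSE."""
    v = np.sort(values)
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return None
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v * v)])
    best, best_i = np.inf, None
    for i in range(1, n):  # split: v[:i] | v[i:]
        s1, q1 = csum[i], csq[i]
        s2, q2 = csum[n] - s1, csq[n] - q1
        sse = (q1 - s1 * s1 / i) + (q2 - s2 * s2 / (n - i))
        if sse < best - 1e-15:
            best, best_i = sse, i
    m1 = csum[best_i] / best_i
    m2 = (csum[n] - csum[best_i]) / (n - best_i)
    return m1, m2


def segment_bursts(
    train: SpikeTrain, isi_threshold: float | str = "auto"
) -> BurstSegmentation:
    """Split a spike train into bursts at ISIs exceeding a threshold.

    A new burst starts at every spike whose preceding ISI exceeds the
    threshold.  ``"auto"`` sets the threshold at the geometric mean of the
    two cluster centers of an exact 2-cluster split of the log-ISIs; if that
    split does not separate the ISIs into two scales (center ratio below 2)
    the train is treated as one burst and flagged degenerate.
    """
    if len(train) == 0:
        raise ValueError("cannot segment an empty spike train")
    isis = train.isis()
    degenerate = False
    if isinstance(isi_threshold, str):
        if isi_threshold != "auto":
            raise ValueError(f"unknown threshold mode {isi_threshold!r}")
        split = _best_1d_two_split(np.log(isis)) if len(isis) >= 2 else None
        if split is None or abs(split[1] - split[0]) < math.log(2.0):
            return BurstSegmentation(
                bursts=((0, len(train)),), isi_threshold=np.inf, degenerate=True
            )
        thr = math.exp(0.5 * (split[0] + split[1]))
    else:
        thr = float(isi_threshold)

    starts = [0] + [i + 1 for i, isi in enumerate(isis) if isi > thr]
    stops = starts[1:] + [len(train)]
    return BurstSegmentation(
        bursts=tuple(zip(starts, stops)), isi_threshold=thr, degenerate=degenerate
    )


@dataclass(frozen=True)
class AnticipationClusters:
    """Anticipation-vs-preceding-ISI scatter with 2-D histogram clusters.

    Clusters are connected components (8-connectivity) of occupied cells of
    a 2-D histogram over (ISI, anticipation).  ``summaries`` is one row per
    cluster, ordered by mean ISI: count, ISI range, anticipation range and
    means.
    """

    pairs: pd.DataFrame
    hist: np.ndarray
    isi_edges: np.ndarray
    anticipation_edges: np.ndarray
    labels: np.ndarray
    summaries: pd.DataFrame


def anticipation_vs_isi(table: pd.DataFrame, bins: int = 40) -> AnticipationClusters:
    """Correlate each matched slave spike's preceding ISI with its anticipation.

    Records without a preceding ISI (the slave's first spike) are dropped.
    The (ISI, anticipation) pairs are binned on a ``bins x bins`` grid over
    the observed range, and clusters are connected components of occupied
    cells; each cluster summary reports its spike count, ISI and anticipation
    ranges, and mean anticipation.
    """
    from scipy import ndimage

    if len(table) == 0:
        raise ValueError("anticipation table is empty")
    df = table.dropna(subset=["preceding_isi"]).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no records with a preceding ISI")
    isi = df["preceding_isi"].to_numpy()
    ant = df["anticipation"].to_numpy()
    hist, xe, ye = np.histogram2d(isi, ant, bins=bins)
    lab, n_lab = ndimage.label(hist > 0, structure=np.ones((3, 3), dtype=int))

    # map each pair to its cell's component label
    ix = np.clip(np.searchsorted(xe, isi, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, ant, side="right") - 1, 0, bins - 1)
    pair_label = lab[ix, iy]

    rows = []
    for c in range(1, n_lab + 1):
        m = pair_label == c
        rows.append(
            {
                "cluster": c,
                "count": int(m.sum()),
                "isi_min": isi[m].min(),
                "isi_max": isi[m].max(),
                "isi_mean": isi[m].mean(),
                "anticipation_min": ant[m].min(),
                "anticipation_max": ant[m].max(),
                "anticipation_mean": ant[m].mean(),
            }
        )
    summaries = (
        pd.DataFrame(rows).sort_values("isi_mean").reset_index(drop=True)
        if rows
        else pd.DataFrame()
    )
    return AnticipationClusters(
        pairs=df.assign(cluster=pair_label),
        hist=hist,
        isi_edges=xe,
        anticipation_edges=ye,
        labels=lab,
        summaries=summaries,
    )


def principal_clusters(
    clusters: AnticipationClusters, min_frac: float = 0.01, min_count: int = 5
) -> pd.DataFrame:
    """Cluster summaries excluding stray components.

    Components holding fewer than ``max(min_count, min_frac * n_pairs)``
    spikes are isolated outliers of the 2-D histogram, not the prominent
    ISI-anticipation groupings; this drops them, keeping the rows ordered
    by mean ISI (first row = fastest intra-burst spikes, last row = the
    burst-initiating spikes with the longest preceding ISIs).
    """
    s = clusters.summaries
    cut = max(min_count, int(min_frac * len(clusters.pairs)))
    return s[s["count"] >= cut].reset_index(drop=True)
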