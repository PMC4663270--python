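"""Causal-window plasticity of the slave -> X synapse.

A variant of spike-timing-dependent plasticity driven by the relative timing
of the two inputs converging on neuron X rather than by X's own output: if
the slave-origin spike reaches X before the master-origin spike, inside a
temporal window of half-width ``w`` centred on the master event, the synapse
is potentiated by ``r_i``; otherwise it is depressed by ``r_d``.  Updates are
amplitude-constant — they do not depend on the size of the time difference,
only on its sign and whether it falls inside the window.

Because the master and slave dynamics are independent of X (coupling is
strictly feed-forward onto X), the event sequence seen by the synapse equals
the master-slave anticipation table, and the weight trace can be computed
offline from that table.  The weight tracked is the non-negative magnitude
``g(t)`` of the (inhibitory) coupling, with ``g(0) = |k_SX|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

__all__ = [
    "PlasticityParams",
    "PlasticityTrace",
    "eligibility",
    "plasticity_trace",
    "window_sweep",
]

Variant = Literal["depress-outside", "ignore-outside"]


@dataclass(frozen=True)
class PlasticityParams:
    """Window half-width ``w`` (full width 2w), rates and initial weight."""

    w: float = 0.5
    r_i: float = 0.02
    r_d: float = 0.02 / 7
    g0: float = 3.0
    floor: float = 0.0
    variant: Variant = "depress-outside"

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("window half-width w must be >= 0")
        if self.r_i < 0 or self.r_d < 0:
            raise ValueError("rates r_i and r_d must be non-negative")
        if self.floor < 0 or self.g0 < self.floor:
            raise ValueError("need g0 >= floor >= 0")
        if self.variant not in ("depress-outside", "ignore-outside"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class PlasticityTrace:
    """Event-by-event weight evolution; one row per master-spike event."""

    events: pd.DataFrame  # columns: event_time, decision, weight
    initial_weight: float
    params: PlasticityParams

    @property
    def final_weight(self) -> float:
        if len(self.events) == 0:
            return self.initial_weight
        return float(self.events["weight"].iloc[-1])

    @property
    def net_change(self) -> float:
        return self.final_weight - self.initial_weight

    def counts(self) -> dict[str, int]:
        c = self.events["decision"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("potentiate", "depress", "no-change")}

    def to_csv(self, path_or_buf) -> None:
        self.events.to_csv(path_or_buf, index=False)


def eligibility(anticipation: float, params: PlasticityParams) -> str:
    """Decision for one matched spike pair.

    Potentiate iff the slave event precedes the master event within the
    window: ``0 <= anticipation <= w`` (both boundaries included).  Outside
    that, the default variant depresses; the ``ignore-outside`` variant
    leaves pairs with ``anticipation > w`` untouched (still depressing
    reversed pairs, anticipation < 0).
    """
    if 0.0 <= anticipation <= params.w:
        return "potentiate"
    if anticipation > params.w and params.variant == "ignore-outside":
        return "no-change"
    return "depress"


def plasticity_trace(
    table: pd.DataFrame, params: PlasticityParams
) -> PlasticityTrace:
    """Run the rule over an anticipation table in master-spike-time order.

    The weight moves by +r_i on potentiation and -r_d on depression, clipped
    at ``params.floor``.  An empty table yields a trace holding only the
    initial weight.
    """
    if len(table) == 0:
        return PlasticityTrace(
            events=pd.DataFrame(columns=["event_time", "decision", "weight"]),
            initial_weight=params.g0,
            params=params,
        )
    df = table.sort_values("master_time", kind="stable")
    g = params.g0
    rows = []
    for t, a in zip(df["master_time"].to_numpy(), df["anticipation"].to_numpy()):
        decision = eligibility(float(a), params)
        if decision == "potentiate":
            g += params.r_i
        elif decision == "depress":
            g = max(params.floor, g - params.r_d)
        rows.append((t, decision, g))
    return PlasticityTrace(
        events=pd.DataFrame(rows, columns=["event_time", "decision", "weight"]),
        initial_weight=params.g0,
        params=params,
    )


def window_sweep(
    table: pd.DataFrame,
    w_values: list[float] = (0.5, 0.4, 0.3),
    params: PlasticityParams | None = None,
) -> dict[float, float]:
    """Net weight change (final - initial) per window half-width."""
    from dataclasses import replace

    params = params or PlasticityParams()
    return {
        float(w): plasticity_trace(table, replace(params, w=float(w))).net_change
        for w in w_values
    }
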