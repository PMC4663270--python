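"""Hindmarsh-Rose neurons and the coupled network right-hand side.

The single neuron is the classic three-variable Hindmarsh-Rose model — a fast
membrane variable ``x``, a recovery variable ``y`` and a slow adaptation
current ``z`` — with the fast equation divided by a capacitance-like factor
``C`` that sets the neuron's intrinsic time scale.  A chain of unidirectionally
coupled neurons (master -> intermediaries -> slave), each slightly faster than
its driver (``C_m > C_1 > ... > C_n > C_s``), exhibits anticipating
synchronization: the slave fires its spikes *before* the master while staying
synchronized.  An optional convergent neuron X receives excitatory input from
the master and inhibitory input from the slave.

Coupling is diffusive: each directed edge (pre -> post, strength k) adds
``k * (x_pre - x_post)`` to the post-neuron's fast equation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "ChainSpec",
    "XNeuronSpec",
    "NetworkSpec",
    "hr_derivatives",
    "build_chain",
    "assemble_network",
]

#: column order of the per-neuron parameter matrix consumed by the integrator
PARAM_FIELDS = ("a", "b", "c", "d", "s", "r", "x_st", "J0", "C")


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one Hindmarsh-Rose neuron.

    Defaults are the standard chaotic-bursting parameter set: a=1, b=3, c=1,
    d=5, s=4, r=0.005, x_st=-1.6, J0=3.25, with unit capacitance.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    s: float = 4.0
    r: float = 0.005
    x_st: float = -1.6
    J0: float = 3.25
    C: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"NeuronParams.{name} must be finite, got {v!r}")
        if self.C <= 0:
            raise ValueError(f"capacitance C must be positive, got {self.C}")
        if self.r <= 0:
            raise ValueError(f"slow-variable rate r must be positive, got {self.r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)


def hr_derivatives(
    state: Sequence[float],
    params: NeuronParams,
    coupling_input: float = 0.0,
) -> tuple[float, float, float]:
    """Time derivatives (dx, dy, dz) of a single HR neuron.

    ``coupling_input`` is the summed diffusive input current; it enters the
    fast equation only, which is divided by the capacitance ``C``::

        dx = [y + x^2 (b - a x) - z + J0 + input] / C
        dy = c - d x^2 - y
        dz = r (s (x - x_st) - z)
    """
    x, y, z = state
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise ValueError(f"non-finite state {state!r}")
    if not math.isfinite(coupling_input):
        raise ValueError(f"non-finite coupling input {coupling_input!r}")
    p = params
    dx = (y + x * x * (p.b - p.a * x) - z + p.J0 + coupling_input) / p.C
    dy = p.c - p.d * x * x - y
    dz = p.r * (p.s * (x - p.x_st) - z)
    return (dx, dy, dz)


@dataclass(frozen=True)
class ChainSpec:
    """Master -> intermediaries -> slave chain with per-neuron capacitances.

    Anticipation requires each driven neuron to be faster than its driver,
    i.e. strictly decreasing capacitances along the chain.
    """

    n: int
    C_master: float
    C_slave: float
    C_intermediaries: tuple[float, ...]
    k_intermediaries: tuple[float, ...]
    k_slave: float

    def __post_init__(self) -> None:
        if self.n < 0 or self.n != len(self.C_intermediaries):
            raise ValueError("n must equal the number of intermediary capacitances")
        if len(self.k_intermediaries) != self.n:
            raise ValueError("need one coupling per intermediary")
        caps = (self.C_master, *self.C_intermediaries, self.C_slave)
        if any(not math.isfinite(c) for c in caps):
            raise ValueError("capacitances must be finite")
        if any(c2 <= 0 for c2 in caps):
            raise ValueError("capacitances must be positive")
        if any(hi <= lo for hi, lo in zip(caps, caps[1:])):
            raise ValueError(
                "anticipation precondition violated: capacitances must satisfy "
                "C_master > C_1 > ... > C_n > C_slave"
            )
        if not all(math.isfinite(k) for k in (*self.k_intermediaries, self.k_slave)):
            raise ValueError("couplings must be finite")


def build_chain(
    n: int,
    C_master: float = 1.0,
    C_slave: float = 0.7,
    k: float = 1.7,
) -> ChainSpec:
    """Chain with ``n`` intermediaries whose capacitances are equispaced
    strictly inside the open interval ``(C_slave, C_master)``.

    The interval is split into ``n + 1`` equal steps so that neither endpoint
    is duplicated: ``C_j = C_master - j (C_master - C_slave) / (n + 1)``.
    All couplings are set to ``k``.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not (C_master > C_slave > 0):
        raise ValueError(
            f"anticipation requires C_master > C_slave > 0, "
            f"got C_master={C_master}, C_slave={C_slave}"
        )
    step = (C_master - C_slave) / (n + 1)
    caps = tuple(C_master - j * step for j in range(1, n + 1))
    return ChainSpec(
        n=n,
        C_master=C_master,
        C_slave=C_slave,
        C_intermediaries=caps,
        k_intermediaries=(k,) * n,
        k_slave=k,
    )


@dataclass(frozen=True)
class XNeuronSpec:
    """Convergent neuron X driven by master (k_MX) and slave (k_SX).

    Positive coupling models an excitatory afferent, negative an inhibitory
    one; no sign is enforced because the no-anticipation control swaps them.
    """

    J0X: float = 1.3
    C_X: float = 1.0
    k_MX: float = 3.0
    k_SX: float = -3.0

    def __post_init__(self) -> None:
        for name in ("J0X", "C_X", "k_MX", "k_SX"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"XNeuronSpec.{name} must be finite")
        if self.C_X <= 0:
            raise ValueError("C_X must be positive")

    def swapped(self) -> "XNeuronSpec":
        """Exchange k_MX and k_SX (the 'no anticipation' control)."""
        return replace(self, k_MX=self.k_SX, k_SX=self.k_MX)


@dataclass(frozen=True)
class NetworkSpec:
    """Directed network of HR neurons: an ordered neuron list plus edges.

    ``edges`` are (pre_index, post_index, strength) triples; each contributes
    ``k * (x_pre - x_post)`` to the post-neuron's fast equation.  The state
    vector stacks (x, y, z) blocks in neuron order, so its dimension is
    ``3 * n_neurons``.
    """

    names: tuple[str, ...]
    neurons: tuple[NeuronParams, ...]
    edges: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.neurons):
            raise ValueError("one name per neuron required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("neuron names must be unique")
        n = len(self.neurons)
        for pre, post, k in self.edges:
            if not (0 <= pre < n and 0 <= post < n):
                raise ValueError(f"edge ({pre}, {post}) out of range for {n} neurons")
            if pre == post:
                raise ValueError("self-coupling is not allowed")
            if not math.isfinite(k):
                raise ValueError("edge strength must be finite")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def dim(self) -> int:
        return 3 * len(self.neurons)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no neuron named {name!r}; have {self.names}") from None

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(params matrix (N, 9), pre, post, k) in the integrator's layout."""
        P = np.array([p.as_array() for p in self.neurons], dtype=float)
        if self.edges:
            pre, post, k = (np.array(col) for col in zip(*self.edges))
        else:
            pre = post = np.zeros(0, dtype=np.int64)
            k = np.zeros(0, dtype=float)
        return P, pre.astype(np.int64), post.astype(np.int64), k.astype(float)

    def rhs(self):
        """Vectorized numpy right-hand side ``f(t, y) -> dy``."""
        P, pre, post, k = self.arrays()
        a, b, c, d, s, r, x_st, J0, C = P.T.copy()
        n = self.n_neurons

        def f(t: float, y: np.ndarray) -> np.ndarray:
            x = y[0::3]
            v = y[1::3]
            z = y[2::3]
            u = np.zeros(n)
            if len(k):
                np.add.at(u, post, k * (x[pre] - x[post]))
            out = np.empty_like(y)
            out[0::3] = (v + x * x * (b - a * x) - z + J0 + u) / C
            out[1::3] = c - d * x * x - v
            out[2::3] = r * (s * (x - x_st) - z)
            return out

        return f

    # -- JSON round trip: experiment presets are data, not code --------------

    def to_json(self) -> str:
        doc = {
            "neurons": [
                {"name": nm, **{f: getattr(p, f) for f in PARAM_FIELDS}}
                for nm, p in zip(self.names, self.neurons)
            ],
            "edges": [
                {"pre": self.names[i], "post": self.names[j], "k": k}
                for i, j, k in self.edges
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        doc = json.loads(text)
        names = tuple(n["name"] for n in doc["neurons"])
        neurons = tuple(
            NeuronParams(**{f: n[f] for f in PARAM_FIELDS}) for n in doc["neurons"]
        )
        idx = {nm: i for i, nm in enumerate(names)}
        edges = tuple(
            (idx[e["pre"]], idx[e["post"]], float(e["k"])) for e in doc["edges"]
        )
        return cls(names=names, neurons=neurons, edges=edges)


def assemble_network(
    chain: ChainSpec,
    x_spec: XNeuronSpec | None = None,
    base: NeuronParams | None = None,
) -> NetworkSpec:
    """Stack the chain (and optional X neuron) into a :class:`NetworkSpec`.

    Neuron order is master, i1..in, slave[, X].  The master receives no input
    (unidirectional drive); X receives feed-forward input from master and
    slave only and never feeds back.
    """
    base = base or NeuronParams()
    names = ["master"] + [f"i{j}" for j in range(1, chain.n + 1)] + ["slave"]
    neurons = [replace(base, C=chain.C_master)]
    neurons += [replace(base, C=c) for c in chain.C_intermediaries]
    neurons.append(replace(base, C=chain.C_slave))

    edges: list[tuple[int, int, float]] = []
    ks = list(chain.k_intermediaries) + [chain.k_slave]
    for j, k in enumerate(ks):
        edges.append((j, j + 1, k))  # driver j -> driven j+1

    if x_spec is not None:
        names.append("X")
        neurons.append(replace(base, C=x_spec.C_X, J0=x_spec.J0X))
        i_x = len(names) - 1
        edges.append((0, i_x, x_spec.k_MX))            # master -> X
        edges.append((i_x - 1, i_x, x_spec.k_SX))      # slave -> X

    return NetworkSpec(names=tuple(names), neurons=tuple(neurons), edges=tuple(edges))
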