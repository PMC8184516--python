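"""Network topologies of the in-vitro rostrocaudal circuit.

The in-vitro gene-regulatory network has five nodes: the three brain-region
fate nodes FB (forebrain), MB (midbrain), HB (hindbrain), the kinase GSK3
and the external GSK3 inhibitor CT.  Two interactions are fixed by the
biology of the experiment: CT represses GSK3 (that is what the inhibitor
does) and GSK3 activates itself (required for a non-trivial steady state
under constant repression).  The remaining twelve candidate interactions --
the three self-interactions of FB, MB, HB plus all nine directed
interactions among {FB, MB, HB} and from GSK3 onto each fate node -- are
each either an activation or a repression, giving 2**12 = 4096 candidate
topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

ACTIVATION = 1
REPRESSION = -1
ABSENT = 0

_SIGN_NAMES = {ACTIVATION: "activation", REPRESSION: "repression", ABSENT: "absent"}
_SIGN_FROM_NAME = {v: k for k, v in _SIGN_NAMES.items()}

NODES = ("FB", "MB", "HB", "GSK3", "CT")

#: Documented enumeration order of the twelve variable interactions,
#: as (target, source) pairs.  Bit i of the enumeration index addresses
#: VARIABLE_EDGES[i]; a set bit means activation, a cleared bit repression.
VARIABLE_EDGES = (
    ("FB", "FB"),
    ("FB", "GSK3"),
    ("FB", "MB"),
    ("FB", "HB"),
    ("MB", "MB"),
    ("MB", "FB"),
    ("MB", "HB"),
    ("MB", "GSK3"),
    ("HB", "HB"),
    ("HB", "FB"),
    ("HB", "MB"),
    ("HB", "GSK3"),
)

#: Immutable interactions: CT represses GSK3, GSK3 activates itself.
FIXED_EDGES = {
    ("GSK3", "CT"): REPRESSION,
    ("GSK3", "GSK3"): ACTIVATION,
}

#: Full edge universe used by :func:`topology_score`.
ALL_EDGES = VARIABLE_EDGES + tuple(FIXED_EDGES)


@dataclass(frozen=True)
class Topology:
    """A sign assignment for every edge of the in-vitro network.

    Parameters
    ----------
    signs
        Mapping ``(target, source) -> sign`` for the variable edges, where
        sign is one of ``ACTIVATION`` (+1), ``REPRESSION`` (-1) or
        ``ABSENT`` (0).  Unlisted variable edges default to ``ABSENT``.
        The two fixed edges are always present and cannot be overridden.
    """

    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        for edge, sign in self.signs.items():
            if edge in FIXED_EDGES:
                if sign != FIXED_EDGES[edge]:
                    raise ValueError(f"fixed edge {edge} cannot be overridden")
            elif edge not in VARIABLE_EDGES:
                raise ValueError(f"unknown edge {edge}")
            if sign not in (_SIGN_NAMES):
                raise ValueError(f"invalid sign {sign!r} for edge {edge}")

    def sign(self, target: str, source: str) -> int:
        """Sign of the interaction ``source -> target`` (0 if absent)."""
        edge = (target, source)
        if edge in FIXED_EDGES:
            return FIXED_EDGES[edge]
        return self.signs.get(edge, ABSENT)

    def edges(self) -> dict[tuple[str, str], int]:
        """All non-absent edges, fixed ones included."""
        out = {e: s for e, s in self.signs.items() if s != ABSENT}
        out.update(FIXED_EDGES)
        return out

    def incoming(self, target: str) -> list[tuple[str, int]]:
        """``(source, sign)`` pairs of non-absent edges into ``target``."""
        return [
            (src, s) for (tgt, src), s in self.edges().items() if tgt == target
        ]

    def index(self) -> int:
        """Enumeration index (only defined if no variable edge is absent)."""
        idx = 0
        for i, edge in enumerate(VARIABLE_EDGES):
            s = self.signs.get(edge, ABSENT)
            if s == ABSENT:
                raise ValueError(f"edge {edge} is absent; index undefined")
            if s == ACTIVATION:
                idx |= 1 << i
        return idx

    def bitstring(self) -> str:
        """12-character string over {a, r, .} in VARIABLE_EDGES order."""
        chars = {ACTIVATION: "a", REPRESSION: "r", ABSENT: "."}
        return "".join(chars[self.signs.get(e, ABSENT)] for e in VARIABLE_EDGES)

    def replace(self, **edge_signs) -> "Topology":
        raise TypeError("Topology is immutable; build a new one")

    @classmethod
    def from_index(cls, idx: int) -> "Topology":
        """Topology number ``idx`` of the canonical binary enumeration."""
        if not 0 <= idx < 2 ** len(VARIABLE_EDGES):
            raise ValueError(f"index {idx} out of range")
        signs = {
            edge: (ACTIVATION if idx >> i & 1 else REPRESSION)
            for i, edge in enumerate(VARIABLE_EDGES)
        }
        return cls(signs)

    @classmethod
    def consensus(cls) -> "Topology":
        """The data-selected tristable-switch topology.

        GSK3 activates FB and represses MB and HB; FB, MB, HB are mutually
        repressive; MB and HB self-activate; FB does not self-interact.
        """
        return cls(
            {
                ("FB", "GSK3"): ACTIVATION,
                ("FB", "MB"): REPRESSION,
                ("FB", "HB"): REPRESSION,
                ("MB", "MB"): ACTIVATION,
                ("MB", "FB"): REPRESSION,
                ("MB", "HB"): REPRESSION,
                ("MB", "GSK3"): REPRESSION,
                ("HB", "HB"): ACTIVATION,
                ("HB", "FB"): REPRESSION,
                ("HB", "MB"): REPRESSION,
                ("HB", "GSK3"): REPRESSION,
            }
        )


def enumerate_topologies(edges: tuple = VARIABLE_EDGES) -> Iterator[Topology]:
    """Yield every activation/repression assignment of the variable edges.

    The enumeration is a binary count over ``edges`` (default: the full
    twelve-interaction universe, yielding 4096 topologies); bit i set means
    ``edges[i]`` is an activation.  Edges not in ``edges`` are left absent.
    """
    for e in edges:
        if e not in VARIABLE_EDGES:
            raise ValueError(f"unknown variable edge {e}")
    m = len(edges)
    for idx in range(2 ** m):
        signs = {
            edge: (ACTIVATION if idx >> i & 1 else REPRESSION)
            for i, edge in enumerate(edges)
        }
        yield Topology(signs)


def topology_score(a: Topology, b: Topology) -> float:
    """Fraction of identically assigned interactions between two topologies.

    Counts every position of the 14-edge universe (twelve variable plus two
    fixed interactions), "absent" included as an assignment: the score is 1
    for identical topologies and 0 when every interaction differs.
    """
    same = sum(1 for t, s in ALL_EDGES if a.sign(t, s) == b.sign(t, s))
    return same / len(ALL_EDGES)


def sign_name(sign: int) -> str:
    return _SIGN_NAMES[sign]


def sign_from_name(name: str) -> int:
    return _SIGN_FROM_NAME[name]
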