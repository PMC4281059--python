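"""Network topology and the (graph, functions) model pair.

A topology is a directed acyclic graph over n genes in which every node has
at most two parents (regulators).  Nodes with no parents are *roots* and are
modelled as independent Bernoulli variables; every non-root carries a
non-degenerate Boolean function of its parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .functions import BooleanFunction

__all__ = ["Topology", "NetworkModel", "is_valid_topology", "topological_order"]


@dataclass(frozen=True)
class Topology:
    """Per-node parent sets; parents are stored sorted ascending."""

    n: int
    parents: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.parents) != self.n:
            raise ValueError("parents must have one entry per node")
        for i, pa in enumerate(self.parents):
            for p in pa:
                if not (0 <= p < self.n):
                    raise ValueError(f"node {i}: parent index {p} out of range")
            if tuple(sorted(set(pa))) != tuple(pa):
                raise ValueError(f"node {i}: parents must be sorted and distinct")

    def roots(self) -> Tuple[int, ...]:
        return tuple(i for i, pa in enumerate(self.parents) if not pa)

    def in_degree(self, i: int) -> int:
        return len(self.parents[i])


def is_valid_topology(t: Topology) -> bool:
    """True iff acyclic with in-degree <= 2, no self-loops, no duplicates.

    Acyclicity is checked with Kahn's algorithm (iterated root removal).
    """
    for i, pa in enumerate(t.parents):
        if len(pa) > 2 or i in pa or len(set(pa)) != len(pa):
            return False
    return _kahn_order(t) is not None


def topological_order(t: Topology) -> Tuple[int, ...]:
    """An ordering placing every node after all of its parents.

    Deterministic: among available nodes the smallest index goes first.
    """
    order = _kahn_order(t)
    if order is None:
        raise ValueError("topology contains a directed cycle")
    return order


def _kahn_order(t: Topology) -> Optional[Tuple[int, ...]]:
    import heapq

    indeg = [len(pa) for pa in t.parents]
    children: list[list[int]] = [[] for _ in range(t.n)]
    for i, pa in enumerate(t.parents):
        for p in pa:
            children[p].append(i)
    heap = [i for i in range(t.n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        u = heapq.heappop(heap)
        order.append(u)
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, v)
    return tuple(order) if len(order) == t.n else None


@dataclass(frozen=True)
class NetworkModel:
    """A topology together with one Boolean function per non-root node."""

    topology: Topology
    functions: Tuple[Optional[BooleanFunction], ...]

    def __post_init__(self) -> None:
        t = self.topology
        if len(self.functions) != t.n:
            raise ValueError("functions must have one entry per node")
        for i, f in enumerate(self.functions):
            k = t.in_degree(i)
            if k == 0:
                if f is not None:
                    raise ValueError(f"root node {i} must not carry a function")
            else:
                if f is None:
                    raise ValueError(f"non-root node {i} needs a function")
                if f.arity != k:
                    raise ValueError(
                        f"node {i}: function arity {f.arity} != in-degree {k}"
                    )

    @property
    def n(self) -> int:
        return self.topology.n

    def state_key(self) -> Tuple[Tuple[Tuple[int, ...], Tuple[int, ...]], ...]:
        """Hashable canonical form: per node (parents, truth table)."""
        return tuple(
            (pa, self.functions[i].table if self.functions[i] else ())
            for i, pa in enumerate(self.topology.parents)
        )
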