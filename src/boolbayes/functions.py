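"""Boolean truth-table algebra.

A regulatory relation is a Boolean function of one or two parent genes,
stored as a canonical truth table.  Only *non-degenerate* functions are
admitted: the output must depend on every input.  With in-degree capped at
two this leaves 2 one-input functions (identity, NOT) and 10 two-input
functions (AND, OR, XOR, their negations, and the four and/or forms with
exactly one negated input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Tuple

__all__ = [
    "BooleanFunction",
    "enumerate_functions",
    "apply_function",
    "is_nondegenerate",
]


@dataclass(frozen=True)
class BooleanFunction:
    """A non-degenerate Boolean function of arity 1 or 2.

    The truth table is indexed by the parent value pattern in lexicographic
    order: for arity 2, index = 2*v_first + v_second, where "first" is the
    smaller-index parent under the sorted parent-set convention.
    Equality and hashing use (arity, table) only; the label is cosmetic.
    """

    arity: int
    table: Tuple[int, ...]
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.arity not in (1, 2):
            raise ValueError(f"arity must be 1 or 2, got {self.arity}")
        if len(self.table) != 2**self.arity:
            raise ValueError(
                f"table length {len(self.table)} does not match arity {self.arity}"
            )
        if any(b not in (0, 1) for b in self.table):
            raise ValueError("table entries must be bits")
        if not is_nondegenerate(self.arity, self.table):
            raise ValueError(f"degenerate truth table {self.table}")

    def __call__(self, parent_values: Tuple[int, ...]) -> int:
        return apply_function(self, parent_values)


def is_nondegenerate(arity: int, table: Tuple[int, ...]) -> bool:
    """True iff the output depends on every input."""
    if arity == 1:
        return table in ((0, 1), (1, 0))
    if arity == 2:
        # depends on first input: flipping it changes the output somewhere
        dep_a = table[0] != table[2] or table[1] != table[3]
        dep_b = table[0] != table[1] or table[2] != table[3]
        return dep_a and dep_b
    raise ValueError(f"arity must be 1 or 2, got {arity}")


# canonical labels; a = smaller-index parent, b = larger-index parent
_LABELS_2 = {
    (0, 0, 0, 1): "a AND b",
    (0, 0, 1, 0): "a AND NOT b",
    (0, 1, 0, 0): "NOT a AND b",
    (0, 1, 1, 0): "a XOR b",
    (0, 1, 1, 1): "a OR b",
    (1, 0, 0, 0): "NOT (a OR b)",
    (1, 0, 0, 1): "NOT (a XOR b)",
    (1, 0, 1, 1): "a OR NOT b",
    (1, 1, 0, 1): "NOT a OR b",
    (1, 1, 1, 0): "NOT (a AND b)",
}
_LABELS_1 = {(0, 1): "a", (1, 0): "NOT a"}


@lru_cache(maxsize=None)
def enumerate_functions(arity: int) -> Tuple[BooleanFunction, ...]:
    """All distinct non-degenerate functions of the given arity.

    Returned in a fixed deterministic order (ascending truth table).
    Arity 0 (a root node) has no function and returns the empty tuple.
    """
    if arity == 0:
        return ()
    if arity not in (1, 2):
        raise ValueError(f"arity must be 0, 1 or 2, got {arity}")
    labels = _LABELS_1 if arity == 1 else _LABELS_2
    out = []
    for table in sorted(product((0, 1), repeat=2**arity)):
        if is_nondegenerate(arity, table):
            out.append(BooleanFunction(arity, table, labels[table]))
    return tuple(out)


def apply_function(f: BooleanFunction, parent_values: Tuple[int, ...]) -> int:
    """Evaluate ``f`` on a bit pattern of its parents."""
    if len(parent_values) != f.arity:
        raise ValueError(
            f"expected {f.arity} parent values, got {len(parent_values)}"
        )
    idx = 0
    for v in parent_values:
        idx = 2 * idx + v
    return f.table[idx]
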