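"""Modular-arithmetic helpers for circular chromosomes.

All intervals are 0-based, half-open arcs ``[start, start+length)`` taken
modulo the chromosome length ``L``.  An arc is stored as ``(start, length)``
with ``0 <= start < L`` and ``0 < length <= L``.
"""

from __future__ import annotations


def norm(pos: float, L: int) -> float:
    """Normalise a coordinate into [0, L)."""
    return pos % L


def arc(start: float, length: float, L: int) -> tuple[float, float]:
    if length <= 0 or length > L:
        raise ValueError(f"arc length {length} outside (0, {L}]")
    return (start % L, length)


def forward_gap(a: float, b: float, direction: int, L: int) -> float:
    """Distance from ``a`` to ``b`` travelling in ``direction`` (+1/-1)."""
    return ((b - a) * direction) % L


def arc_contains(a: tuple[float, float], pos: float, L: int) -> bool:
    start, length = a
    return ((pos - start) % L) < length


def arcs_overlap(a: tuple[float, float], b: tuple[float, float], L: int) -> bool:
    """True iff two circular half-open arcs share at least one point."""
    (a0, la), (b0, lb) = a, b
    return ((b0 - a0) % L) < la or ((a0 - b0) % L) < lb
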