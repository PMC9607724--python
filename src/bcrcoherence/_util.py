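"""Small internal helpers shared across modules."""

from __future__ import annotations

from typing import Hashable, List, Sequence

from .errors import LengthMismatch


class DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self, items: Sequence[Hashable]):
        self._parent = {x: x for x in items}
        self._size = {x: 1 for x in items}

    def find(self, x: Hashable) -> Hashable:
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, a: Hashable, b: Hashable) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self._size[ra] < self._size[rb]:
            ra, rb = rb, ra
        self._parent[rb] = ra
        self._size[ra] += self._size[rb]

    def groups(self) -> List[List[Hashable]]:
        """Members grouped by root, in first-seen order within and across groups."""
        by_root = {}
        for x in self._parent:
            by_root.setdefault(self.find(x), []).append(x)
        return list(by_root.values())


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise LengthMismatch(f"lengths differ: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def fraction_identity(a: str, b: str) -> float:
    """Positional identity (0..1) of two equal-length strings."""
    if len(a) != len(b):
        raise LengthMismatch(f"lengths differ: {len(a)} vs {len(b)}")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)
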