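"""Sire/dam pedigree as a directed acyclic graph.

Unknown parents are ``None``; founders are individuals with both parents
unknown and carry inbreeding coefficient 0 unless overridden via
``founder_f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache


class PedigreeCycleError(ValueError):
    """Raised when an individual is its own ancestor."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("pedigree cycle: " + " -> ".join(cycle))


@dataclass
class Pedigree:
    """Mapping id -> (sire or None, dam or None), validated acyclic."""

    parents: dict[str, tuple[str | None, str | None]]
    founder_f: dict[str, float] = field(default_factory=dict)
    #: optional sex labels ('M'/'F'), populated by the simulator
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # parents referenced but not listed become implicit founders
        for sire, dam in list(self.parents.values()):
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.parents, WHITE)
        for start in self.parents:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            path: list[str] = []
            while stack:
                node, pi = stack[-1]
                if pi == 0:
                    color[node] = GREY
                    path.append(node)
                parents = [p for p in self.parents[node] if p is not None]
                if pi < len(parents):
                    stack[-1] = (node, pi + 1)
                    nxt = parents[pi]
                    if color[nxt] == GREY:
                        raise PedigreeCycleError(path[path.index(nxt):] + [nxt])
                    if color[nxt] == WHITE:
                        stack.append((nxt, 0))
                else:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()

    @property
    def founders(self) -> set[str]:
        return {i for i, (s, d) in self.parents.items() if s is None and d is None}

    @property
    def individuals(self) -> list[str]:
        return list(self.parents)

    def sire(self, ind: str) -> str | None:
        return self.parents[ind][0]

    def dam(self, ind: str) -> str | None:
        return self.parents[ind][1]

    def depth(self, ind: str) -> int:
        """Generation number: 0 for founders, 1 + max(parent depths) otherwise."""
        return self._depth_cached()(ind)

    def _depth_cached(self):
        if not hasattr(self, "_depth_fn"):
            @lru_cache(maxsize=None)
            def _depth(i: str) -> int:
                s, d = self.parents[i]
                ds = [_depth(p) for p in (s, d) if p is not None]
                return 1 + max(ds) if ds else 0
            self._depth_fn = _depth
        return self._depth_fn

    def topological_order(self) -> list[str]:
        """Individuals sorted parents-before-offspring."""
        return sorted(self.parents, key=lambda i: (self.depth(i), i))

    def max_depth(self) -> int:
        return max((self.depth(i) for i in self.parents), default=0)
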