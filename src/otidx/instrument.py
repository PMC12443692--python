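"""Operation counting for hardware-independent complexity measurements."""

from __future__ import annotations

__all__ = ["OpCounter"]


class OpCounter:
    """Named monotone counters attached to one algorithm run.

    Counts are the normative performance signal (wall-clock is not): node
    visits, membership tests, descendant checks, emissions, and so on are
    incremented (often batched) by the algorithms and summed by
    :meth:`total`.  Deterministic for a fixed input and algorithm.
    """

    def __init__(self, n: int = 0, sigma: int = 0):
        self.n = n
        self.sigma = sigma
        self.counts: dict = {}

    def add(self, name: str, k: int = 1) -> None:
        if k < 0:
            raise ValueError("counters are monotone")
        self.counts[name] = self.counts.get(name, 0) + k

    def total(self, names=None) -> int:
        if names is None:
            return sum(self.counts.values())
        return sum(self.counts.get(name, 0) for name in names)

    def __getitem__(self, name: str) -> int:
        return self.counts.get(name, 0)

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join("%s=%d" % kv for kv in sorted(self.counts.items()))
        return "OpCounter(n=%d, %s)" % (self.n, body)
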