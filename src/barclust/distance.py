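"""Exact Levenshtein distances between barcodes and the neighbor index.

Distances are unit-cost edit distances computed with edlib (myers bit-vector
algorithm) with an early cutoff at ``max_ed`` where applicable; results are
exact, and the test suite checks them against a textbook DP oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

from .errors import ConfigError


def levenshtein(a: str, b: str, max_ed: Optional[int] = None) -> int:
    """Unit-cost Levenshtein distance.

    With ``max_ed`` given, any distance greater than ``max_ed`` is reported
    as ``max_ed + 1`` (cheap banded computation with early termination).
    """
    if a == b:
        return 0
    k = -1 if max_ed is None else max_ed
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    if d == -1:
        return max_ed + 1
    return d


@dataclass(frozen=True)
class BarcodeNeighborIndex:
    """All pairs of distinct barcodes within ``max_ed`` of each other.

    ``neighbors[b]`` maps each neighbor of ``b`` to its distance; the
    structure is symmetric and contains no self-pairs.
    """

    max_ed: int
    neighbors: dict[str, dict[str, int]]

    def neighbors_of(self, barcode: str) -> dict[str, int]:
        return self.neighbors.get(barcode, {})

    def distance(self, a: str, b: str) -> Optional[int]:
        """Distance if within ``max_ed`` (0 for equal strings), else None."""
        if a == b:
            return 0
        return self.neighbors.get(a, {}).get(b)


def build_neighbor_index(barcodes: Iterable[str], max_ed: int) -> BarcodeNeighborIndex:
    """All-pairs neighbor search over distinct barcodes.

    A length-difference prefilter skips pairs that cannot be within
    ``max_ed``; the result is independent of input order.
    """
    if max_ed < 1:
        raise ConfigError("max_ed must be >= 1 for neighbor indexing")
    distinct = sorted(set(barcodes))
    neighbors: dict[str, dict[str, int]] = {b: {} for b in distinct}
    for ia, a in enumerate(distinct):
        for b in distinct[ia + 1 :]:
            if abs(len(a) - len(b)) > max_ed:
                continue
            d = levenshtein(a, b, max_ed=max_ed)
            if 1 <= d <= max_ed:
                neighbors[a][b] = d
                neighbors[b][a] = d
    return BarcodeNeighborIndex(max_ed=max_ed, neighbors=neighbors)
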