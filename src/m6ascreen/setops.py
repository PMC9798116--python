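"""Venn-style gene-set intersections used to nominate shared candidates.

Gene identity is the symbol string after whitespace trimming, case-sensitive.
Region counts are keyed by membership pattern over the input sets in order
('110' = in the first two sets, not the third), the machine-readable analogue
of a Venn diagram.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

from .errors import M6AScreenError

logger = logging.getLogger(__name__)


def _clean(name: str, genes: Iterable[str]) -> set[str]:
    items = [str(g).strip() for g in genes]
    unique = set(items)
    if len(unique) < len(items):
        logger.warning("set %r: %d duplicate symbols collapsed", name, len(items) - len(unique))
    return unique


def intersect_sets(named_sets: Mapping[str, Iterable[str]]) -> tuple[set[str], dict[str, int]]:
    """Exact intersection of 2-3 named gene sets plus all Venn region counts.

    Returns ``(intersection, regions)`` where ``regions`` maps membership
    patterns (see module docstring) to cardinalities. Region counts partition
    the union.
    """
    if not 2 <= len(named_sets) <= 3:
        raise M6AScreenError(f"intersect_sets takes 2-3 sets, got {len(named_sets)}")
    names = list(named_sets)
    sets = [_clean(n, named_sets[n]) for n in names]
    intersection = set.intersection(*sets)
    union = set.union(*sets)
    regions: dict[str, int] = {}
    for pattern in range(1, 2 ** len(sets)):
        bits = [(pattern >> (len(sets) - 1 - i)) & 1 for i in range(len(sets))]
        region = union.copy()
        for s, bit in zip(sets, bits):
            region = region & s if bit else region - s
        regions["".join(map(str, bits))] = len(region)
    return intersection, regions
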