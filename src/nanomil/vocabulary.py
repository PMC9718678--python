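"""Fivemer sequence space around DRACH centers.

m6A occurs at the central A of DRACH motifs (D = A/G/T, R = A/G, H = A/C/T,
written in the DNA alphabet that eventalign emits).  A site model that looks
at the centered fivemer plus ``w`` flanking fivemers only ever encounters
fivemers whose overlap with the DRACH window is constrained; the embedding
vocabulary is the exact enumeration of those fivemers.  For the default
flank width ``w = 1`` this gives 18 center motifs plus 24 upstream and 24
downstream neighbours, 66 fivemers in total.
"""

from __future__ import annotations

import hashlib
from itertools import product
from typing import Iterable

BASES = ("A", "C", "G", "T")

#: allowed bases per DRACH slot, upstream to downstream
DRACH_SLOTS = (("A", "G", "T"), ("A", "G"), ("A",), ("C",), ("A", "C", "T"))


def drach_motifs() -> list[str]:
    """All fivemers matching DRACH, sorted lexicographically."""
    return sorted("".join(m) for m in product(*DRACH_SLOTS))


def is_drach(fivemer: str) -> bool:
    if len(fivemer) != 5:
        return False
    return all(b in slot for b, slot in zip(fivemer, DRACH_SLOTS))


class FivemerVocabulary:
    """Ordered fivemer -> index mapping with loud out-of-vocabulary failure."""

    def __init__(self, fivemers: Iterable[str]):
        fivemers = list(fivemers)
        if len(set(fivemers)) != len(fivemers):
            raise ValueError("duplicate fivemers in vocabulary")
        for f in fivemers:
            if len(f) != 5 or any(b not in BASES for b in f):
                raise ValueError(f"invalid fivemer {f!r}")
        self.fivemers: tuple[str, ...] = tuple(fivemers)
        self._index = {f: i for i, f in enumerate(self.fivemers)}

    def index(self, fivemer: str) -> int:
        try:
            return self._index[fivemer]
        except KeyError:
            raise KeyError(
                f"fivemer {fivemer!r} is not in the {len(self)}-entry vocabulary"
            ) from None

    def __len__(self) -> int:
        return len(self.fivemers)

    def __contains__(self, fivemer: str) -> bool:
        return fivemer in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, FivemerVocabulary) and self.fivemers == other.fivemers

    @property
    def checksum(self) -> str:
        return hashlib.sha256(",".join(self.fivemers).encode()).hexdigest()[:16]


def window_vocabulary(flank_width: int = 1) -> FivemerVocabulary:
    """Enumerate every fivemer that can appear at offsets -w..w of a DRACH center.

    The fivemer reported at offset ``d`` covers sequence positions
    ``c - 2 + d .. c + 2 + d`` around the modified base ``c``; positions
    falling inside the DRACH window are constrained to its slots, the rest
    are free.
    """
    if flank_width < 0:
        raise ValueError("flank_width must be >= 0")
    seen: set[str] = set()
    for d in range(-flank_width, flank_width + 1):
        slots = []
        for j in range(5):
            t = d + j
            slots.append(DRACH_SLOTS[t] if 0 <= t <= 4 else BASES)
        seen.update("".join(m) for m in product(*slots))
    return FivemerVocabulary(sorted(seen))
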