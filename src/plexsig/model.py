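"""Core domain types for multiplex chromatin-interaction data.

A *chromatin complex* is the set of genomic fragments captured under one
barcode (a ChIA-Drop GEM or a SPRITE cluster).  All statistics downstream
are built from the vector of neighboring fragment-to-fragment (F2F)
distances of a complex: ``x_f2f[i] = start(frag[i+1]) - end(frag[i])``,
their sum ``d_tot`` and the normalized probability vector ``p_f2f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicFragment",
    "ChromatinComplex",
    "DistanceProfile",
    "distance_profile",
]


@dataclass(frozen=True, slots=True, order=True)
class GenomicFragment:
    """A mapped fragment in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("fragment chromosome name must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"fragment start must be < end, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError(f"fragment start must be >= 0, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _merge_sorted(frags: list[GenomicFragment]) -> tuple[GenomicFragment, ...]:
    """Merge overlapping or book-ended fragments (input sorted by start)."""
    merged: list[GenomicFragment] = []
    for f in frags:
        if merged and f.start <= merged[-1].end:
            last = merged[-1]
            if f.end > last.end:
                merged[-1] = GenomicFragment(last.chrom, last.start, f.end)
        else:
            merged.append(f)
    return tuple(merged)


@dataclass(slots=True)
class ChromatinComplex:
    """An intra-chromosomal complex: ordered, non-overlapping fragments.

    ``category`` tracks the test state assigned by the distance or
    enrichment test (``pass1``/``fail1``/``defer``/``pass2``/``fail2``/...),
    ``parent_id`` records split lineage when a multiplet was separated.
    """

    id: str
    fragments: tuple[GenomicFragment, ...]
    category: str = "unassigned"
    raw_p: float | None = None
    adj_p: float | None = None
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"complex {self.id!r} has no fragments")
        chroms = {f.chrom for f in self.fragments}
        if len(chroms) > 1:
            raise ValueError(
                f"complex {self.id!r} spans chromosomes {sorted(chroms)}; "
                "split per-chromosome at parse time"
            )
        starts = [f.start for f in self.fragments]
        if starts != sorted(starts):
            raise ValueError(f"fragments of complex {self.id!r} are not sorted")
        for a, b in zip(self.fragments, self.fragments[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"fragments of complex {self.id!r} overlap; merge at parse time"
                )

    @classmethod
    def from_fragments(
        cls,
        cid: str,
        fragments: Iterable[GenomicFragment],
        merge: bool = True,
        **kwargs,
    ) -> "ChromatinComplex":
        """Build a complex, sorting and (by default) merging overlapping or
        book-ended fragments."""
        frags = sorted(fragments, key=lambda f: (f.start, f.end))
        if merge:
            frags = list(_merge_sorted(frags))
        return cls(cid, tuple(frags), **kwargs)

    @property
    def n(self) -> int:
        """Number of fragments (the fragment class F_j index)."""
        return len(self.fragments)

    @property
    def chrom(self) -> str:
        return self.fragments[0].chrom

    @property
    def span_start(self) -> int:
        return self.fragments[0].start

    @property
    def span_end(self) -> int:
        return self.fragments[-1].end

    @property
    def span(self) -> int:
        return self.span_end - self.span_start


@dataclass(frozen=True, slots=True)
class DistanceProfile:
    """Neighboring-distance profile of a complex.

    Empty (zero-length vectors) for single-fragment complexes.
    """

    x_f2f: np.ndarray
    d_tot: int
    p_f2f: np.ndarray

    @property
    def empty(self) -> bool:
        return self.x_f2f.size == 0


def distance_profile(c: ChromatinComplex) -> DistanceProfile:
    """Compute F2F distances of a complex.

    Distances are ``start(next) - end(prev)`` floored at 1 bp so that the
    probability vector is always well defined even for book-ended
    fragments that escaped parse-time merging.
    """
    if c.n < 2:
        empty = np.empty(0, dtype=np.int64)
        return DistanceProfile(empty, 0, np.empty(0, dtype=float))
    starts = np.fromiter((f.start for f in c.fragments), np.int64, c.n)
    ends = np.fromiter((f.end for f in c.fragments), np.int64, c.n)
    x = np.maximum(starts[1:] - ends[:-1], 1)
    d_tot = int(x.sum())
    return DistanceProfile(x, d_tot, x / d_tot)
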