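"""SPRITE cluster pre-processing into the complexes master format.

SPRITE identifies chromatin complexes by combinatorial split-pool
barcodes; a "clusters" file has one cluster per line: a barcode followed
by read entries (``chrom:position`` tokens).  Reads are converted into
fragments by (1) restricting to one target chromosome, (2) de-duplicating
reads closer than ``min_sep`` to the previously retained read (a greedy
left-to-right sweep, absorbing PCR-duplicate pileups), (3) extending each
surviving position by ``extend`` bp, and (4) keeping only clusters with a
fragment count in ``[min_frags, max_frags]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .model import ChromatinComplex, GenomicFragment

__all__ = ["SpriteCluster", "read_clusters", "clusters_to_complexes"]


@dataclass(slots=True)
class SpriteCluster:
    barcode: str
    reads: list[tuple[str, int]]  # (chrom, position)

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"cluster {self.barcode!r} has no reads")


def read_clusters(
    path,
    field_sep: str = "\t",
    entry_sep: str = ":",
    chrom_index: int = 0,
    pos_index: int = 1,
) -> Iterator[SpriteCluster]:
    """Stream clusters from a SPRITE text file.

    The dialect is configurable because released cluster files vary:
    ``entry_sep`` splits a read entry (default ``chrom:pos``), and
    ``chrom_index`` / ``pos_index`` locate the chromosome and position
    among the split tokens (extra tokens such as strand are ignored).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(field_sep)
            if len(parts) < 2:
                continue  # barcode with no reads
            barcode, entries = parts[0], parts[1:]
            reads = []
            for entry in entries:
                tokens = entry.split(entry_sep)
                try:
                    reads.append(
                        (tokens[chrom_index], int(tokens[pos_index]))
                    )
                except (IndexError, ValueError) as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed read entry {entry!r}"
                    ) from exc
            yield SpriteCluster(barcode, reads)


def clusters_to_complexes(
    clusters: Iterable[SpriteCluster],
    target_chrom: str,
    extend: int = 1000,
    min_sep: int = 10_000,
    min_frags: int = 2,
    max_frags: int = 500,
) -> list[ChromatinComplex]:
    """Apply the SPRITE pre-processing rules; see module docstring.

    The de-duplication sweep keeps a read only if it is at least
    ``min_sep`` bp to the right of the previously *retained* read, so
    retained fragments never overlap for ``min_sep > extend``.
    """
    out: list[ChromatinComplex] = []
    for cluster in clusters:
        positions = sorted(p for chrom, p in cluster.reads if chrom == target_chrom)
        if not positions:
            continue
        kept = [positions[0]]
        for p in positions[1:]:
            if p - kept[-1] >= min_sep:
                kept.append(p)
        if not (min_frags <= len(kept) <= max_frags):
            continue
        frags = tuple(
            GenomicFragment(target_chrom, p, p + extend) for p in kept
        )
        out.append(ChromatinComplex(cluster.barcode, frags))
    return out
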