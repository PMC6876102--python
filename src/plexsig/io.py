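"""Readers and writers for the text formats used across the pipeline.

The *complexes master* format is a tab-delimited BED-like file with one
fragment per line::

    chrom  start  end  complexID  [category  raw_p  adj_p]

Fragments sharing a complexID form one complex.  This is the lossless
on-disk representation used between pipeline stages (it mirrors the
fragment lists emitted by droplet-barcoding preprocessing pipelines).

Also provided: two-column ``chrom.sizes``, juicer ``.short`` pair export,
BED interval output and bedGraph input/output.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import ChromatinComplex, GenomicFragment

__all__ = [
    "ParseError",
    "read_chrom_sizes",
    "read_complexes",
    "write_complexes",
    "write_short",
    "read_bedgraph",
    "write_bedgraph",
    "write_bed",
    "read_bed",
    "read_master",
    "write_master",
]


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(path, i, "expected 'chrom length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(path, i, f"bad chromosome length {parts[1]!r}")
    return sizes


def read_complexes(
    path,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, list[ChromatinComplex]]:
    """Parse a complexes master file into per-chromosome complex lists.

    Fragments are grouped by complexID, sorted, and overlapping or
    book-ended fragments within one complex are merged.  A complexID whose
    fragments map to several chromosomes is split into per-chromosome
    sub-complexes with deterministic ``|chrom`` suffixes (all downstream
    tests are intra-chromosomal).
    """
    # id -> chrom -> fragment list, insertion-ordered
    by_id: dict[str, dict[str, list[GenomicFragment]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, i, "expected >=4 tab-delimited columns")
            chrom, s, e, cid = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(path, i, f"non-integer coordinates {s!r}, {e!r}")
            if start < 0 or start >= end:
                raise ParseError(path, i, f"bad interval [{start}, {end})")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ParseError(path, i, f"unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise ParseError(
                        path, i,
                        f"fragment end {end} exceeds length of {chrom} "
                        f"({chrom_sizes[chrom]})",
                    )
            by_id.setdefault(cid, {}).setdefault(chrom, []).append(
                GenomicFragment(chrom, start, end)
            )

    out: dict[str, list[ChromatinComplex]] = {}
    for cid, per_chrom in by_id.items():
        split = len(per_chrom) > 1
        for chrom, frags in per_chrom.items():
            sub_id = f"{cid}|{chrom}" if split else cid
            c = ChromatinComplex.from_fragments(sub_id, frags)
            out.setdefault(chrom, []).append(c)
    return out


def _iter_complexes(
    complexes: Iterable[ChromatinComplex] | Mapping[str, list[ChromatinComplex]],
):
    if isinstance(complexes, Mapping):
        for chrom in sorted(complexes):
            yield from complexes[chrom]
    else:
        yield from complexes


def write_complexes(complexes, path, with_state: bool = False) -> None:
    """Write complexes in the master (one fragment per line) format."""
    with open(path, "w") as fh:
        for c in _iter_complexes(complexes):
            for f in c.fragments:
                fields = [f.chrom, str(f.start), str(f.end), c.id]
                if with_state:
                    fields += [
                        c.category,
                        "NA" if c.raw_p is None else f"{c.raw_p:.10g}",
                        "NA" if c.adj_p is None else f"{c.adj_p:.10g}",
                    ]
                fh.write("\t".join(fields) + "\n")


def write_short(complexes, path) -> int:
    """Export complexes as juicer ``.short`` pairwise contacts.

    Every unordered fragment pair of a complex becomes one line
    (``C(n, 2)`` lines per complex), with strands fixed to 0, positions as
    1-based fragment midpoints and restriction-fragment fields 0/1.
    Single-fragment complexes are skipped.  Returns the line count.
    """
    n_lines = 0
    with open(path, "w") as fh:
        for c in _iter_complexes(complexes):
            if c.n < 2:
                continue
            mids = [f.midpoint + 1 for f in c.fragments]
            for i in range(len(mids)):
                for j in range(i + 1, len(mids)):
                    fh.write(
                        f"0 {c.chrom} {mids[i]} 0 0 {c.chrom} {mids[j]} 1\n"
                    )
                    n_lines += 1
    return n_lines


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def write_bed(intervals, path) -> None:
    """Write intervals with ``chrom/start/end`` and optional ``kind`` as name."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "kind", getattr(iv, "name", "."))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# master table (one row per complex, fragments inlined) -- the stable
# interface between the distance test and the TAD / inter-TAD stages.

_MASTER_COLS = [
    "complex_id", "chrom", "n", "start", "end",
    "category", "raw_p", "adj_p", "parent_id", "entropy", "fragments",
]


def complexes_to_table(complexes) -> pd.DataFrame:
    rows = []
    for c in _iter_complexes(complexes):
        rows.append(
            {
                "complex_id": c.id,
                "chrom": c.chrom,
                "n": c.n,
                "start": c.span_start,
                "end": c.span_end,
                "category": c.category,
                "raw_p": c.raw_p,
                "adj_p": c.adj_p,
                "parent_id": c.parent_id,
                "entropy": np.nan,
                "fragments": ";".join(f"{f.start}-{f.end}" for f in c.fragments),
            }
        )
    return pd.DataFrame(rows, columns=_MASTER_COLS)


def write_master(df: pd.DataFrame, path) -> None:
    """Write a master table TSV with stable float formatting (so identical
    runs produce byte-identical files)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_master(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"complex_id": str, "parent_id": str})
    return df


def master_to_complexes(
    df: pd.DataFrame, categories: Iterable[str] | None = None
) -> dict[str, list[ChromatinComplex]]:
    """Rebuild complexes from a master table, optionally restricted to
    categories (``PASS`` selects the significant pass1+pass2 union)."""
    if categories is not None:
        cats = set(categories)
        if "PASS" in cats:
            cats |= {"pass1", "pass2"}
        df = df[df["category"].isin(cats)]
    out: dict[str, list[ChromatinComplex]] = {}
    for row in df.itertuples(index=False):
        frags = []
        for tok in row.fragments.split(";"):
            s, e = tok.split("-")
            frags.append(GenomicFragment(row.chrom, int(s), int(e)))
        c = ChromatinComplex.from_fragments(
            str(row.complex_id), frags,
            category=row.category,
            raw_p=None if pd.isna(row.raw_p) else float(row.raw_p),
            adj_p=None if pd.isna(row.adj_p) else float(row.adj_p),
            parent_id=None if pd.isna(row.parent_id) else str(row.parent_id),
        )
        out.setdefault(row.chrom, []).append(c)
    return out
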