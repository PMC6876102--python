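"""Enrichment test for protein-enriched (e.g. RNAPII) multiplex data.

Each complex's binding score ``covg`` is the mean over its fragments of
the mean coverage signal under each fragment.  Its null is empirical:
the whole complex is rigidly shifted to random in-bounds positions of
the same chromosome and the score recomputed; the raw p-value is the
proportion of shifted placements whose score strictly exceeds the
observed one.  BH adjustment is applied per chromosome.

Coverage lookups use a binned approximation (10-bp bins by default): a
fragment's mean is the simple mean of the values of all bins it overlaps.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ChromatinComplex, GenomicFragment
from .distance import bh_adjust

__all__ = [
    "BinnedCoverage",
    "EnrichmentConfig",
    "bin_coverage",
    "complex_coverage",
    "enrichment_pvalue",
    "run_enrichment_test",
    "filter_repeats",
]


class BinnedCoverage:
    """Binned mean fragment-coverage signal for one chromosome."""

    __slots__ = ("chrom", "bin_size", "values", "_prefix")

    def __init__(self, chrom: str, bin_size: int, values) -> None:
        self.chrom = chrom
        self.bin_size = bin_size
        self.values = np.asarray(values, dtype=float)
        # prefix sums for O(1) range means
        self._prefix = np.concatenate(([0.0], np.cumsum(self.values)))

    def range_mean(self, b0, b1):
        """Mean of bins b0..b1 inclusive (vector-friendly)."""
        return (self._prefix[b1 + 1] - self._prefix[b0]) / (b1 - b0 + 1)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BinnedCoverage({self.chrom!r}, bin_size={self.bin_size}, "
            f"n_bins={len(self.values)})"
        )


@dataclass(slots=True)
class EnrichmentConfig:
    """Random-placement null parameters.

    n_samples: rigid shifts drawn per complex (default 10,000).
    fdr: Benjamini-Hochberg false-discovery rate (default 0.1).
    bin_size: coverage bin width in bp (default 10).
    seed: base RNG seed; one stream per chromosome.
    """

    n_samples: int = 10_000
    fdr: float = 0.1
    bin_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError(f"n_samples must be >= 100, got {self.n_samples}")
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")


def bin_coverage(
    bedgraph: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    bin_size: int = 10,
) -> BinnedCoverage:
    """Bin a (sorted, non-overlapping) bedGraph into fixed-width bins.

    Each bin's value is the coverage-weighted mean of overlapping
    intervals, with uncovered base pairs contributing zero; fully
    uncovered bins are zero.
    """
    sub = bedgraph[bedgraph["chrom"] == chrom]
    starts = sub["start"].to_numpy(np.int64)
    ends = sub["end"].to_numpy(np.int64)
    vals = sub["value"].to_numpy(float)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError(f"overlapping bedGraph intervals on {chrom}")
    n_bins = -(-chrom_length // bin_size)
    sums = np.zeros(n_bins)
    for s, e, v in zip(starts, ends, vals):
        e = min(e, chrom_length)
        if e <= s:
            continue
        b0, b1 = s // bin_size, (e - 1) // bin_size
        if b0 == b1:
            sums[b0] += v * (e - s)
            continue
        sums[b0] += v * ((b0 + 1) * bin_size - s)
        sums[b1] += v * (e - b1 * bin_size)
        if b1 > b0 + 1:
            sums[b0 + 1 : b1] += v * bin_size
    return BinnedCoverage(chrom, bin_size, sums / bin_size)


def _frag_bins(starts, ends, bin_size):
    b0 = starts // bin_size
    b1 = (ends - 1) // bin_size
    return b0, b1


def complex_coverage(c: ChromatinComplex, cov: BinnedCoverage) -> float:
    """Mean over fragments of the fragment-mean binned signal."""
    bs = cov.bin_size
    total = 0.0
    for f in c.fragments:
        b0, b1 = f.start // bs, (f.end - 1) // bs
        total += cov.range_mean(b0, b1)
    return total / c.n


def enrichment_pvalue(
    c: ChromatinComplex,
    cov: BinnedCoverage,
    chrom_length: int,
    cfg: EnrichmentConfig,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Empirical p-value from random rigid shifts of the complex.

    Inter-fragment spacing is preserved; placements are uniform over
    start positions that keep the whole complex within
    ``[0, chrom_length)``.  Returns None (untestable) when the complex
    span does not fit on the chromosome.
    """
    span = c.span
    if span >= chrom_length:
        return None
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    obs = complex_coverage(c, cov)
    offs = np.array([f.start - c.span_start for f in c.fragments])
    lens = np.array([f.length for f in c.fragments])
    shifts = rng.integers(0, chrom_length - span + 1, size=cfg.n_samples)
    bs = cov.bin_size
    scores = np.zeros(cfg.n_samples)
    for off, ln in zip(offs, lens):
        st = shifts + off
        b0, b1 = st // bs, (st + ln - 1) // bs
        scores += cov.range_mean(b0, b1)
    scores /= c.n
    return float(np.count_nonzero(scores > obs) / cfg.n_samples)


def run_enrichment_test(
    complexes: Mapping[str, Sequence[ChromatinComplex]] | Sequence[ChromatinComplex],
    coverage: Mapping[str, BinnedCoverage],
    chrom_sizes: Mapping[str, int],
    cfg: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Score every complex, build its random-placement null and apply BH
    per chromosome.  Significant complexes (adjusted p <= FDR) are
    classified ``pass``, the rest ``fail``; complexes whose span exceeds
    the chromosome are flagged ``untestable``."""
    cfg = cfg or EnrichmentConfig()
    if not isinstance(complexes, Mapping):
        grouped: dict[str, list[ChromatinComplex]] = {}
        for c in complexes:
            grouped.setdefault(c.chrom, []).append(c)
        complexes = grouped

    rows: list[dict] = []
    for chrom in sorted(complexes):
        cov = coverage[chrom]
        length = chrom_sizes[chrom]
        if not np.any(cov.values > 0):
            warnings.warn(
                f"all-zero coverage on {chrom}: every p-value degenerates to 0",
                stacklevel=2,
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(chrom.encode())])
        )
        chrom_rows = []
        pvals = []
        for c in complexes[chrom]:
            p = enrichment_pvalue(c, cov, length, cfg, rng)
            row = {
                "complex_id": c.id,
                "chrom": chrom,
                "n": c.n,
                "start": c.span_start,
                "end": c.span_end,
                "covg": complex_coverage(c, cov),
                "raw_p": p,
                "fragments": ";".join(f"{f.start}-{f.end}" for f in c.fragments),
            }
            chrom_rows.append(row)
            if p is not None:
                pvals.append(p)
        adj, sig = bh_adjust(pvals, cfg.fdr)
        it = iter(zip(adj, sig))
        for row in chrom_rows:
            if row["raw_p"] is None:
                row["raw_p"] = np.nan
                row["adj_p"] = np.nan
                row["category"] = "untestable"
            else:
                a, s = next(it)
                row["adj_p"] = float(a)
                row["category"] = "pass" if s else "fail"
        rows.extend(chrom_rows)
    cols = [
        "complex_id", "chrom", "n", "start", "end",
        "covg", "raw_p", "adj_p", "category", "fragments",
    ]
    return pd.DataFrame(rows, columns=cols)


def filter_repeats(
    complexes: Sequence[ChromatinComplex],
    repeats: pd.DataFrame,
) -> list[ChromatinComplex]:
    """Drop fragments overlapping repeat-masker intervals; complexes left
    with fewer than two fragments are removed entirely."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in repeats.groupby("chrom"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy(np.int64)
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.array(out, dtype=np.int64)
        merged[chrom] = (arr[:, 0], arr[:, 1])

    kept: list[ChromatinComplex] = []
    for c in complexes:
        if c.chrom not in merged:
            kept.append(c)
            continue
        starts, ends = merged[c.chrom]
        frags = []
        for f in c.fragments:
            i = int(np.searchsorted(starts, f.end, side="left")) - 1
            overlaps = i >= 0 and ends[i] > f.start
            if not overlaps:
                frags.append(f)
        if len(frags) >= 2:
            kept.append(
                ChromatinComplex(
                    c.id, tuple(frags),
                    category=c.category, raw_p=c.raw_p,
                    adj_p=c.adj_p, parent_id=c.parent_id,
                )
            )
    return kept
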