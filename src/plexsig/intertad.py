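"""Significance of TAD combinations via the expanded-pair binomial test.

A complex "touches" a TAD when at least ``min_frags`` of its fragments
fall inside it; the sorted set of touched TADs is the complex's TAD
combination TC_i.  Combinations are partitioned into classes G_j by size.
Because a pair of TADs can recur verbatim in its own class or inside a
larger combination, each combination is credited with "expanded pairs":

* ``a`` - occurrence-weighted count of its pairs among the pair sets of
  same-class combinations (including itself),
* ``b`` - occurrence-weighted count of strict supersets in higher classes,
* ``x = a + b * N(N-1)/2`` with N the combination size,
* ``k`` - the class-wise sum of x (shared trial count).

The one-sided binomial tail P(X >= x | k, 1/|G_j|) is then adjusted with
Benjamini-Hochberg across all combinations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations as iter_combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .model import ChromatinComplex
from .tad import TadInterval
from .distance import bh_adjust

__all__ = [
    "complex_tad_set",
    "collect_combinations",
    "expanded_pair_stats",
    "binomial_combo_test",
    "run_intertad_test",
]


def complex_tad_set(
    c: ChromatinComplex,
    tads: Sequence[TadInterval],
    min_frags: int = 2,
) -> frozenset[str]:
    """TADs containing at least ``min_frags`` of the complex's fragments.

    A fragment is assigned to a TAD iff its midpoint lies inside the
    (disjoint) TAD interval.  TAD identifiers are ``chrom:start-end``.
    """
    doms = sorted(
        (t for t in tads if t.kind == "tad" and t.chrom == c.chrom),
        key=lambda t: t.start,
    )
    if not doms:
        return frozenset()
    starts = np.array([t.start for t in doms])
    ends = np.array([t.end for t in doms])
    counts: Counter[int] = Counter()
    for f in c.fragments:
        i = int(np.searchsorted(starts, f.midpoint, side="right")) - 1
        if i >= 0 and f.midpoint < ends[i]:
            counts[i] += 1
    return frozenset(
        f"{doms[i].chrom}:{doms[i].start}-{doms[i].end}"
        for i, cnt in counts.items()
        if cnt >= min_frags
    )


def collect_combinations(
    complexes: Sequence[ChromatinComplex],
    tads: Sequence[TadInterval],
    min_frags: int = 2,
) -> Counter:
    """Count, per distinct TAD combination of size >= 2, the number of
    complexes exhibiting exactly that combination."""
    combos: Counter = Counter()
    for c in complexes:
        ts = complex_tad_set(c, tads, min_frags)
        if len(ts) >= 2:
            combos[ts] += 1
    return combos


def expanded_pair_stats(combos: Mapping[frozenset, int]) -> pd.DataFrame:
    """Compute (a, b, x, k) for every combination.

    ``combos`` maps each distinct combination (frozenset of TAD ids) to
    its occurrence count (number of complexes).
    """
    items = sorted(combos.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    sizes = sorted({len(tc) for tc, _ in items})
    # per-class occurrence-weighted pair counts
    pair_counts: dict[int, Counter] = {}
    for tc, occ in items:
        pc = pair_counts.setdefault(len(tc), Counter())
        for pair in iter_combinations(sorted(tc), 2):
            pc[frozenset(pair)] += occ

    rows = []
    for tc, occ in items:
        n = len(tc)
        a = sum(
            pair_counts[n][frozenset(pair)]
            for pair in iter_combinations(sorted(tc), 2)
        )
        b = sum(
            w_occ
            for w, w_occ in combos.items()
            if len(w) != n and tc < w
        )
        x = a + b * (n * (n - 1) // 2)
        rows.append(
            {
                "tads": ",".join(sorted(tc)),
                "n_tads": n,
                "occurrences": occ,
                "a": a,
                "b": b,
                "x": x,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["tads", "n_tads", "occurrences", "a", "b", "x"],
    )
    if len(df):
        df["k"] = df.groupby("n_tads")["x"].transform("sum")
        df["class_size"] = df.groupby("n_tads")["x"].transform("size")
    else:
        df["k"] = df["class_size"] = pd.Series(dtype=int)
    return df


def binomial_combo_test(df: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """One-sided exact binomial test per combination plus pooled BH.

    Success count x, trials k (class-wise sum), null success probability
    1/|G_j|; alternative: observed probability greater than expected.
    """
    df = df.copy()
    raw = np.ones(len(df))
    for i, (x, k, m) in enumerate(
        zip(df["x"].astype(int), df["k"].astype(int), df["class_size"].astype(int))
    ):
        if k > 0:
            raw[i] = binomtest(x, k, 1.0 / m, alternative="greater").pvalue
    df["raw_p"] = raw
    adj, sig = bh_adjust(raw, fdr)
    df["adj_p"] = adj
    df["significant"] = sig
    return df


def run_intertad_test(
    complexes: Sequence[ChromatinComplex] | Mapping[str, Sequence[ChromatinComplex]],
    tads: Sequence[TadInterval],
    min_frags: int = 2,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Full inter-TAD pipeline: combination counting, expanded-pair
    statistics and the binomial test with BH adjustment."""
    if isinstance(complexes, Mapping):
        flat: list[ChromatinComplex] = []
        for chrom in sorted(complexes):
            flat.extend(complexes[chrom])
        complexes = flat
    combos = collect_combinations(complexes, tads, min_frags)
    stats = expanded_pair_stats(combos)
    if not len(stats):
        stats["raw_p"] = stats["adj_p"] = pd.Series(dtype=float)
        stats["significant"] = pd.Series(dtype=bool)
        return stats
    return binomial_combo_test(stats, fdr)
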