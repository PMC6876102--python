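"""Two-stage resampling distance test with an entropy multiplet filter.

This is the de-noising core for non-enriched multiplex data.  Complexes
are stratified by fragment class F_j (j = fragment count) and compared,
per chromosome, against an empirical null built by rewiring fragments:
all observed neighboring distances go into a bucket B, and each "expected
complex" of class j is j-1 i.i.d. draws (with replacement) from B.  The
raw p-value of a complex is the proportion of expected complexes with a
smaller total distance; Benjamini-Hochberg adjustment is applied per
(chromosome, class).

Insignificant complexes with three or more fragments ("deferred") are
passed through the entropy filter: a complex whose normalized Shannon
entropy of the distance probability vector falls below the class-mean
entropy of the expected complexes is presumed a multiplet and is split at
its dominating gap (and at the second-largest gap when that is at least
1/tau of the largest).  The resulting sub-complexes are re-tested in
their new class (second distance test).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import ChromatinComplex, distance_profile

__all__ = [
    "DistanceTestConfig",
    "FragmentClassNull",
    "NullBank",
    "build_null",
    "raw_pvalue",
    "bh_adjust",
    "classify_first",
    "normalized_entropy",
    "UndefinedEntropyError",
    "entropy_split",
    "second_pass",
    "run_distance_test",
    "step_statistics",
]


@dataclass(slots=True)
class DistanceTestConfig:
    """Parameters of the distance test.

    fdr
        Benjamini-Hochberg false-discovery rate (default 0.1).
    tau
        Second-cut ratio: a deferred complex flagged by the entropy filter
        is also cut at its second-largest gap when that gap is at least
        ``1/tau`` of the largest (default 2; CLI ``--cef``).
    sample_size
        Number of expected complexes drawn per fragment class
        (default 100,000; CLI ``--sz``).
    seed
        Base RNG seed; one independent stream is derived per
        (chromosome, class) so per-chromosome runs are reproducible.
    max_frags_fail
        Optional cap: insignificant complexes with more fragments are
        failed outright in the first test (100 in SPRITE mode).
    min_complexes
        Chromosomes with fewer testable complexes are warned and skipped.
    """

    fdr: float = 0.1
    tau: float = 2.0
    sample_size: int = 100_000
    seed: int = 0
    max_frags_fail: int | None = None
    min_complexes: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.sample_size < 1000:
            raise ValueError(f"sample_size must be >= 1000, got {self.sample_size}")


@dataclass(slots=True)
class FragmentClassNull:
    """Resampled null for one fragment class F_j.

    Stores only what downstream steps need: the sorted total distances of
    the expected complexes and their mean normalized entropy (defined for
    j >= 3, NaN otherwise).
    """

    j: int
    d_tot_samples: np.ndarray  # sorted ascending
    mean_entropy: float
    sample_size: int


class UndefinedEntropyError(ValueError):
    """Entropy of a length-1 probability vector (class F_2) is undefined."""


def normalized_entropy(p) -> float:
    """Normalized Shannon entropy H(p) / log2(len(p)) in [0, 1].

    ``p`` must be a probability vector with at least two entries (a
    complex with n fragments has n-1 gaps, so this requires n >= 3);
    0 * log2(1/0) is taken as 0.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise UndefinedEntropyError(
            "entropy needs a probability vector of length >= 2 "
            f"(got length {p.size}); class F_2 is never entropy-filtered"
        )
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("entries must be non-negative and sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h / float(np.log2(p.size))


def _entropy_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise normalized entropy of a matrix of positive distances."""
    p = x / x.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=1) / np.log2(x.shape[1])


def _class_rng(seed: int, chrom: str, j: int) -> np.random.Generator:
    # stable per-(chromosome, class) stream; crc32 keeps entries < 2**32
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(chrom.encode()), j])
    )


class NullBank(Mapping):
    """Per-class nulls for one chromosome, built lazily from the bucket B.

    Classes that only arise after entropy splitting (no observed member)
    reuse the same bucket on demand, with the same seeding scheme.
    """

    def __init__(self, bucket: np.ndarray, cfg: DistanceTestConfig, chrom: str):
        if bucket.size == 0:
            raise ValueError(
                f"empty distance bucket on {chrom}: no complex with >= 2 fragments"
            )
        self.bucket = np.asarray(bucket, dtype=np.int64)
        self.cfg = cfg
        self.chrom = chrom
        self._cache: dict[int, FragmentClassNull] = {}

    def __getitem__(self, j: int) -> FragmentClassNull:
        if j < 2:
            raise KeyError(f"fragment class must be >= 2, got {j}")
        if j not in self._cache:
            self._cache[j] = self._build(j)
        return self._cache[j]

    def _build(self, j: int) -> FragmentClassNull:
        rng = _class_rng(self.cfg.seed, self.chrom, j)
        ss = self.cfg.sample_size
        idx = rng.integers(0, self.bucket.size, size=(ss, j - 1))
        draws = self.bucket[idx]
        d_tot = draws.sum(axis=1)
        mean_h = float(_entropy_rows(draws).mean()) if j >= 3 else float("nan")
        return FragmentClassNull(j, np.sort(d_tot), mean_h, ss)

    def __iter__(self):
        return iter(self._cache)

    def __len__(self):
        return len(self._cache)


def build_null(
    complexes: Sequence[ChromatinComplex],
    cfg: DistanceTestConfig,
    chrom: str | None = None,
) -> NullBank:
    """Build the bucket B and the nulls for every observed fragment class.

    All neighboring distances of the given (single-chromosome) complexes
    are pooled into B; for each observed class j, ``cfg.sample_size``
    expected complexes of j-1 distances are drawn with replacement.
    """
    if chrom is None:
        chrom = complexes[0].chrom if complexes else ""
    gaps = [distance_profile(c).x_f2f for c in complexes if c.n >= 2]
    bucket = np.concatenate(gaps) if gaps else np.empty(0, dtype=np.int64)
    bank = NullBank(bucket, cfg, chrom)
    for j in sorted({c.n for c in complexes if c.n >= 2}):
        bank[j]
    return bank


def raw_pvalue(d_tot_obs, null: FragmentClassNull):
    """Proportion of expected complexes with total distance strictly
    smaller than the observation (scalar or vector)."""
    counts = np.searchsorted(null.d_tot_samples, d_tot_obs, side="left")
    return counts / null.sample_size


def bh_adjust(pvals, fdr: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, significant)`` with ``significant = adjusted <= fdr``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    _, adj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return adj, adj <= fdr


def classify_first(
    complexes: Sequence[ChromatinComplex],
    nulls: NullBank,
    cfg: DistanceTestConfig,
) -> list[ChromatinComplex]:
    """First distance test: assign pass1 / fail1 / defer, per class.

    Significant (adjusted p <= FDR) complexes pass; among the rest,
    two-fragment complexes (and, when configured, complexes above
    ``max_frags_fail`` fragments) fail outright, others are deferred to
    the entropy filter.
    """
    by_class: dict[int, list[ChromatinComplex]] = {}
    for c in complexes:
        if c.n >= 2:
            by_class.setdefault(c.n, []).append(c)
    for j, members in sorted(by_class.items()):
        d_obs = np.array([distance_profile(c).d_tot for c in members])
        raw = raw_pvalue(d_obs, nulls[j])
        adj, sig = bh_adjust(raw, cfg.fdr)
        for c, rp, ap, s in zip(members, raw, adj, sig):
            c.raw_p, c.adj_p = float(rp), float(ap)
            if s:
                c.category = "pass1"
            elif c.n == 2 or (
                cfg.max_frags_fail is not None and c.n > cfg.max_frags_fail
            ):
                c.category = "fail1"
            else:
                c.category = "defer"
    return list(complexes)


def entropy_split(
    c: ChromatinComplex,
    threshold: float,
    tau: float = 2.0,
) -> tuple[ChromatinComplex, ...]:
    """Split a presumed multiplet at its dominating gap(s).

    If the normalized entropy of the complex's distance probability vector
    is below ``threshold`` (the class-mean entropy of the expected
    complexes), the complex is cut at its largest gap; additionally at the
    second-largest gap when that is at least ``1/tau`` of the largest.
    Ties go to the left-most maximal gap.  Returns the complex unchanged
    (length-1 tuple) when entropy is at or above the threshold.
    """
    prof = distance_profile(c)
    if prof.x_f2f.size < 2:
        return (c,)
    h = normalized_entropy(prof.p_f2f)
    if h >= threshold:
        return (c,)
    x = prof.x_f2f
    i1 = int(np.argmax(x))
    cuts = [i1]
    rest = x.astype(float).copy()
    rest[i1] = -np.inf
    i2 = int(np.argmax(rest))
    if rest[i2] * tau >= x[i1]:
        cuts.append(i2)
    cuts.sort()
    pieces: list[tuple] = []
    lo = 0
    for cut in cuts:
        pieces.append(c.fragments[lo : cut + 1])
        lo = cut + 1
    pieces.append(c.fragments[lo:])
    return tuple(
        ChromatinComplex(
            f"{c.id}.{k}", frags, parent_id=c.id
        )
        for k, frags in enumerate(pieces, start=1)
    )


def second_pass(
    subcomplexes: Sequence[ChromatinComplex],
    nulls: NullBank,
    cfg: DistanceTestConfig,
) -> list[ChromatinComplex]:
    """Second distance test on the entropy-filtered pool.

    Each sub-complex is tested against the null of its *new* fragment
    class; BH is applied per class; singletons are recorded (class F_1)
    but never tested.
    """
    by_class: dict[int, list[ChromatinComplex]] = {}
    for c in subcomplexes:
        if c.n == 1:
            c.category = "singleton"
        else:
            by_class.setdefault(c.n, []).append(c)
    for j, members in sorted(by_class.items()):
        d_obs = np.array([distance_profile(c).d_tot for c in members])
        raw = raw_pvalue(d_obs, nulls[j])
        adj, sig = bh_adjust(raw, cfg.fdr)
        for c, rp, ap, s in zip(members, raw, adj, sig):
            c.raw_p, c.adj_p = float(rp), float(ap)
            c.category = "pass2" if s else "fail2"
    return list(subcomplexes)


def _run_chrom(
    complexes: Sequence[ChromatinComplex],
    cfg: DistanceTestConfig,
    chrom: str,
) -> list[dict]:
    nulls = build_null(complexes, cfg, chrom)
    classify_first(complexes, nulls, cfg)

    rows: list[dict] = []

    def _row(c: ChromatinComplex, entropy: float = float("nan")) -> dict:
        return {
            "complex_id": c.id,
            "chrom": c.chrom,
            "n": c.n,
            "start": c.span_start,
            "end": c.span_end,
            "category": c.category,
            "raw_p": c.raw_p,
            "adj_p": c.adj_p,
            "parent_id": c.parent_id,
            "entropy": entropy,
            "fragments": ";".join(f"{f.start}-{f.end}" for f in c.fragments),
        }

    filtered_pool: list[ChromatinComplex] = []
    deferred_rows: list[dict] = []
    for c in complexes:
        if c.category != "defer":
            rows.append(_row(c))
            continue
        h = normalized_entropy(distance_profile(c).p_f2f)
        children = entropy_split(c, nulls[c.n].mean_entropy, cfg.tau)
        if len(children) == 1:
            filtered_pool.append(c)
            deferred_rows.append(_row(c, h))  # category updated in-place later
        else:
            c.category = "split"
            rows.append(_row(c, h))
            filtered_pool.extend(children)
            for ch in children:
                deferred_rows.append(_row(ch))

    second_pass(filtered_pool, nulls, cfg)
    # refresh rows of the re-tested pool with their final state
    by_id = {c.id: c for c in filtered_pool}
    for r in deferred_rows:
        c = by_id[r["complex_id"]]
        r.update(category=c.category, raw_p=c.raw_p, adj_p=c.adj_p)
    rows.extend(deferred_rows)
    return rows


def run_distance_test(
    complexes: Mapping[str, Sequence[ChromatinComplex]] | Sequence[ChromatinComplex],
    cfg: DistanceTestConfig | None = None,
) -> pd.DataFrame:
    """Run the full two-stage distance test, one chromosome at a time.

    Returns the master table: one row per input complex and per split
    sub-complex, with category in {pass1, fail1, split, pass2, fail2,
    singleton}, raw/adjusted p-values, entropy of deferred complexes and
    the split lineage (``parent_id``).  "Significant" complexes are the
    pass1 + pass2 union.  Fixed seed implies a byte-identical table.
    """
    cfg = cfg or DistanceTestConfig()
    if not isinstance(complexes, Mapping):
        grouped: dict[str, list[ChromatinComplex]] = {}
        for c in complexes:
            grouped.setdefault(c.chrom, []).append(c)
        complexes = grouped

    rows: list[dict] = []
    for chrom in sorted(complexes):
        chrom_cx = list(complexes[chrom])
        testable = [c for c in chrom_cx if c.n >= 2]
        if len(testable) < cfg.min_complexes:
            warnings.warn(
                f"skipping {chrom}: only {len(testable)} testable complexes "
                f"(< {cfg.min_complexes})",
                stacklevel=2,
            )
            continue
        rows.extend(_run_chrom(chrom_cx, cfg, chrom))
    from .io import _MASTER_COLS

    return pd.DataFrame(rows, columns=_MASTER_COLS)


def step_statistics(master: pd.DataFrame) -> dict[str, int]:
    """Per-step counts of the distance-test flow (inputs, first-test
    categories, splits, second-test categories, total significant)."""
    cats = master["category"]
    parents = master["parent_id"].notna()
    n_input = int((~parents).sum())
    split_parents = master[cats == "split"]
    children_per_parent = (
        master.loc[parents, "parent_id"].value_counts() if parents.any() else None
    )
    doublets = triplets = 0
    if children_per_parent is not None and len(split_parents):
        counts = children_per_parent.reindex(split_parents["complex_id"])
        doublets = int((counts == 2).sum())
        triplets = int((counts == 3).sum())
    deferred = int(
        (cats == "split").sum()
        + ((cats.isin(["pass2", "fail2"])) & ~parents).sum()
    )
    return {
        "input": n_input,
        "pass1": int((cats == "pass1").sum()),
        "fail1": int((cats == "fail1").sum()),
        "defer": deferred,
        "split_doublet": doublets,
        "split_triplet": triplets,
        "singleton": int((cats == "singleton").sum()),
        "pass2": int((cats == "pass2").sum()),
        "fail2": int((cats == "fail2").sum()),
        "significant": int(cats.isin(["pass1", "pass2"]).sum()),
    }
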