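"""Seeded synthetic multiplex chromatin-interaction datasets with truth.

The generator emulates the data model the pipeline is built for:

* *intra-TAD* complexes — all fragments inside one planted TAD, with
  log-uniform intra-complex gaps (so the distance probability vector is
  non-degenerate);
* *noise* complexes — fragments uniform over the chromosome (long-range
  experimental noise);
* *multiplets* — two (doublets) or three (triplets) independently drawn
  intra-TAD singlets concatenated under one barcode, emulating droplet
  co-encapsulation; the singlets come from well-separated TADs so one or
  two gaps dominate;
* *peak-bound* vs *background* complexes plus a noisy peaked coverage
  track, for the enrichment test.

Every emitted complex carries exactly one truth label, so downstream
recovery rates can be measured directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ChromatinComplex, GenomicFragment

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_tads",
    "default_peaks",
    "simulate_dataset",
]

_TAD_SIZES = (300_000, 150_000, 500_000, 200_000, 400_000, 100_000, 250_000, 350_000)
_TAD_GAPS = (100_000, 150_000, 80_000, 200_000, 120_000, 60_000, 90_000, 110_000)


def default_tads(
    chrom_length: int, n_tads: int = 8, first_start: int = 1_000_000
) -> tuple[tuple[int, int], ...]:
    """A deterministic TAD layout: sizes 100-500 kb, gaps 60-200 kb."""
    tads = []
    pos = first_start
    for i in range(n_tads):
        size = _TAD_SIZES[i % len(_TAD_SIZES)]
        if pos + size > chrom_length - 200_000:
            break
        tads.append((pos, pos + size))
        pos += size + _TAD_GAPS[i % len(_TAD_GAPS)]
    if not tads:
        raise ValueError(f"chromosome of {chrom_length} bp too short for TADs")
    return tuple(tads)


def default_peaks(
    chrom_length: int, n_peaks: int = 10, width: int = 2000, height: float = 30.0
) -> tuple[tuple[int, int, float], ...]:
    """Evenly spaced (center, width, height) coverage peaks."""
    centers = np.linspace(chrom_length * 0.05, chrom_length * 0.95, n_peaks)
    return tuple((int(c), width, height) for c in centers)


@dataclass(slots=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Fractions partition the ``n_complexes`` total: ``noise_fraction``
    uniform-random complexes, ``multiplet_fraction`` concatenated
    singlets (of which ``triplet_share`` are triplets), and — when
    ``peaks`` is non-empty — ``peak_bound_fraction`` peak-anchored
    complexes with the remainder labeled ``background``.  The rest are
    intra-TAD singlets.
    """

    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    tads: tuple[tuple[int, int], ...] | None = None
    n_complexes: int = 10_000
    frag_mean: float = 500.0
    frag_sd: float = 100.0
    frag_min: int = 100
    frags_lambda: float = 8.0  # n = 2 + Poisson(lambda)
    gap_min: int = 1_000
    gap_decades: float = 1.0  # gaps log-uniform over [gap_min, gap_min*10**decades]
    noise_fraction: float = 0.0
    multiplet_fraction: float = 0.0
    triplet_share: float = 0.0
    multiplet_min_sep: int | None = None  # default: 20x the largest intra gap
    peaks: tuple[tuple[int, int, float], ...] = ()
    peak_bound_fraction: float = 0.0
    coverage_baseline: float = 1.0
    coverage_bin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_fraction", "multiplet_fraction",
                     "triplet_share", "peak_bound_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tads is None:
            try:
                self.tads = default_tads(self.chrom_length)
            except ValueError:
                if self.peaks:  # enrichment-only dataset needs no TADs
                    self.tads = ()
                else:
                    raise
        tads = sorted(self.tads)
        if not tads:
            return
        for (s1, e1), (s2, e2) in zip(tads, tads[1:]):
            if s2 < e1:
                raise ValueError("planted TADs must be disjoint")
        if tads and max(e for _, e in tads) >= self.chrom_length:
            raise ValueError("TADs must fit inside the chromosome")
        self.tads = tuple(tads)
        if self.multiplet_min_sep is None:
            self.multiplet_min_sep = int(
                20 * self.gap_min * 10 ** self.gap_decades
            )

    @property
    def gap_max(self) -> int:
        return int(self.gap_min * 10 ** self.gap_decades)


@dataclass(slots=True)
class SimulatedDataset:
    config: SimulationConfig
    complexes: list[ChromatinComplex]
    truth: pd.DataFrame  # complex_id, origin, tads, parents
    coverage: pd.DataFrame | None  # bedGraph, None when no peaks configured
    chrom_sizes: dict[str, int]

    def complexes_by_chrom(self) -> dict[str, list[ChromatinComplex]]:
        return {self.config.chrom: list(self.complexes)}

    def write(self, outdir) -> None:
        from . import io

        os.makedirs(outdir, exist_ok=True)
        io.write_complexes(self.complexes, os.path.join(outdir, "complexes.tsv"))
        self.truth.to_csv(
            os.path.join(outdir, "truth.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        if self.coverage is not None:
            io.write_bedgraph(
                self.coverage, os.path.join(outdir, "coverage.bedgraph")
            )


def _frag_lengths(rng, cfg, n):
    lens = rng.normal(cfg.frag_mean, cfg.frag_sd, n)
    return np.maximum(np.round(lens), cfg.frag_min).astype(np.int64)


def _n_frags(rng, cfg):
    return 2 + int(rng.poisson(cfg.frags_lambda))


def _log_uniform_gaps(rng, cfg, m):
    exp = rng.uniform(np.log10(cfg.gap_min), np.log10(cfg.gap_max), m)
    return np.round(10.0 ** exp).astype(np.int64)


def _singlet_fragments(rng, cfg, tad):
    """Fragments of one compact complex inside a planted TAD."""
    t0, t1 = tad
    tad_len = t1 - t0
    n = _n_frags(rng, cfg)
    lens = _frag_lengths(rng, cfg, n)
    if int(lens.sum()) + (n - 1) >= int(0.9 * tad_len):
        raise ValueError(
            f"infeasible config: {n} fragments of total {lens.sum()} bp "
            f"cannot fit in a {tad_len} bp TAD"
        )
    gaps = _log_uniform_gaps(rng, cfg, n - 1)
    span = int(lens.sum() + gaps.sum())
    budget = int(0.95 * tad_len) - int(lens.sum())
    if gaps.sum() > budget:  # shrink gaps proportionally to fit the TAD
        gaps = np.maximum((gaps * (budget / gaps.sum())).astype(np.int64), 1)
        span = int(lens.sum() + gaps.sum())
    start = t0 + int(rng.integers(0, tad_len - span + 1))
    frags = []
    pos = start
    for i, ln in enumerate(lens):
        frags.append((pos, pos + int(ln)))
        pos += int(ln) + (int(gaps[i]) if i < n - 1 else 0)
    return frags


def _noise_fragments(rng, cfg):
    """Fragments uniform over the chromosome (sorted, non-overlapping)."""
    for _ in range(100):
        n = _n_frags(rng, cfg)
        lens = _frag_lengths(rng, cfg, n)
        starts = np.sort(
            rng.integers(0, cfg.chrom_length - int(lens.max()), n)
        )
        ends = starts + lens
        if np.all(starts[1:] > ends[:-1]):
            return list(zip(starts.tolist(), ends.tolist()))
    raise RuntimeError("could not place a non-overlapping noise complex")


def _separated_tad_choice(rng, cfg, k):
    """k distinct TADs pairwise separated by at least multiplet_min_sep."""
    tads = cfg.tads
    for _ in range(200):
        idx = rng.choice(len(tads), size=k, replace=False)
        idx.sort()
        ok = all(
            tads[b][0] - tads[a][1] >= cfg.multiplet_min_sep
            for a, b in zip(idx, idx[1:])
        )
        if ok:
            return [tads[i] for i in idx]
    raise ValueError(
        "cannot find planted TADs separated by "
        f"{cfg.multiplet_min_sep} bp for a multiplet"
    )


def _peak_fragments(rng, cfg):
    """Fragments anchored in coverage-peak regions (non-overlapping)."""
    n = _n_frags(rng, cfg)
    k = min(len(cfg.peaks), max(1, int(rng.integers(1, 3))))
    chosen = rng.choice(len(cfg.peaks), size=k, replace=False)
    frags = []
    for i in range(n):
        center, width, _ = cfg.peaks[chosen[i % k]]
        ln = int(_frag_lengths(rng, cfg, 1)[0])
        lo = max(0, center - width)
        hi = min(cfg.chrom_length - ln, center + width)
        s = int(rng.integers(lo, hi + 1))
        frags.append((s, s + ln))
    frags.sort()
    merged = [list(frags[0])]
    for s, e in frags[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(f) for f in merged]


def _background_fragments(rng, cfg):
    """Compact complex geometry at a uniform random location."""
    n = _n_frags(rng, cfg)
    lens = _frag_lengths(rng, cfg, n)
    gaps = _log_uniform_gaps(rng, cfg, n - 1)
    span = int(lens.sum() + gaps.sum())
    start = int(rng.integers(0, cfg.chrom_length - span))
    frags = []
    pos = start
    for i, ln in enumerate(lens):
        frags.append((pos, pos + int(ln)))
        pos += int(ln) + (int(gaps[i]) if i < n - 1 else 0)
    return frags


def _coverage_track(rng, cfg) -> pd.DataFrame:
    bs = cfg.coverage_bin
    n_bins = -(-cfg.chrom_length // bs)
    centers = np.arange(n_bins) * bs + bs / 2
    # gamma noise around the baseline keeps the null continuous
    values = rng.gamma(4.0, cfg.coverage_baseline / 4.0, n_bins)
    for c, w, h in cfg.peaks:
        sigma = w / 4.0
        lo = max(0, int((c - 4 * w) // bs))
        hi = min(n_bins, int((c + 4 * w) // bs) + 1)
        values[lo:hi] += h * np.exp(
            -0.5 * ((centers[lo:hi] - c) / sigma) ** 2
        )
    starts = np.arange(n_bins, dtype=np.int64) * bs
    ends = np.minimum(starts + bs, cfg.chrom_length)
    return pd.DataFrame(
        {"chrom": cfg.chrom, "start": starts, "end": ends,
         "value": np.round(values, 4)}
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one labeled dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    n_noise = int(round(cfg.noise_fraction * cfg.n_complexes))
    n_mult = int(round(cfg.multiplet_fraction * cfg.n_complexes))
    n_trip = int(round(cfg.triplet_share * n_mult))
    if cfg.peaks and cfg.peak_bound_fraction > 0:
        n_peak = int(round(cfg.peak_bound_fraction * cfg.n_complexes))
        n_bg = cfg.n_complexes - n_peak
        origins = ["peak_bound"] * n_peak + ["background"] * n_bg
    else:
        n_intra = cfg.n_complexes - n_noise - n_mult
        origins = (
            ["intra_tad"] * n_intra
            + ["noise"] * n_noise
            + ["triplet"] * n_trip
            + ["doublet"] * (n_mult - n_trip)
        )

    complexes: list[ChromatinComplex] = []
    truth_rows: list[dict] = []
    for i, origin in enumerate(origins):
        cid = f"SIM{i:06d}"
        tad_labels: list[str] = []
        parents: list[str] = []
        junctions: list[str] = []
        if origin == "intra_tad":
            tad = cfg.tads[int(rng.integers(0, len(cfg.tads)))]
            frags = _singlet_fragments(rng, cfg, tad)
            tad_labels = [f"{tad[0]}-{tad[1]}"]
        elif origin == "noise":
            frags = _noise_fragments(rng, cfg)
        elif origin in ("doublet", "triplet"):
            k = 3 if origin == "triplet" else 2
            chosen = _separated_tad_choice(rng, cfg, k)
            frags = []
            parts = []
            for j, tad in enumerate(chosen, start=1):
                part = _singlet_fragments(rng, cfg, tad)
                parts.append(part)
                frags.extend(part)
                tad_labels.append(f"{tad[0]}-{tad[1]}")
                parents.append(f"{cid}:singlet{j}")
            junctions = [
                f"{pa[-1][1]}|{pb[0][0]}"
                for pa, pb in zip(parts, parts[1:])
            ]
        elif origin == "peak_bound":
            frags = _peak_fragments(rng, cfg)
        else:  # background
            frags = _background_fragments(rng, cfg)
        complexes.append(
            ChromatinComplex.from_fragments(
                cid,
                (GenomicFragment(cfg.chrom, s, e) for s, e in frags),
            )
        )
        truth_rows.append(
            {
                "complex_id": cid,
                "origin": origin,
                "tads": ",".join(tad_labels),
                "parents": ",".join(parents),
                "junctions": ",".join(junctions),
            }
        )

    coverage = _coverage_track(rng, cfg) if cfg.peaks else None
    truth = pd.DataFrame(
        truth_rows,
        columns=["complex_id", "origin", "tads", "parents", "junctions"],
    )
    return SimulatedDataset(
        cfg, complexes, truth, coverage, {cfg.chrom: cfg.chrom_length}
    )
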