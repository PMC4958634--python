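"""Copy-number-variable regions: reciprocal-overlap merging, summaries, gene overlap.

Per-sample CNV calls are merged within and across samples into CNVRs: two calls are
linked when they show at least 50% pairwise reciprocal overlap (the overlap length
must be >= t of BOTH call lengths), and each connected component of that link graph —
single linkage over the ORIGINAL calls, not over growing merged spans — becomes one
CNVR spanning the union of its members. Because linkage is evaluated on the original
calls, two CNVRs may physically overlap without being merged, which is why the sum of
CNVR sizes can exceed the unique (union) span.

All coordinates are 0-based half-open internally; GFF3 (1-based closed) is converted
at the boundary. Strand is ignored for CNVR-gene overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "reciprocal_overlap",
    "build_cnvrs",
    "summarize",
    "overlap_genes",
    "CnvRegion",
    "CnvrSummary",
]

ALLOSOMES = {"X", "Y", "chrX", "chrY"}
BP_PER_MB = 1e6


@dataclass(frozen=True)
class CnvRegion:
    """One CNVR: the union span of a connected component of reciprocally-overlapping calls."""

    chrom: str
    start: int
    end: int
    member_calls: tuple[int, ...]
    n_samples: int
    type: str  # gain / loss / mixed

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnvrSummary:
    n_cnvrs: int
    n_autosomal: int
    n_allosomal: int
    size_min_mb: float
    size_max_mb: float
    size_mean_mb: float
    size_median_mb: float
    unique_span_mb: float
    genome_fraction_pct: float = field(default=float("nan"))


def reciprocal_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int], t: float = 0.5
) -> tuple[float, float, bool]:
    """Overlap fractions of two half-open intervals and the predicate at threshold t.

    Returns ``(o/len(a), o/len(b), passes)`` where ``passes`` requires BOTH fractions
    to be >= t. Intervals on different chromosomes never pass and have fractions 0.
    """
    (ca, sa, ea), (cb, sb, eb) = a, b
    if ea <= sa or eb <= sb:
        raise ValueError("intervals must have end > start")
    if ca != cb:
        return 0.0, 0.0, False
    o = min(ea, eb) - max(sa, sb)
    if o <= 0:
        return 0.0, 0.0, False
    fa, fb = o / (ea - sa), o / (eb - sb)
    return fa, fb, (fa >= t and fb >= t)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_cnvrs(calls: pd.DataFrame, t: float = 0.5) -> list[CnvRegion]:
    """Single-linkage CNVR construction from per-sample calls.

    Parameters
    ----------
    calls
        DataFrame with columns ``chrom``, ``start``, ``end``, ``sample``, ``cn``
        (half-open bp coordinates). Row order is irrelevant; components are
        order-independent.
    t
        Reciprocal-overlap threshold for a merge edge (default 0.5).

    Returns
    -------
    List of :class:`CnvRegion` sorted by (chrom, start). ``member_calls`` holds the
    positional indices of ``calls`` rows; ``type`` is gain/loss/mixed from the
    members' copy numbers relative to diploid.
    """
    n = len(calls)
    uf = _UnionFind(n)
    df = calls.reset_index(drop=True)
    order = df.sort_values(["chrom", "start", "end"]).index.to_numpy()
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    # sorted sweep: only pairs that physically overlap can pass the predicate
    active: list[int] = []
    prev_chrom = None
    for i in order:
        if chroms[i] != prev_chrom:
            active = []
            prev_chrom = chroms[i]
        active = [j for j in active if ends[j] > starts[i]]
        for j in active:
            o = min(ends[i], ends[j]) - max(starts[i], starts[j])
            if o >= t * (ends[i] - starts[i]) and o >= t * (ends[j] - starts[j]):
                uf.union(i, j)
        active.append(int(i))

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    regions = []
    for members in comps.values():
        sub = df.loc[members]
        cns = sub["cn"].to_numpy()
        gains, losses = (cns > 2).any(), (cns < 2).any()
        rtype = "mixed" if (gains and losses) else ("gain" if gains else "loss")
        regions.append(
            CnvRegion(
                chrom=str(sub["chrom"].iloc[0]),
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                member_calls=tuple(sorted(members)),
                n_samples=int(sub["sample"].nunique()),
                type=rtype,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def _union_length(regions: list[CnvRegion]) -> int:
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def summarize(regions: list[CnvRegion], genome_length: int | None = None) -> CnvrSummary:
    """Size statistics (Mb), unique union span and genome fraction of a CNVR set.

    ``genome_fraction_pct`` is 100 * unique_span / genome_length, rounded to two
    decimals on the percent scale.
    """
    if not regions:
        raise ValueError("no CNVRs to summarize")
    sizes = np.array([r.length for r in regions], dtype=float) / BP_PER_MB
    uniq = _union_length(regions) / BP_PER_MB
    allo = sum(r.chrom in ALLOSOMES for r in regions)
    frac = float("nan")
    if genome_length is not None:
        if genome_length <= 0:
            raise ValueError("genome_length must be positive")
        frac = round(100.0 * uniq * BP_PER_MB / genome_length, 2)
    return CnvrSummary(
        n_cnvrs=len(regions),
        n_autosomal=len(regions) - allo,
        n_allosomal=allo,
        size_min_mb=float(sizes.min()),
        size_max_mb=float(sizes.max()),
        size_mean_mb=float(sizes.mean()),
        size_median_mb=float(np.median(sizes)),
        unique_span_mb=uniq,
        genome_fraction_pct=frac,
    )


def overlap_genes(regions: list[CnvRegion], annotation: pd.DataFrame) -> list[str]:
    """Genes whose span intersects any CNVR by at least 1 bp (partial overlap counts).

    ``annotation`` needs columns ``chrom``, ``start``, ``end``, ``gene`` in half-open
    coordinates (see :func:`feedquad.io.read_gene_annotation` for GFF3/BED loading).
    Malformed rows (end <= start or missing fields) are skipped and counted in a log
    message. Each gene is reported once, in sorted order.
    """
    import logging

    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    hits: set[str] = set()
    bad = 0
    for row in annotation.itertuples(index=False):
        try:
            chrom, start, end, gene = str(row.chrom), int(row.start), int(row.end), row.gene
        except (ValueError, TypeError, AttributeError):
            bad += 1
            continue
        if end <= start or pd.isna(gene):
            bad += 1
            continue
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            hits.add(str(gene))
    if bad:
        logging.getLogger(__name__).warning("skipped %d malformed annotation rows", bad)
    return sorted(hits)
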