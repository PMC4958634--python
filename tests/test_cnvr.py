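"""Reciprocal-overlap merging, CNVR summaries and gene overlap vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from feedquad.cnvr import (
    build_cnvrs,
    overlap_genes,
    reciprocal_overlap,
    summarize,
)


def brute_force_components(calls, t=0.5):
    """O(n^2) all-pairs union-find oracle over the reciprocal-overlap relation."""
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rows = calls.reset_index(drop=True)
    for i in range(n):
        for j in range(i + 1, n):
            a = (rows["chrom"][i], rows["start"][i], rows["end"][i])
            b = (rows["chrom"][j], rows["start"][j], rows["end"][j])
            if reciprocal_overlap(a, b, t)[2]:
                parent[find(j)] = find(i)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


def random_calls(rng, n, n_chroms=3, span=1_000_000):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(500, 20_000, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice([str(c + 1) for c in range(n_chroms)], n),
            "start": starts,
            "end": starts + lengths,
            "sample": rng.choice(["s1", "s2", "s3", "s4"], n),
            "cn": rng.choice([0, 1, 3, 4], n),
        }
    )


class TestReciprocalOverlap:
    def test_symmetric_half_overlap_passes_at_half(self):
        fa, fb, ok = reciprocal_overlap(("1", 100, 200), ("1", 150, 250), 0.5)
        assert (fa, fb, ok) == (0.5, 0.5, True)

    def test_small_overlap_fails(self):
        fa, fb, ok = reciprocal_overlap(("1", 0, 100), ("1", 90, 200), 0.5)
        assert fa == pytest.approx(0.10)
        assert fb == pytest.approx(10 / 110)
        assert not ok

    def test_identical_intervals_pass_any_threshold(self):
        assert reciprocal_overlap(("1", 5, 50), ("1", 5, 50), 1.0) == (1.0, 1.0, True)

    def test_different_chromosomes_never_pass(self):
        assert reciprocal_overlap(("1", 0, 100), ("2", 0, 100), 0.1) == (0.0, 0.0, False)

    def test_one_sided_containment_needs_both_fractions(self):
        # b inside a covers all of b but little of a
        fa, fb, ok = reciprocal_overlap(("1", 0, 1000), ("1", 0, 100), 0.5)
        assert fb == 1.0 and fa == pytest.approx(0.1) and not ok


class TestBuildCnvrs:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "cn"])

    def test_single_call_is_its_own_cnvr(self):
        regions = build_cnvrs(self._calls([("1", 0, 100, "s1", 1)]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end, regions[0].type) == (0, 100, "loss")

    def test_transitive_chain_merges_into_one_region(self):
        """Edges (1,2) and (2,3) but not (1,3) still give one CNVR [0,180)."""
        regions = build_cnvrs(
            self._calls(
                [("1", 0, 100, "s1", 3), ("1", 40, 140, "s2", 3), ("1", 80, 180, "s3", 1)]
            )
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 180)
        assert regions[0].n_samples == 3
        assert regions[0].type == "mixed"

    def test_matches_brute_force_oracle_on_random_calls(self, rng):
        calls = random_calls(rng, 300)
        regions = build_cnvrs(calls)
        got = {frozenset(r.member_calls) for r in regions}
        assert got == brute_force_components(calls)

    def test_components_independent_of_input_order(self, rng):
        calls = random_calls(rng, 150)
        base = {
            (r.chrom, r.start, r.end, frozenset(r.member_calls))
            for r in build_cnvrs(calls)
        }
        for _ in range(20):
            perm = calls.sample(frac=1, random_state=int(rng.integers(1 << 30)))
            idx_map = {new: old for new, old in enumerate(perm.index)}
            shuffled = {
                (r.chrom, r.start, r.end, frozenset(idx_map[m] for m in r.member_calls))
                for r in build_cnvrs(perm)
            }
            assert shuffled == base

    def test_cnvr_count_monotone_in_threshold(self, rng):
        calls = random_calls(rng, 400)
        counts = [len(build_cnvrs(calls, t)) for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts)


class TestSummarize:
    def _regions(self, spans):
        calls = pd.DataFrame(
            [(c, s, e, "s1", 3) for c, s, e in spans],
            columns=["chrom", "start", "end", "sample", "cn"],
        )
        # spans widely separated -> each its own component unless overlapping
        return build_cnvrs(calls)

    def test_study_scale_genome_fraction(self):
        """12.0038 unique Mb over a 2,670.04 Mb genome is 0.45%."""
        regions = self._regions([("1", 0, 12_003_800)])
        summary = summarize(regions, genome_length=2_670_040_000)
        assert summary.unique_span_mb == pytest.approx(12.0038)
        assert summary.genome_fraction_pct == 0.45

    def test_disjoint_regions_sum(self):
        s = summarize(self._regions([("1", 0, 10 ** 6), ("1", 5 * 10 ** 6, 6 * 10 ** 6)]))
        assert s.unique_span_mb == pytest.approx(2.0)
        assert s.size_mean_mb == pytest.approx(1.0)
        assert s.n_cnvrs == 2

    def test_overlapping_distinct_components_exceed_unique_span(self):
        """Two CNVRs [0,2) and [1,3) Mb: sizes sum to 4 Mb but the union is 3 Mb."""
        a = self._regions([("1", 0, 2_000_000)])
        b = self._regions([("1", 1_000_000, 3_000_000)])
        s = summarize(a + b)
        assert s.size_mean_mb * s.n_cnvrs == pytest.approx(4.0)
        assert s.unique_span_mb == pytest.approx(3.0)

    def test_allosome_partition(self):
        s = summarize(self._regions([("1", 0, 1000), ("chrX", 0, 1000)]))
        assert (s.n_autosomal, s.n_allosomal) == (1, 1)


class TestOverlapGenes:
    def _annotation(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])

    def test_contained_and_single_bp_overlaps_reported(self):
        regions = build_cnvrs(
            pd.DataFrame(
                [("1", 1000, 2000, "s1", 1)],
                columns=["chrom", "start", "end", "sample", "cn"],
            )
        )
        ann = self._annotation(
            [
                ("1", 1200, 1300, "inside"),
                ("1", 1999, 2500, "one_bp"),
                ("1", 2000, 2500, "adjacent_not_overlapping"),
                ("2", 1200, 1300, "wrong_chrom"),
            ]
        )
        assert overlap_genes(regions, ann) == ["inside", "one_bp"]

    def test_matches_brute_force_intersection(self, rng):
        calls = random_calls(rng, 100)
        regions = build_cnvrs(calls)
        starts = rng.integers(0, 1_000_000, 300)
        ann = self._annotation(
            [
                (str(rng.integers(1, 4)), int(s), int(s + rng.integers(100, 30_000)), f"g{k}")
                for k, s in enumerate(starts)
            ]
        )
        expect = set()
        for r in regions:
            for row in ann.itertuples(index=False):
                if row.chrom == r.chrom and row.start < r.end and r.start < row.end:
                    expect.add(row.gene)
        assert overlap_genes(regions, ann) == sorted(expect)

    def test_malformed_rows_skipped_with_count(self, caplog):
        regions = build_cnvrs(
            pd.DataFrame(
                [("1", 0, 1000, "s1", 1)], columns=["chrom", "start", "end", "sample", "cn"]
            )
        )
        ann = self._annotation([("1", 10, 20, "good"), ("1", 30, 30, "empty_span")])
        with caplog.at_level("WARNING"):
            out = overlap_genes(regions, ann)
        assert out == ["good"]
        assert "1 malformed" in caplog.text
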