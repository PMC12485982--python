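"""Element classification: peak calling, divergent pairing, annotation."""

import itertools

import numpy as np
import pytest

from procap_atlas import (
    Element,
    GenomicInterval,
    Peak,
    TruthConfig,
    annotate_context,
    annotate_proximity,
    naive_peak_call,
    pair_divergent,
    simulate_dataset,
)
from procap_atlas.shape import pool_tissue_signal
from conftest import make_track


def peak(summit, strand, chrom="chr1", halfwidth=20, count=10):
    return Peak(
        GenomicInterval(chrom, summit - halfwidth, summit + halfwidth + 1, strand),
        summit,
        count,
    )


class TestNaivePeakCall:
    def test_single_hot_position(self):
        t = make_track({("chr1", "+"): {1000: 10}})
        peaks = naive_peak_call(t, min_count=5, window=10)
        assert len(peaks) == 1
        assert peaks[0].summit == 1000
        assert peaks[0].count == 10

    def test_all_zero_track_yields_nothing(self):
        from procap_atlas import SignalTrack

        assert naive_peak_call(SignalTrack(), min_count=5, window=10) == []

    def test_islands_separated_beyond_window_split(self):
        t = make_track({("chr1", "+"): {100: 6, 101: 6, 200: 6, 201: 6}})
        peaks = naive_peak_call(t, min_count=5, window=10)
        assert len(peaks) == 2
        assert [p.summit for p in peaks] == [100, 200]

    def test_matches_brute_force_run_enumeration(self, rng):
        """Oracle: mark every window start whose sum >= min_count, take maximal
        runs, trim to nonzero positions — computed by brute force."""
        min_count, window = 4, 6
        for _ in range(25):
            positions = rng.choice(200, size=12, replace=False)
            counts = {int(p): int(c) for p, c in zip(positions, rng.integers(1, 5, 12))}
            t = make_track({("chr1", "+"): counts})
            dense = np.zeros(300, dtype=int)
            for p, c in counts.items():
                dense[p] = c
            hot = [
                i
                for i in range(300 - window)
                if dense[i : i + window].sum() >= min_count
            ]
            expected = []
            for _, grp in itertools.groupby(enumerate(hot), key=lambda t: t[1] - t[0]):
                run = [i for _, i in grp]
                lo, hi = run[0], run[-1] + window
                nz = np.flatnonzero(dense[lo:hi])
                if len(nz):
                    expected.append((lo + nz[0], lo + nz[-1] + 1))
            got = [(p.interval.start, p.interval.end) for p in naive_peak_call(t, min_count, window)]
            assert got == expected


def nearest_first_oracle(plus_summits, minus_summits, max_gap):
    """Independent exhaustive implementation of nearest-first matching.

    Repeatedly scans all remaining cross-strand pairs for the global
    minimum distance (O(n^3), no sorting) and — unlike the library's
    leftmost tie-break — resolves exact ties to the *rightmost* summits,
    so any disagreement with the library localizes an exact distance tie.
    Returns the number of pairs formed.
    """
    used_p, used_m = set(), set()
    pairs = 0
    while True:
        cands = [
            (abs(p - m), p, m, pi, mi)
            for pi, p in enumerate(plus_summits)
            if pi not in used_p
            for mi, m in enumerate(minus_summits)
            if mi not in used_m and abs(p - m) <= max_gap
        ]
        if not cands:
            return pairs
        dmin = min(c[0] for c in cands)
        choice = max((c for c in cands if c[0] == dmin), key=lambda c: (c[1], c[2]))
        used_p.add(choice[3])
        used_m.add(choice[4])
        pairs += 1


def brute_force_matching(plus_summits, minus_summits, max_gap):
    """Maximum-cardinality, minimum-total-distance matching by enumeration."""
    best = (0, 0.0)  # (n_pairs, -total_dist) to maximize
    n_p, n_m = len(plus_summits), len(minus_summits)
    feasible = {
        (i, j)
        for i in range(n_p)
        for j in range(n_m)
        if abs(plus_summits[i] - minus_summits[j]) <= max_gap
    }

    def rec(i, used_m, n_pairs, total):
        nonlocal best
        if i == n_p:
            cand = (n_pairs, -total)
            if cand > best:
                best = cand
            return
        rec(i + 1, used_m, n_pairs, total)  # leave plus i unmatched
        for j in range(n_m):
            if j not in used_m and (i, j) in feasible:
                rec(i + 1, used_m | {j}, n_pairs + 1,
                    total + abs(plus_summits[i] - minus_summits[j]))

    rec(0, frozenset(), 0, 0.0)
    return best[0]


class TestPairDivergent:
    def test_summits_within_gap_pair(self):
        els = pair_divergent([peak(1000, "+")], [peak(1250, "-")])
        assert [e.directionality for e in els] == ["divergent"]
        e = els[0]
        assert e.span.start == min(e.plus_peak.interval.start, e.minus_peak.interval.start)
        assert e.span.end == max(e.plus_peak.interval.end, e.minus_peak.interval.end)

    def test_summits_beyond_gap_stay_unidirectional(self):
        els = pair_divergent([peak(1000, "+")], [peak(1400, "-")])
        assert sorted(e.directionality for e in els) == ["unidirectional", "unidirectional"]

    def test_tie_breaks_to_leftmost_plus_summit(self):
        els = pair_divergent([peak(1000, "+"), peak(1100, "+")], [peak(1050, "-")])
        div = [e for e in els if e.directionality == "divergent"]
        assert len(div) == 1
        assert div[0].plus_peak.summit == 1000
        uni = [e for e in els if e.directionality == "unidirectional"]
        assert uni[0].plus_peak.summit == 1100

    def test_partition_every_peak_in_exactly_one_element(self, rng):
        plus = [peak(int(s), "+") for s in rng.choice(5000, 8, replace=False)]
        minus = [peak(int(s), "-") for s in rng.choice(5000, 8, replace=False)]
        els = pair_divergent(plus, minus)
        seen = [id(p) for e in els for p in e.peaks]
        assert sorted(seen) == sorted(id(p) for p in plus + minus)

    def test_result_invariant_under_input_order(self, rng):
        plus = [peak(int(s), "+") for s in rng.choice(3000, 6, replace=False)]
        minus = [peak(int(s), "-") for s in rng.choice(3000, 6, replace=False)]
        ref = pair_divergent(plus, minus)
        shuffled = pair_divergent(plus[::-1], list(reversed(minus)))
        assert [e.element_id for e in ref] == [e.element_id for e in shuffled]
        assert [e.directionality for e in ref] == [e.directionality for e in shuffled]

    def test_duplicate_peaks_rejected(self):
        p = peak(100, "+")
        with pytest.raises(ValueError, match="duplicate"):
            pair_divergent([p, peak(100, "+")], [])

    def test_greedy_agrees_with_exhaustive_nearest_first_oracle(self, rng):
        """Greedy pair counts equal an independent repeated-global-argmin
        implementation of the same rule except at exact distance ties, and
        never exceed the true maximum matching."""
        for trial in range(200):
            n_p = int(rng.integers(1, 7))
            n_m = int(rng.integers(1, 7))
            ps = sorted(rng.choice(np.arange(50, 3000, 50), n_p, replace=False).tolist())
            ms = sorted(rng.choice(np.arange(75, 3000, 50), n_m, replace=False).tolist())
            els = pair_divergent(
                [peak(s, "+") for s in ps], [peak(s, "-") for s in ms], max_gap=300
            )
            greedy = sum(e.directionality == "divergent" for e in els)
            oracle = nearest_first_oracle(ps, ms, 300)
            if greedy != oracle:
                dists = [abs(p - m) for p in ps for m in ms if abs(p - m) <= 300]
                assert len(dists) != len(set(dists)), (ps, ms)
            assert greedy <= brute_force_matching(ps, ms, 300)


class TestAnnotation:
    def make_element(self, start, end, chrom="chr1"):
        return Element(
            "e", GenomicInterval(chrom, start, end), "unidirectional",
            plus_peak=peak((start + end) // 2, "+", chrom=chrom, halfwidth=(end - start) // 2 - 1),
        )

    def test_proximity_boundary_inclusive(self, toy_genes):
        # geneA TSS at 10_000; element midpoint exactly 500 away
        e = self.make_element(10_400, 10_600)  # midpoint 10_500
        (out,) = annotate_proximity([e], toy_genes)
        assert out.proximity == "proximal"

    def test_just_beyond_cutoff_is_distal(self, toy_genes):
        e = self.make_element(10_401, 10_601)  # midpoint 10_501
        (out,) = annotate_proximity([e], toy_genes)
        assert out.proximity == "distal"

    def test_chromosome_without_genes_is_distal(self, toy_genes):
        e = self.make_element(100, 300, chrom="chr7")
        (out,) = annotate_proximity([e], toy_genes)
        assert out.proximity == "distal"

    def test_minus_strand_gene_tss_is_right_edge(self, toy_genes):
        # geneB on minus strand: TSS at 70_000 - 1
        e = self.make_element(69_900, 70_100)
        (out,) = annotate_proximity([e], toy_genes)
        assert out.proximity == "proximal"

    def test_context_inside_gene(self, toy_genes):
        (out,) = annotate_context([self.make_element(15_000, 15_200)], toy_genes)
        assert out.context == "intragenic"

    def test_context_far_from_genes(self, toy_genes):
        (out,) = annotate_context([self.make_element(40_000, 40_200)], toy_genes)
        assert out.context == "intergenic"

    def test_one_bp_overlap_is_intragenic(self, toy_genes):
        # geneA spans [10_000, 30_000); element ending at 10_001 overlaps 1 bp
        (out,) = annotate_context([self.make_element(9_801, 10_001)], toy_genes)
        assert out.context == "intragenic"
        (out,) = annotate_context([self.make_element(9_800, 10_000)], toy_genes)
        assert out.context == "intergenic"


class TestSyntheticRecovery:
    def test_directionality_recovered_without_noise(self):
        cfg = TruthConfig(
            background_rate=0.0,
            frac_peaked=1.0,
            divergent_gap=(80, 290),
            tissues={"liver": 2},
            seed=7,
        )
        ds = simulate_dataset(cfg)
        pooled = pool_tissue_signal(list(ds.tracks5.values()))
        peaks = naive_peak_call(pooled, min_count=10, window=20)
        plus = [p for p in peaks if p.interval.strand == "+"]
        minus = [p for p in peaks if p.interval.strand == "-"]
        called = pair_divergent(plus, minus, max_gap=300)
        # match each truth element to the called element containing its midpoint
        correct = 0
        for t in ds.truth:
            mid = t.interval.midpoint
            hits = [e for e in called if e.span.chrom == t.interval.chrom
                    and e.span.contains(mid)]
            if len(hits) == 1 and hits[0].directionality == t.directionality:
                correct += 1
        assert correct == len(ds.truth)
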