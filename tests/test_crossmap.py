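"""Chain parsing, liftover semantics (including minus strand), conservation
rate against simulation truth, and overlap statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from hmcdiff.bins import make_bins
from hmcdiff.crossmap import (
    ChainFormatError,
    LiftoverParams,
    conservation_rate,
    invert_chain,
    liftover,
    ortholog_overlap,
    parse_chain,
    region_overlap_test,
)

IDENTITY = "chain 100 chr1 1000 + 0 1000 chrA 1000 + 0 1000 1\n1000\n"

SHIFT100 = "chain 100 chr1 1000 + 0 900 chrA 1100 + 100 1000 1\n900\n"

# two blocks of 400, a 100 bp source gap between them
GAPPED = "chain 100 chr1 1000 + 0 900 chrA 1000 + 0 800 1\n400 100 0\n400\n"

# inversion: chr1:[0,600) maps to the minus strand of chrA (size 1000)
INVERTED = "chain 100 chr1 1000 + 0 600 chrA 1000 - 0 600 1\n600\n"


class TestParse:
    def test_minimal_identity_chain(self):
        chains = parse_chain(IDENTITY)
        assert len(chains) == 1
        c = chains[0]
        assert c.blocks == [(1000, 0, 0)]
        assert c.src_end - c.src_start == 1000

    def test_block_sum_mismatch_rejected(self):
        bad = "chain 100 chr1 1000 + 0 1000 chrA 1000 + 0 1000 1\n900\n"
        with pytest.raises(ChainFormatError):
            parse_chain(bad)

    def test_two_block_gap_offsets(self):
        """Source gap of 100: source 500 (in block 2) maps to target 400."""
        c = parse_chain(GAPPED)[0]
        res = liftover(("chr1", 500, 600), [c])
        assert res.mapped == ("chrA", 400, 500, "+")

    def test_malformed_header_rejected(self):
        with pytest.raises(ChainFormatError):
            parse_chain("chain 1 2 3\n100\n")


class TestLiftover:
    def test_identity(self):
        c = parse_chain(IDENTITY)
        res = liftover(("chr1", 100, 300), c)
        assert res.mapped == ("chrA", 100, 300, "+")
        assert res.fraction == 1.0

    def test_constant_shift(self):
        c = parse_chain(SHIFT100)
        assert liftover(("chr1", 50, 150), c).mapped == ("chrA", 150, 250, "+")

    def test_partial_below_min_ratio(self):
        """Half the region sits in an unaligned gap: unmapped(partial)."""
        c = parse_chain(GAPPED)
        res = liftover(("chr1", 350, 550), c, LiftoverParams(min_ratio=0.95))
        assert not res.ok and res.reason == "partial"
        assert res.fraction == pytest.approx(0.5)

    def test_no_chain_for_chrom(self):
        res = liftover(("chr9", 0, 100), parse_chain(IDENTITY))
        assert res.reason == "none"

    def test_region_outside_all_blocks_deleted(self):
        res = liftover(("chr1", 950, 1000), parse_chain(SHIFT100))
        assert res.reason == "deleted"

    def test_inversion_reverses_interval_order(self):
        """On a minus-strand chain, source [0,100) and [500,600) swap ends of
        the target interval."""
        c = parse_chain(INVERTED)
        lo = liftover(("chr1", 0, 100), c).mapped
        hi = liftover(("chr1", 500, 600), c).mapped
        assert lo == ("chrA", 900, 1000, "-")
        assert hi == ("chrA", 400, 500, "-")

    def test_round_trip_through_inverted_chain(self):
        for text in (IDENTITY, SHIFT100, GAPPED, INVERTED):
            c = parse_chain(text)[0]
            inv = invert_chain(c)
            region = ("chr1", 10, 110)
            m = liftover(region, [c])
            if not m.ok:
                continue
            back = liftover(m.mapped[:3], [inv])
            assert back.mapped[:3] == region


class TestConservation:
    def test_all_mapped_identity(self):
        regions = pd.DataFrame({"chrom": "chr1", "start": [0, 200], "end": [100, 400]})
        rate, report = conservation_rate(regions, parse_chain(IDENTITY))
        assert rate == 1.0 and (report.status == "mapped").all()

    def test_no_chains_for_chroms(self):
        regions = pd.DataFrame({"chrom": "chrX", "start": [0], "end": [100]})
        rate, report = conservation_rate(regions, parse_chain(IDENTITY))
        assert rate == 0.0 and report.status.iloc[0] == "none"

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            conservation_rate(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                              parse_chain(IDENTITY))

    def test_matches_simulation_truth_exactly(self, bundle):
        chains = parse_chain(bundle.chain_text)
        regions = bundle.truth.planted_gain[["chrom", "start", "end"]]
        rate, _ = conservation_rate(regions, chains)
        assert rate == bundle.truth.mappable_fraction(regions)

    def test_truth_segments_map_exactly(self, bundle):
        """Every recorded aligned segment lifts to its recorded destination,
        including the minus-strand chromosome."""
        chains = parse_chain(bundle.chain_text)
        for _, s in bundle.truth.chain_segments.iterrows():
            res = liftover((s.src_chrom, s.src_start + 7, s.src_start + 207), chains)
            if s.strand == "+":
                assert res.mapped == (s.dst_chrom, s.dst_start + 7, s.dst_start + 207, "+")
            else:
                assert res.mapped == (s.dst_chrom, s.dst_end - 207, s.dst_end - 7, "-")


class TestOverlapStats:
    def test_identical_sets(self):
        grid = make_bins({"chr1": 20_000}, 2000)
        a = pd.DataFrame({"chrom": "chr1", "start": [0, 4000], "end": [2000, 6000]})
        n, pct, p, _ = region_overlap_test(a, a, grid)
        assert n == 2 and pct == 100.0

    def test_disjoint_sets(self):
        grid = make_bins({"chr1": 20_000}, 2000)
        a = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [2000]})
        b = pd.DataFrame({"chrom": "chr1", "start": [4000], "end": [6000]})
        n, pct, p, _ = region_overlap_test(a, b, grid)
        assert n == 0 and pct == 0.0 and p > 0.5

    def test_hypergeometric_tail_enumeration(self):
        """10-bin universe, |A|=4, |B|=5, overlap 4: p = enumeration tail."""
        from math import comb

        grid = make_bins({"chr1": 20_000}, 2000)
        a = pd.DataFrame({"chrom": "chr1", "start": [0, 2000, 4000, 6000],
                          "end": [2000, 4000, 6000, 8000]})
        b = pd.DataFrame({"chrom": "chr1", "start": [0, 2000, 4000, 6000, 8000],
                          "end": [2000, 4000, 6000, 8000, 10000]})
        n, pct, p, _ = region_overlap_test(a, b, grid)
        assert n == 4 and pct == 100.0
        # drawing |A|=4 bins from 10 with 5 marked: P(all 4 marked)
        expected = comb(5, 4) * comb(5, 0) / comb(10, 4)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_one_bp_overlap_marks_bin(self):
        grid = make_bins({"chr1": 20_000}, 2000)
        a = pd.DataFrame({"chrom": "chr1", "start": [1999], "end": [2001]})
        b = pd.DataFrame({"chrom": "chr1", "start": [2000], "end": [4000]})
        n, pct, _, _ = region_overlap_test(a, b, grid)
        assert n == 1  # bins [0,2000) and [2000,4000) both marked by A


class TestOrthologOverlap:
    def test_printed_counts_reproduce_percentage(self):
        """461 common of 779 orthologous genes -> 59.18%."""
        genes_a = [f"h{i}" for i in range(461 + 318 + 50)]
        omap = pd.DataFrame(
            {"gene_a": [f"h{i}" for i in range(461 + 318)],
             "gene_b": [f"m{i}" for i in range(461 + 318)]}
        )
        genes_b = [f"m{i}" for i in range(461)]
        counts, pct = ortholog_overlap(genes_a, omap, genes_b)
        assert counts == {"no_ortholog": 50, "ortholog_only": 318, "common": 461}
        assert round(pct, 2) == 59.18

    def test_all_common(self):
        omap = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        counts, pct = ortholog_overlap(["a"], omap, ["b"])
        assert pct == 100.0

    def test_empty_map_gives_na(self):
        omap = pd.DataFrame({"gene_a": [], "gene_b": []})
        counts, pct = ortholog_overlap(["a", "b"], omap, ["x"])
        assert counts["no_ortholog"] == 2 and math.isnan(pct)

    def test_one_to_many_collapsed_to_first(self):
        omap = pd.DataFrame({"gene_a": ["a", "a"], "gene_b": ["m1", "m2"]})
        _, pct = ortholog_overlap(["a"], omap, ["m2"])
        assert pct == 0.0  # first mapping (m1) wins and is absent from B
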