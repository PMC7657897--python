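"""Degenerate/near-miss scanning, pairing and upstream coordinates."""

import pytest
from hypothesis import given, settings, strategies as st

from cpscan.io_formats import SeqRecord
from cpscan.motif_scan import (
    EBOX_GENERIC,
    MotifHit,
    EBOX_MYOD,
    MotifPattern,
    PromoterRegion,
    compare_regions,
    find_near_misses,
    from_upstream_coords,
    iupac_matches,
    pair_hits,
    revcomp,
    scan,
    to_upstream_coords,
)
from cpscan.study_inputs import ALCALICA_PAIRED_EBOX, NILOTICUS_EBOX_FRAGMENT

from helpers_oracles import brute_force_scan


def region(seq, seq_id="r"):
    return PromoterRegion(record=SeqRecord(id=seq_id, residues=seq, alphabet="dna"))


class TestIupacMatches:
    @pytest.mark.parametrize(
        "symbol,base,expected",
        [("S", "G", True), ("S", "C", True), ("S", "A", False),
         ("N", "T", True), ("N", "A", True),
         ("A", "A", True), ("A", "G", False),
         ("R", "A", True), ("Y", "A", False),
         ("A", "N", False), ("N", "N", False)],  # subject N matches nothing
    )
    def test_symbol_semantics(self, symbol, base, expected):
        assert iupac_matches(symbol, base) is expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            iupac_matches("Z", "A")
        with pytest.raises(ValueError):
            MotifPattern("bad", "CAOGTG")


class TestScanPrintedFragments:
    """The two 31-nt upstream fragments of the cross-species comparison."""

    def test_alcalica_has_exact_myod_pair(self, alcalica_region):
        hits = scan(alcalica_region, EBOX_MYOD, max_mismatches=0)
        assert [(h.start, h.end) for h in hits] == [(1, 6), (26, 31)]
        assert all(h.is_exact for h in hits)
        pairs = pair_hits(hits, max_gap=19)
        assert len(pairs) == 1 and pairs[0].gap == 19

    def test_alcalica_generic_ebox_starts(self, alcalica_region):
        hits = scan(alcalica_region, EBOX_GENERIC, max_mismatches=0)
        assert [h.start for h in hits] == [1, 26]

    def test_niloticus_single_exact_myod_motif(self, niloticus_region):
        hits = scan(niloticus_region, EBOX_MYOD, max_mismatches=0)
        assert len(hits) == 1 and hits[0].start == 1

    def test_fragments_differ_by_one_substitution(self):
        diffs = [
            (a, b) for a, b in zip(ALCALICA_PAIRED_EBOX, NILOTICUS_EBOX_FRAGMENT) if a != b
        ]
        assert len(ALCALICA_PAIRED_EBOX) == len(NILOTICUS_EBOX_FRAGMENT) == 31
        assert len(diffs) == 1


class TestNearMisses:
    def test_niloticus_caggtt_near_miss(self, niloticus_region):
        near = find_near_misses(niloticus_region, EBOX_MYOD, k=1)
        caggtt = [h for h in near if h.matched == "CAGGTT"]
        assert len(caggtt) == 1
        hit = caggtt[0]
        assert hit.mismatches == 1 and (hit.start, hit.end) == (26, 31)
        # the reported edit restores the degraded motif and the inter-species identity
        offset, offending, replacement = hit.replacements[0]
        assert offending == "T"
        edited = list(NILOTICUS_EBOX_FRAGMENT)
        edited[hit.start - 1 + offset] = replacement
        assert "".join(edited) == ALCALICA_PAIRED_EBOX

    def test_exact_windows_excluded(self, alcalica_region):
        near = find_near_misses(alcalica_region, EBOX_MYOD, k=1)
        assert all(h.mismatches >= 1 for h in near)
        assert 26 not in [h.start for h in near]

    def test_k_zero_is_an_error(self, alcalica_region):
        with pytest.raises(ValueError, match="use scan"):
            find_near_misses(alcalica_region, EBOX_MYOD, k=0)

    def test_pattern_longer_than_region_is_empty(self):
        assert find_near_misses(region("ACG"), EBOX_MYOD, k=1) == []
        assert scan(region("ACG"), EBOX_MYOD) == []

    def test_empty_region_is_an_error(self):
        rec = SeqRecord(id="e", residues="A", alphabet="dna")
        rec.residues = ""
        with pytest.raises(ValueError, match="empty"):
            scan(PromoterRegion(record=rec), EBOX_MYOD)


class TestPairing:
    def test_exact_pair_gap_19(self, alcalica_region):
        hits = scan(alcalica_region, EBOX_MYOD)
        [pair] = pair_hits(hits, max_gap=25)
        assert (pair.first.start, pair.first.end) == (1, 6)
        assert (pair.second.start, pair.second.end) == (26, 31)
        assert pair.gap == 19 and pair.category == "exact"

    def test_presumptive_pair_with_near_miss_partner(self, niloticus_region):
        hits = scan(niloticus_region, EBOX_MYOD) + find_near_misses(niloticus_region, EBOX_MYOD, 1)
        pairs = pair_hits(hits, max_gap=19, allow_near_miss_partner=True)
        assert [p.category for p in pairs] == ["presumptive"]
        assert pairs[0].gap == 19
        # without the flag no pair is formed
        assert pair_hits(hits, max_gap=19) == []

    def test_gap_threshold_excludes_distant_hits(self):
        r = region("CAGGTG" + "A" * 30 + "CAGGTG")
        hits = scan(r, EBOX_MYOD)
        assert pair_hits(hits, max_gap=25) == []
        assert len(pair_hits(hits, max_gap=30)) == 1

    def test_overlapping_hits_do_not_pair(self):
        # CANNTG windows at 1 and 3 overlap
        r = region("CACATGTG")
        hits = scan(r, EBOX_GENERIC)
        assert any(h.start == 1 for h in hits) and any(h.start == 3 for h in hits)
        assert pair_hits(hits, max_gap=19) == []

    def test_mixed_region_hits_rejected(self):
        h1 = scan(region("CAGGTGA", "a"), EBOX_MYOD)
        h2 = scan(region("CAGGTGA", "b"), EBOX_MYOD)
        with pytest.raises(ValueError, match="single region"):
            pair_hits(h1 + h2)


class TestUpstreamCoords:
    @pytest.mark.parametrize("span,expected", [((1, 6), (3500, 3495)), ((3495, 3500), (6, 1))])
    def test_formula(self, span, expected):
        r = region("A" * 3500)
        hit = MotifHit(seq_id="r", start=span[0], end=span[1], strand="+",
                        pattern="p", mismatches=0, matched="CAGGTG")
        assert to_upstream_coords(hit, r) == expected

    def test_composite_pair_distal_edge(self):
        """A 31-base composite ending 940 upstream starts 970 upstream."""
        L = 3500
        start = L - 970 + 1
        r = region("A" * L)
        hit = MotifHit(seq_id="r", start=start, end=start + 31 - 1, strand="+",
                        pattern="p", mismatches=0, matched="")
        distal, proximal = to_upstream_coords(hit, r)
        assert (distal, proximal) == (970, 940)

    def test_hit_outside_region_is_error(self):
        r = region("ACGTACGT")
        bad = MotifHit(seq_id="r", start=5, end=10, strand="+",
                        pattern="p", mismatches=0, matched="")
        with pytest.raises(ValueError, match="outside"):
            to_upstream_coords(bad, r)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(10, 5000), st.data())
    def test_bijection(self, L, data):
        start = data.draw(st.integers(1, L))
        end = data.draw(st.integers(start, L))
        r = region("A" * L)
        hit = MotifHit(seq_id="r", start=start, end=end, strand="+",
                        pattern="p", mismatches=0, matched="")
        span = to_upstream_coords(hit, r)
        assert span[0] >= span[1]
        assert from_upstream_coords(span, r) == (start, end)


IUPAC_CODES = "ACGTRYSWKMBDHVN"


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    st.text(alphabet="ACGTN", min_size=1, max_size=50),
    st.text(alphabet=IUPAC_CODES, min_size=1, max_size=8),
    st.integers(0, 2),
)
def test_scan_agrees_with_enumeration_oracle(seq, pattern, k):
    """Windowed minimal-Hamming scan equals brute-force concretization enumeration."""
    r = region(seq)
    pat = MotifPattern("p", pattern)
    if len(pattern) > len(seq):
        assert scan(r, pat, max_mismatches=k) == []
        return
    got = [(h.start, h.mismatches) for h in scan(r, pat, max_mismatches=k)]
    assert got == brute_force_scan(seq, pattern, k)
    near = [(h.start, h.mismatches) for h in find_near_misses(r, pat, k=max(k, 1))]
    assert near == [(s, d) for s, d in brute_force_scan(seq, pattern, max(k, 1)) if d >= 1]


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=6, max_size=50),
    st.text(alphabet=IUPAC_CODES, min_size=2, max_size=6),
)
def test_strand_symmetry(seq, pattern):
    """Scanning the reverse complement with the reverse-complemented pattern
    mirrors the coordinate set."""
    if len(pattern) > len(seq):
        return
    r = region(seq)
    rc = region(revcomp(seq))
    pat = MotifPattern("p", pattern)
    fwd = scan(r, pat, max_mismatches=1)
    mirrored = scan(rc, pat.reverse_complement(), max_mismatches=1)
    L = len(seq)
    expect = sorted((L - h.end + 1, L - h.start + 1, h.mismatches) for h in fwd)
    got = sorted((h.start, h.end, h.mismatches) for h in mirrored)
    assert got == expect


def test_reverse_strand_hits_in_forward_coordinates():
    # CACCTG is the reverse complement of CAGGTG
    r = region("TTCACCTGTT")
    hits = scan(r, EBOX_MYOD, strands="both")
    assert [(h.start, h.end, h.strand) for h in hits] == [(3, 8, "-")]


class TestCompareRegions:
    def test_cross_species_table(self, alcalica_region, niloticus_region):
        table, hits = compare_regions([alcalica_region, niloticus_region])
        table = table.set_index("species")
        assert table.loc["A. alcalica", "exact_pairs"] == 1
        assert table.loc["A. alcalica", "presumptive_pairs"] == 0
        assert table.loc["O. niloticus", "exact_pairs"] == 0
        assert table.loc["O. niloticus", "presumptive_pairs"] == 1
        assert set(hits) == {"A. alcalica", "O. niloticus"}

    def test_empty_pattern_list_gives_empty_table(self, alcalica_region):
        table, _ = compare_regions([alcalica_region], patterns=())
        assert table.empty

    def test_duplicated_region_gives_identical_rows(self, alcalica_region):
        dup = PromoterRegion(
            record=SeqRecord(id="copy", residues=alcalica_region.sequence, alphabet="dna"),
            species="copy",
        )
        table, _ = compare_regions([alcalica_region, dup])
        cols = [c for c in table.columns if c.startswith(("n_", "exact", "presumptive"))]
        assert table.iloc[0][cols].tolist() == table.iloc[1][cols].tolist()
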