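"""Consensus, known-site filtering, region annotation, and the merged table."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cellsafety.synthetic import write_vcf
from cellsafety.variants import (
    CallerCallSet,
    VariantKey,
    annotate_regions,
    filter_known_sites,
    intersect_callers,
    merge_cell_types,
    normalize_key,
    read_caller_vcf,
    read_known_sites,
    table_keys,
)


def _cs(name, keys, af=0.5, depth=40, vtype="SNV"):
    return CallerCallSet(name, vtype, {k: (af, depth) for k in keys})


def _keys(*positions):
    return [VariantKey("chr1", p, "A", "G") for p in positions]


class TestVariantKey:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            VariantKey("chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantKey("chr1", 5, "A", "A")
        with pytest.raises(ValueError):
            VariantKey("chr1", 5, "N", "G")

    def test_normalize_trims_shared_suffix_and_prefix(self):
        # padded InDel representations collapse to one parsimonious key
        assert normalize_key(VariantKey("chr1", 10, "ATG", "AG")) == \
            VariantKey("chr1", 10, "AT", "A")
        assert normalize_key(VariantKey("chr1", 10, "CAT", "CGT")) == \
            VariantKey("chr1", 11, "A", "G")

    def test_normalize_left_aligns_with_reference(self):
        #        0123456789
        ref = {"chr1": "GGAAAAATCC"}
        # deletion of one A in the homopolymer shifts to its leftmost placement
        shifted = normalize_key(VariantKey("chr1", 6, "AA", "A"), reference=ref)
        assert shifted == VariantKey("chr1", 2, "GA", "G")


class TestIntersectCallers:
    def test_full_overlap(self):
        v1, v2, v3 = _keys(1, 2, 3)
        out = intersect_callers([_cs("a", [v1, v2]), _cs("b", [v1, v3]), _cs("c", [v1, v2])])
        assert set(out) == {v1}

    def test_identity_and_disjoint(self):
        keys = _keys(1, 2, 3)
        same = [_cs(n, keys) for n in "abc"]
        assert set(intersect_callers(same)) == set(keys)
        disjoint = [_cs("a", _keys(1)), _cs("b", _keys(2)), _cs("c", _keys(3))]
        assert intersect_callers(disjoint) == {}

    def test_primary_caller_supplies_af(self):
        v = _keys(1)[0]
        out = intersect_callers([_cs("a", [v], af=0.4), _cs("b", [v], af=0.6)])
        assert out[v][0] == 0.4
        out = intersect_callers([_cs("a", [v], af=0.4), _cs("b", [v], af=0.6)],
                                primary_caller="b")
        assert out[v][0] == 0.6

    def test_mean_fallback_when_primary_lacks_key(self):
        v1, v2 = _keys(1, 2)
        out = intersect_callers([_cs("a", [v1], af=0.2), _cs("b", [v1, v2], af=0.4),
                                 _cs("c", [v2], af=0.6)], min_callers=2)
        assert out[v2][0] == pytest.approx(0.5)

    def test_rejects_mixed_types_and_bad_min(self):
        v = _keys(1)[0]
        indel = CallerCallSet("d", "InDel", {VariantKey("chr1", 5, "AT", "A"): (0.5, 40)})
        with pytest.raises(ValueError):
            intersect_callers([_cs("a", [v]), indel])
        with pytest.raises(ValueError):
            intersect_callers([_cs("a", [v])], min_callers=0)
        with pytest.raises(ValueError):
            intersect_callers([_cs("a", [v])], min_callers=2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.sets(st.integers(1, 20), max_size=10), min_size=1, max_size=4),
           st.data())
    def test_matches_brute_force_oracle(self, poss, data):
        callsets = [_cs(f"c{i}", _keys(*ps)) for i, ps in enumerate(poss)]
        mc = data.draw(st.integers(1, len(callsets)))
        out = set(intersect_callers(callsets, min_callers=mc))
        all_keys = set(itertools.chain.from_iterable(cs.calls for cs in callsets))
        oracle = {k for k in all_keys
                  if sum(k in cs.calls for cs in callsets) >= mc}
        assert out == oracle
        if mc == len(callsets):
            for cs in callsets:
                assert out <= set(cs.calls)


class TestFilterKnownSites:
    def test_set_difference(self):
        keys = _keys(1, 2, 3, 4, 5)
        consensus = {k: (0.5, 40) for k in keys}
        out = filter_known_sites(consensus, set(keys[:2]))
        assert set(out) == set(keys[2:])
        assert filter_known_sites(consensus, set()) == consensus
        assert filter_known_sites(consensus, set(keys)) == {}

    def test_idempotent_and_counts(self):
        keys = _keys(*range(1, 11))
        consensus = {k: (0.5, 40) for k in keys}
        known = set(_keys(2, 4, 99))
        once = filter_known_sites(consensus, known)
        assert filter_known_sites(once, known) == once
        assert len(once) == len(consensus) - len(set(consensus) & known)


class TestAnnotateRegions:
    FEATURES = [
        ("chr1", 100, 200, "exonic"),
        ("chr1", 100, 300, "promoter_enhancer"),
        ("chr1", 400, 500, "intronic"),
    ]

    def test_single_feature_and_default(self):
        inside_intron, nowhere = _keys(450, 9999)
        out = annotate_regions([inside_intron, nowhere], self.FEATURES)
        assert out[inside_intron] == "intronic"
        assert out[nowhere] == "intergenic"

    def test_precedence(self):
        v = _keys(150)[0]  # inside exon AND promoter intervals
        assert annotate_regions([v], self.FEATURES)[v] == "exonic"

    def test_rejects_malformed_interval(self):
        with pytest.raises(ValueError, match="chr1:500-400"):
            annotate_regions(_keys(1), [("chr1", 500, 400, "exonic")])


class TestMergeCellTypes:
    def test_union_with_af_zero_fill(self):
        v = _keys(10)[0]
        depth = {"fibro": {("chr1", 10): 33}}
        table = merge_cell_types({}, {v: (0.5, 40)}, {v: (0.5, 41)}, depth_lookup=depth)
        row = table.iloc[0]
        assert (row.af_fibro, row.af_ipsc, row.af_isc) == (0.0, 0.5, 0.5)
        assert row.depth_fibro == 33

    def test_identity_and_empty(self):
        v = _keys(10)[0]
        calls = {v: (0.5, 40)}
        table = merge_cell_types(calls, calls, calls)
        assert len(table) == 1
        assert list(table.iloc[0][["af_fibro", "af_ipsc", "af_isc"]]) == [0.5, 0.5, 0.5]
        assert len(merge_cell_types({}, {}, {})) == 0

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.integers(1, 30), max_size=10),
           st.sets(st.integers(1, 30), max_size=10),
           st.sets(st.integers(1, 30), max_size=10))
    def test_row_count_equals_key_union(self, a, b, c):
        sets = [{k: (0.5, 40) for k in _keys(*ps)} for ps in (a, b, c)]
        table = merge_cell_types(*sets)
        assert len(table) == len(a | b | c)
        assert set(table_keys(table)) == set().union(*map(set, sets))


class TestVcfRoundTrip:
    def test_written_vcf_reads_back_losslessly(self, tmp_path):
        calls = {VariantKey("chr1", p, "A", "G"): (round(0.1 * p, 6), 30 + p)
                 for p in range(1, 6)}
        path = str(tmp_path / "x.vcf")
        write_vcf(path, calls)
        back = read_caller_vcf(path, "w", "SNV")
        assert back.calls.keys() == calls.keys()
        for k in calls:
            assert back.calls[k][0] == pytest.approx(calls[k][0], abs=1e-6)
            assert back.calls[k][1] == calls[k][1]

    def test_known_sites_reader(self, tmp_path):
        calls = {VariantKey("chr1", 5, "A", "G"): (0.5, 40)}
        path = str(tmp_path / "known.vcf")
        write_vcf(path, calls)
        assert read_known_sites(path) == set(calls)
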