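"""Identical-mapping merge, score regeneration, and the filter cascade."""

from __future__ import annotations

import random

import numpy as np
import pysam
import pytest

from conftest import make_remapped_record, simple_header, write_sam
from pseudopipe.merge import (
    FilterDecision,
    FragmentMappingSet,
    MappingUnit,
    MergeError,
    ScoringScheme,
    collect_fragment_sets,
    encode_origin_flag,
    filter_pileup,
    filter_quality,
    filter_random,
    filter_unique,
    link_pairs,
    mappings_identical,
    merge_alignments,
    regenerate_score,
)

CHROMS = {"chr1": 100_000}


def _unit(header, name, pos, om=0, oc="50M", cigar=None, origin=1, end=0, paired=False):
    rec = make_remapped_record(header, name, "chr1", pos, cigar or oc, oc, om)
    return MappingUnit((rec,), origin, regenerate_score(oc, om), paired, end)


class TestOriginFlag:
    def test_two_founder_flags(self):
        assert encode_origin_flag([0], 2) == 0b01
        assert encode_origin_flag([1], 2) == 0b10
        assert encode_origin_flag([0, 1], 2) == 0b11

    def test_n_founder_bitset(self):
        assert encode_origin_flag([0, 2], 3) == 0b101

    def test_empty_or_out_of_range_rejected(self):
        with pytest.raises(MergeError):
            encode_origin_flag([], 2)
        with pytest.raises(MergeError):
            encode_origin_flag([2], 2)


class TestRegenerateScore:
    def test_perfect_end_to_end_match_scores_zero(self):
        assert regenerate_score("100M", 0) == 0

    def test_two_mismatches_default_penalty(self):
        assert regenerate_score("100M", 2) == -12

    def test_mismatches_and_one_gap(self):
        # om=3 minus 1 deleted base leaves 2 mismatches;
        # penalty 2*6 + (open 5 + extend 3*1) = 20
        assert regenerate_score("50M1D50M", 3) == -20

    def test_custom_scheme(self):
        scheme = ScoringScheme(mismatch_penalty=2, gap_open=10, gap_extend=1)
        assert regenerate_score("10M2I10M", 3, scheme) == -(2 * 1) - (10 + 2)

    def test_inconsistent_tags_rejected(self):
        with pytest.raises(MergeError):
            regenerate_score("10M5I10M", 2)


class TestMappingsIdentical:
    def test_reflexive(self):
        h = simple_header(CHROMS)
        u = _unit(h, "r", 500)
        assert mappings_identical(u, u)

    def test_same_position_cigar_end_score_identical(self):
        h = simple_header(CHROMS)
        assert mappings_identical(_unit(h, "r", 500, om=1), _unit(h, "r", 500, om=1))

    def test_different_score_not_identical(self):
        # a read straddling a founder SNP scores differently per pseudogenome
        h = simple_header(CHROMS)
        assert not mappings_identical(_unit(h, "r", 500, om=0), _unit(h, "r", 500, om=1))

    def test_different_position_not_identical(self):
        h = simple_header(CHROMS)
        assert not mappings_identical(_unit(h, "r", 500), _unit(h, "r", 501))


class TestLinkPairs:
    def _paired_unit(self, header, name, p1, p2, om=0):
        r1 = make_remapped_record(
            header, name, "chr1", p1, "50M", "50M", om, flag=0x1 | 0x2 | 0x40,
            next_ref=("chr1", p2),
        )
        r2 = make_remapped_record(
            header, name, "chr1", p2, "50M", "50M", 0, flag=0x1 | 0x2 | 0x80,
            next_ref=("chr1", p1),
        )
        score = regenerate_score("50M", om) + regenerate_score("50M", 0)
        return MappingUnit((r1, r2), 1, score, True, 0)

    def test_paired_unit_evicts_unpaired(self):
        h = simple_header(CHROMS)
        pu = self._paired_unit(h, "f", 100, 400)
        s1 = _unit(h, "f", 100, end=1)
        s2 = _unit(h, "f", 900, end=2)
        fset = FragmentMappingSet("f", [pu, s1, s2])
        out = link_pairs(fset)
        assert len(out) == 1
        assert out[0].units == [pu]

    def test_unpaired_ends_split_into_independent_sets(self):
        h = simple_header(CHROMS)
        fset = FragmentMappingSet(
            "f", [_unit(h, "f", 100, end=1), _unit(h, "f", 900, end=2), _unit(h, "f", 950, end=2)]
        )
        out = link_pairs(fset)
        assert [s.sub for s in out] == [1, 2]
        assert [len(s.units) for s in out] == [1, 2]

    def test_single_end_data_passes_through(self):
        h = simple_header(CHROMS)
        fset = FragmentMappingSet("f", [_unit(h, "f", 100), _unit(h, "f", 200)])
        assert link_pairs(fset) == [fset]


class TestFilters:
    def test_unique_decides_singleton(self):
        h = simple_header(CHROMS)
        fset = FragmentMappingSet("r1", [_unit(h, "r1", 100, origin=0b11)])
        dec = filter_unique(fset)
        assert isinstance(dec, FilterDecision)
        assert dec.label == "U"
        assert dec.unit.origin == 0b11

    def test_unique_passes_multiples_along(self):
        h = simple_header(CHROMS)
        fset = FragmentMappingSet("r4", [_unit(h, "r4", 100), _unit(h, "r4", 200, om=2)])
        assert filter_unique(fset) is fset

    def test_empty_set_is_an_error(self):
        with pytest.raises(MergeError):
            filter_unique(FragmentMappingSet("x", []))

    def test_quality_picks_unique_best_score(self):
        h = simple_header(CHROMS)
        best = _unit(h, "r4", 100, om=0)
        worse = _unit(h, "r4", 200, om=2, origin=2)
        dec = filter_quality(FragmentMappingSet("r4", [best, worse]))
        assert isinstance(dec, FilterDecision)
        assert dec.label == "Q"
        assert dec.unit is best

    def test_quality_passes_ties_and_drops_non_maximal(self):
        h = simple_header(CHROMS)
        a = _unit(h, "r5", 100, om=1)
        b = _unit(h, "r5", 200, om=1, origin=2)
        c = _unit(h, "r5", 300, om=3)
        out = filter_quality(FragmentMappingSet("r5", [a, b, c]))
        assert isinstance(out, FragmentMappingSet)
        assert out.units == [a, b]

    def test_two_way_tie_keeps_both(self):
        h = simple_header(CHROMS)
        a, b = _unit(h, "r", 100), _unit(h, "r", 200, origin=2)
        out = filter_quality(FragmentMappingSet("r", [a, b]))
        assert out.units == [a, b]

    def test_random_deterministic_under_seed(self):
        h = simple_header(CHROMS)
        fset = FragmentMappingSet("r5", [_unit(h, "r5", p, origin=o) for p, o in ((100, 1), (200, 2), (300, 3))])
        picks = {filter_random(fset, seed=17).unit.records[0].reference_start for _ in range(5)}
        assert len(picks) == 1
        assert filter_random(fset, seed=17).label == "R"

    def test_random_choice_depends_on_name_not_order(self):
        h = simple_header(CHROMS)
        units = [_unit(h, "rX", p, origin=o) for p, o in ((100, 1), (200, 2))]
        a = filter_random(FragmentMappingSet("rX", units), seed=3)
        b = filter_random(FragmentMappingSet("rX", list(reversed(units))), seed=3)
        assert a.unit.records[0].reference_start == b.unit.records[0].reference_start

    def test_random_empirically_uniform_over_two(self):
        h = simple_header(CHROMS)
        n = 4000
        hits = 0
        for i in range(n):
            name = f"frag{i:06d}"
            fset = FragmentMappingSet(
                name, [_unit(h, name, 100), _unit(h, name, 200, origin=2)]
            )
            if filter_random(fset, seed=11).unit.records[0].reference_start == 100:
                hits += 1
        sigma = (n * 0.25) ** 0.5
        assert abs(hits - n / 2) < 3 * sigma

    def test_pileup_prefers_deeper_span_and_ties_fall_through(self):
        h = simple_header(CHROMS)
        a = _unit(h, "p", 1000)
        b = _unit(h, "p", 5000, origin=2)
        cov = {"chr1": np.zeros(100_000, dtype=np.int32)}
        cov["chr1"][990:1100] = 40
        cov["chr1"][5000:5050] = 2
        dec = filter_pileup(FragmentMappingSet("p", [a, b]), cov)
        assert isinstance(dec, FilterDecision)
        assert dec.label == "P"
        assert dec.unit is a
        flat = {"chr1": np.ones(100_000, dtype=np.int32)}
        assert isinstance(filter_pileup(FragmentMappingSet("p", [a, b]), flat), FragmentMappingSet)
        zero = {"chr1": np.zeros(100_000, dtype=np.int32)}
        assert isinstance(filter_pileup(FragmentMappingSet("p", [a, b]), zero), FragmentMappingSet)


def _fig3_files(tmp_path):
    """Two single-end founder inputs reproducing the five worked mapping sets.

    read1: identical in both inputs (combined, flag 11) — Unique
    read2: only founder A — Unique;  read3: only founder B — Unique
    read4: both founders, founder A scores better — Quality picks A
    read5: 5a (A only), 5b (B only), 5c/5d identical in both — three equal
           scores — Random
    """
    h = simple_header(CHROMS)
    a = [
        make_remapped_record(h, "read1", "chr1", 1000, "50M", "50M", 0),
        make_remapped_record(h, "read2", "chr1", 2000, "50M", "50M", 1),
        make_remapped_record(h, "read4", "chr1", 4000, "50M", "50M", 0),
        make_remapped_record(h, "read5", "chr1", 5000, "50M", "50M", 1),
        make_remapped_record(h, "read5", "chr1", 5500, "50M", "50M", 1),
    ]
    b = [
        make_remapped_record(h, "read1", "chr1", 1000, "50M", "50M", 0),
        make_remapped_record(h, "read3", "chr1", 3000, "50M", "50M", 0),
        make_remapped_record(h, "read4", "chr1", 4000, "50M", "50M", 2),
        make_remapped_record(h, "read5", "chr1", 5250, "50M", "50M", 1),
        make_remapped_record(h, "read5", "chr1", 5500, "50M", "50M", 1),
    ]
    pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
    write_sam(pa, h, a)
    write_sam(pb, h, b)
    return str(pa), str(pb)


class TestCollectFragmentSets:
    def test_fig3_set_sizes_after_identical_merge(self, tmp_path):
        pa, pb = _fig3_files(tmp_path)
        with pysam.AlignmentFile(pa) as fa, pysam.AlignmentFile(pb) as fb:
            sets = {s.name: s for s in collect_fragment_sets([fa, fb], [pa, pb])}
        assert {n: len(s.units) for n, s in sets.items()} == {
            "read1": 1,
            "read2": 1,
            "read3": 1,
            "read4": 2,
            "read5": 3,
        }
        assert sets["read1"].units[0].origin == 0b11
        merged5 = [u for u in sets["read5"].units if u.origin == 0b11]
        assert len(merged5) == 1  # 5c and 5d combined
        assert merged5[0].records[0].reference_start == 5500

    def test_every_input_record_lands_in_exactly_one_set(self, tmp_path):
        rng = random.Random(123)
        h = simple_header(CHROMS)
        recs_a, recs_b = [], []
        n_records = 0
        for i in range(60):
            name = f"rf{i:04d}"
            for recs in (recs_a, recs_b):
                for _ in range(rng.randint(0, 2)):
                    recs.append(
                        make_remapped_record(
                            h, name, "chr1", rng.randint(0, 90_000), "30M", "30M", rng.randint(0, 2)
                        )
                    )
                    n_records += 1
        pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(pa, h, recs_a)
        write_sam(pb, h, recs_b)
        with pysam.AlignmentFile(str(pa)) as fa, pysam.AlignmentFile(str(pb)) as fb:
            sets = list(collect_fragment_sets([fa, fb], [str(pa), str(pb)]))
        names_with_records = {r.query_name for r in recs_a} | {r.query_name for r in recs_b}
        assert {s.name for s in sets} == names_with_records
        # units ≤ records (identical ones merge), and every unit's flag is sane
        assert sum(len(s.units) for s in sets) <= n_records
        assert all(0 < u.origin <= 0b11 for s in sets for u in s.units)

    def test_unsorted_input_detected(self, tmp_path):
        h = simple_header(CHROMS)
        recs = [
            make_remapped_record(h, "zz", "chr1", 100, "30M", "30M", 0),
            make_remapped_record(h, "aa", "chr1", 200, "30M", "30M", 0),
        ]
        p = tmp_path / "bad.sam"
        write_sam(p, h, recs)
        with pysam.AlignmentFile(str(p)) as f:
            with pytest.raises(MergeError, match="name-sorted"):
                list(collect_fragment_sets([f], [str(p)]))


class TestMergeAlignments:
    def test_fig3_full_cascade_labels(self, tmp_path):
        pa, pb = _fig3_files(tmp_path)
        out = tmp_path / "merged.sam"
        report = merge_alignments([pa, pb], str(out), seed=17)
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            recs = list(af)
        labels = {r.query_name: r.get_tag("ft") for r in recs}
        origins = {r.query_name: r.get_tag("po") for r in recs}
        assert labels == {"read1": "U", "read2": "U", "read3": "U", "read4": "Q", "read5": "R"}
        assert origins["read1"] == 0b11
        assert origins["read2"] == 0b01
        assert origins["read3"] == 0b10
        assert origins["read4"] == 0b01  # founder A's higher-scoring mapping
        assert int(report["fragments"].sum()) == 5
        assert abs(report["percent"].sum() - 100.0) < 1e-9

    def test_duplicate_inputs_all_unique_flag_both(self, tmp_path):
        h = simple_header(CHROMS)
        recs = [
            make_remapped_record(h, f"r{i:03d}", "chr1", 100 + 60 * i, "50M", "50M", 0)
            for i in range(10)
        ]
        pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(pa, h, recs)
        write_sam(pb, h, recs)
        out = tmp_path / "m.sam"
        merge_alignments([str(pa), str(pb)], str(out))
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            for rec in af:
                assert rec.get_tag("ft") == "U"
                assert rec.get_tag("po") == 0b11

    def test_fragment_conservation_on_random_inputs(self, tmp_path):
        rng = random.Random(77)
        h = simple_header(CHROMS)
        paths = []
        names = set()
        for k in range(3):
            recs = []
            for i in range(80):
                if rng.random() < 0.6:
                    name = f"x{i:04d}"
                    names.add(name)
                    recs.append(
                        make_remapped_record(
                            h, name, "chr1", rng.randint(0, 90_000), "30M", "30M", rng.randint(0, 1)
                        )
                    )
            p = tmp_path / f"in{k}.sam"
            write_sam(p, h, recs)
            paths.append(str(p))
        out = tmp_path / "m.sam"
        merge_alignments(paths, str(out), seed=5)
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            out_names = [r.query_name for r in af]
        assert set(out_names) == names  # every mapped fragment, exactly once
        assert len(out_names) == len(set(out_names))

    def test_input_order_swap_changes_nothing(self, tmp_path):
        pa, pb = _fig3_files(tmp_path)
        out1, out2 = tmp_path / "m1.sam", tmp_path / "m2.sam"
        merge_alignments([pa, pb], str(out1), seed=9)
        merge_alignments([pb, pa], str(out2), seed=9)

        def signature(path, flip):
            with pysam.AlignmentFile(path, check_sq=False) as af:
                out = {}
                for r in af:
                    po = r.get_tag("po")
                    if flip:  # founder bits swap with the file order
                        po = ((po & 1) << 1) | (po >> 1)
                    out[r.query_name] = (r.reference_start, r.cigarstring, po, r.get_tag("ft"))
                return out

        assert signature(str(out1), False) == signature(str(out2), True)

    def test_paired_preference_in_full_merge(self, tmp_path):
        h = simple_header(CHROMS)
        # founder A has a proper pair; founder B only a single-end mapping
        r1 = make_remapped_record(h, "fr", "chr1", 100, "50M", "50M", 0,
                                  flag=0x1 | 0x2 | 0x40, next_ref=("chr1", 400))
        r2 = make_remapped_record(h, "fr", "chr1", 400, "50M", "50M", 0,
                                  flag=0x1 | 0x2 | 0x80, next_ref=("chr1", 100))
        sb = make_remapped_record(h, "fr", "chr1", 100, "50M", "50M", 0, flag=0x1 | 0x40)
        pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(pa, h, [r1, r2])
        write_sam(pb, h, [sb])
        out = tmp_path / "m.sam"
        merge_alignments([str(pa), str(pb)], str(out))
        with pysam.AlignmentFile(str(out), check_sq=False) as af:
            recs = list(af)
        assert len(recs) == 2  # both mates of the paired unit, nothing else
        assert all(r.get_tag("po") == 0b01 for r in recs)
        assert all(r.get_tag("ft") == "U" for r in recs)

    def test_pileup_enabled_resolves_tie_and_disabled_matches_three_filter_run(self, tmp_path):
        h = simple_header(CHROMS)
        # supporting unique coverage near position 1000
        support = [
            make_remapped_record(h, f"s{i:03d}", "chr1", 980 + i, "50M", "50M", 0)
            for i in range(20)
        ]
        tie_a = make_remapped_record(h, "tie", "chr1", 1000, "50M", "50M", 0)
        tie_b = make_remapped_record(h, "tie", "chr1", 50_000, "50M", "50M", 0)
        pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(pa, h, sorted(support + [tie_a], key=lambda r: r.query_name))
        write_sam(pb, h, [tie_b])
        out_p = tmp_path / "mp.sam"
        merge_alignments([str(pa), str(pb)], str(out_p), seed=2, pileup=True)
        with pysam.AlignmentFile(str(out_p), check_sq=False) as af:
            tie = {r.query_name: r for r in af}["tie"]
        assert tie.get_tag("ft") == "P"
        assert tie.reference_start == 1000
        # without pileup the same input goes through Unique/Quality/Random only
        out_r = tmp_path / "mr.sam"
        merge_alignments([str(pa), str(pb)], str(out_r), seed=2, pileup=False)
        with pysam.AlignmentFile(str(out_r), check_sq=False) as af:
            labels = {r.get_tag("ft") for r in af}
        assert "P" not in labels


def test_inconsistent_read_lengths_for_one_end_rejected(tmp_path):
    h = simple_header(CHROMS)
    pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
    write_sam(pa, h, [make_remapped_record(h, "rr", "chr1", 100, "30M", "30M", 0)])
    write_sam(pb, h, [make_remapped_record(h, "rr", "chr1", 100, "40M", "40M", 0)])
    with pysam.AlignmentFile(str(pa)) as fa, pysam.AlignmentFile(str(pb)) as fb:
        with pytest.raises(MergeError, match="read lengths"):
            list(collect_fragment_sets([fa, fb], [str(pa), str(pb)]))
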