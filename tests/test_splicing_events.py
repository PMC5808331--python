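"""Event-table ingestion, significance filtering, intersections, lncRNA flags."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncfam.annotation_io import LocusCatalog, TranscriptRecord
from lncfam.splicing_events import (
    ComparisonResult,
    EventTableError,
    SpliceEventRecord,
    build_comparison,
    count_by_type,
    filter_significant,
    flag_lncrna_events,
    intersect_comparisons,
    read_events,
    write_events_rmats,
)

HEADER = "ID\tGeneID\tchr\tstrand\tPValue\tFDR\tIncLevel1\tIncLevel2\tIncLevelDifference\n"


def _table(tmp_path, name, rows):
    path = tmp_path / name
    path.write_text(HEADER + "".join(rows))
    return path


def _row(i, locus, p, fdr, diff="0.2"):
    return f'{i}\t"{locus}"\tChr1\t+\t{p}\t{fdr}\t0.5,0.6\t0.3,0.4\t{diff}\n'


def test_read_events_infers_type_and_parses_rows(tmp_path):
    path = _table(tmp_path, "x.SE.MATS.JC.txt", [
        _row(1, "LOC1", "0.001", "0.01"),
        _row(2, "LOC2", "0.5", "0.9"),
        _row(3, "LOC3", "NA", "0.9"),
    ])
    records = read_events([path])
    assert len(records) == 3
    assert all(r.event_type == "SE" for r in records)
    assert records[0].locus_id == "LOC1"  # quotes stripped
    assert math.isnan(records[2].p_value)
    assert records[0].inc_levels_1 == (0.5, 0.6)


def test_missing_required_column_is_named(tmp_path):
    path = tmp_path / "y.RI.MATS.JC.txt"
    path.write_text("ID\tGeneID\tPValue\tIncLevelDifference\n1\tL\t0.1\t0.2\n")
    with pytest.raises(EventTableError, match="FDR"):
        read_events([path])


def test_unknown_event_type_in_filename(tmp_path):
    path = tmp_path / "whatever.txt"
    path.write_text(HEADER)
    with pytest.raises(EventTableError):
        read_events([path])


def _rec(etype, locus, p, fdr):
    return SpliceEventRecord(
        event_id=f"{etype}:{locus}", event_type=etype, locus_id=locus,
        chrom="Chr1", strand="+", p_value=p, fdr=fdr, inclusion_difference=0.1,
    )


class TestSignificanceFilter:
    def test_strict_boundary_logic(self):
        records = [
            _rec("SE", "a", 0.004, 0.04),   # passes
            _rec("SE", "b", 0.004, 0.06),   # FDR too high
            _rec("SE", "c", 0.006, 0.01),   # p too high
            _rec("SE", "d", 0.005, 0.01),   # boundary p: strict < excludes
            _rec("SE", "e", 0.001, 0.05),   # boundary FDR: strict < excludes
            _rec("SE", "f", 0.00499, 0.0499),  # just inside both
            _rec("SE", "g", float("nan"), 0.01),  # missing fails everything
        ]
        kept = filter_significant(records)
        assert [r.locus_id for r in kept] == ["a", "f"]
        inclusive = filter_significant(records, strict=False)
        assert [r.locus_id for r in inclusive] == ["a", "d", "e", "f"]

    def test_idempotent(self):
        records = [_rec("SE", "a", 0.004, 0.04), _rec("RI", "b", 0.5, 0.5)]
        once = filter_significant(records)
        assert filter_significant(once) == once

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        stats=st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1, allow_nan=False),
                st.floats(min_value=0, max_value=1, allow_nan=False),
            ),
            max_size=40,
        ),
        thresholds=st.tuples(
            st.floats(min_value=0.001, max_value=1),
            st.floats(min_value=0.001, max_value=1),
        ),
    )
    def test_monotone_in_both_thresholds(self, stats, thresholds):
        records = [
            _rec("SE", f"l{i}", p, q) for i, (p, q) in enumerate(stats)
        ]
        p_max, fdr_max = thresholds
        n = len(filter_significant(records, p_max, fdr_max))
        assert len(filter_significant(records, p_max / 2, fdr_max)) <= n
        assert len(filter_significant(records, p_max, fdr_max / 2)) <= n

    def test_all_failing_table_gives_zero_counts(self):
        records = [_rec("SE", "a", 0.9, 0.9), _rec("RI", "b", 0.5, 0.5)]
        assert filter_significant(records) == []
        assert count_by_type(filter_significant(records)) == {
            "SE": 0, "RI": 0, "A5SS": 0, "A3SS": 0,
        }


def _cmp(label, loci):
    return ComparisonResult(
        label=label, per_type_counts=(("SE", len(loci)),),
        loci=frozenset(loci), lncrna_loci=frozenset(),
    )


class TestIntersections:
    def test_set_algebra(self):
        res = intersect_comparisons(
            [_cmp("c1", "ABC"), _cmp("c2", "BCD"), _cmp("c3", "CE")]
        )
        assert res.shared_all == {"C"}
        assert res.region((True, True, False)) == 1  # {B}
        assert res.region((True, False, False)) == 1  # {A}
        assert sum(n for _, n in res.region_counts) == 5  # union size

    def test_identical_sets_fill_only_the_full_intersection(self):
        res = intersect_comparisons([_cmp("c1", "ABC"), _cmp("c2", "ABC")])
        assert res.shared_all == {"A", "B", "C"}
        assert res.region_counts == (((True, True), 3),)

    def test_fewer_than_two_comparisons_rejected(self):
        with pytest.raises(ValueError):
            intersect_comparisons([_cmp("only", "A")])


def _lnc_catalog(loci):
    return LocusCatalog.from_records([
        TranscriptRecord(
            locus_id=l, transcript_id=f"{l}.t1", biotype="lncRNA", chrom=".",
            strand="+", exon_spans=((0, 8),), sequence="ACGTACGT",
        )
        for l in loci
    ])


class TestLncRNAFlagging:
    def test_counts_events_on_lncrna_loci(self):
        records = [
            _rec("SE", "L1", 0.001, 0.01),
            _rec("SE", "L2", 0.001, 0.01),
            _rec("RI", "L1", 0.001, 0.01),
            _rec("SE", "X1", 0.001, 0.01),
            _rec("A3SS", "X2", 0.001, 0.01),
        ]
        counts = flag_lncrna_events(records, _lnc_catalog(["L1", "L2"]))
        assert counts == {"SE": 2, "RI": 1, "A5SS": 0, "A3SS": 0}

    def test_empty_catalog_gives_all_zero(self):
        records = [_rec("SE", "L1", 0.001, 0.01)]
        counts = flag_lncrna_events(records, _lnc_catalog([]))
        assert set(counts.values()) == {0}


def test_round_trip_read_write_read_is_lossless(tmp_path):
    path = _table(tmp_path, "z.A5SS.MATS.JC.txt", [
        _row(1, "LOC1", "0.001", "0.01", diff="-0.35"),
        _row(2, "LOC2", "NA", "0.9"),
    ])
    records = read_events([path])
    out_paths = write_events_rmats(records, tmp_path / "out", label="z")
    back = read_events(out_paths)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.event_id, a.event_type, a.locus_id, a.chrom, a.strand) == \
            (b.event_id, b.event_type, b.locus_id, b.chrom, b.strand)
        for x, y in ((a.p_value, b.p_value), (a.fdr, b.fdr),
                     (a.inclusion_difference, b.inclusion_difference)):
            assert (math.isnan(x) and math.isnan(y)) or x == y
        assert a.inc_levels_1 == b.inc_levels_1
        assert a.inc_levels_2 == b.inc_levels_2


def test_build_comparison_deduplicates_loci():
    records = [
        _rec("SE", "L1", 0.001, 0.01),
        _rec("RI", "L1", 0.001, 0.01),
        _rec("SE", "L2", 0.001, 0.01),
    ]
    cmp_res = build_comparison("c", records, _lnc_catalog(["L2"]))
    assert cmp_res.loci == {"L1", "L2"}
    assert cmp_res.lncrna_loci == {"L2"}
    assert cmp_res.counts()["SE"] == 2  # per-event tally retained
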