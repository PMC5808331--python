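"""Local-alignment engine checked against an independent dynamic-programming
oracle (Bio.Align.PairwiseAligner), plus the tabular interchange format."""

import numpy as np
import pytest
from Bio import Align

from lncfam.annotation_io import TranscriptRecord, reverse_complement
from lncfam.homology_search import (
    AlignmentParams,
    ConfigurationError,
    TabularFormatError,
    align_all,
    export_blast_tabular,
    import_blast_tabular,
    smith_waterman,
)

from conftest import mutate, random_sequence


def _rec(tid, seq, locus=None):
    return TranscriptRecord(
        locus_id=locus or tid,
        transcript_id=tid,
        biotype="lncRNA",
        chrom=".",
        strand="+",
        exon_spans=((0, len(seq)),),
        sequence=seq,
    )


def _oracle():
    return Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-2.5, extend_gap_score=-2.5,
    )


def test_identical_sequences_align_end_to_end(rng):
    seq = random_sequence(rng, 200)
    matches = align_all([_rec("q", seq)], [_rec("s", seq)], AlignmentParams())
    best = max(matches, key=lambda m: m.score)
    assert best.aligned_length == 200
    assert best.percent_identity == 1.0
    assert best.q_span == (0, 200) and best.s_span == (0, 200)
    assert best.evalue < 1e-50


def test_conserved_block_with_three_percent_substitutions(rng):
    # a 605 nt block copied between two loci, 3% substitutions
    block = random_sequence(rng, 605)
    qa = random_sequence(rng, 150) + block + random_sequence(rng, 150)
    sb = random_sequence(rng, 90) + mutate(rng, block, 0.03) + random_sequence(rng, 200)
    matches = align_all([_rec("qa", qa)], [_rec("sb", sb)], AlignmentParams())
    best = max(matches, key=lambda m: m.score)
    assert best.aligned_length >= 0.95 * 605
    assert best.percent_identity > 0.95


def test_self_alignment_emitted_for_identical_ids(rng):
    seq = random_sequence(rng, 300)
    matches = align_all([_rec("x", seq)], [_rec("x", seq)], AlignmentParams())
    selfs = [m for m in matches if m.query_id == m.subject_id]
    assert selfs and selfs[0].aligned_length == 300


def test_seed_longer_than_shortest_sequence_is_a_config_error():
    with pytest.raises(ConfigurationError):
        align_all([_rec("q", "ACGTACGT")], [_rec("s", "ACGTACGT")],
                  AlignmentParams(seed_k=11))


def test_smith_waterman_matches_oracle_on_random_and_homologous_pairs(rng):
    """Best local score equals the independent DP oracle, pair by pair."""
    oracle = _oracle()
    seqs = [random_sequence(rng, int(rng.integers(100, 501))) for _ in range(14)]
    # add homologous pairs: shared blocks at 3% and 10% divergence, one revcomp
    block = random_sequence(rng, 250)
    seqs.append(random_sequence(rng, 60) + block + random_sequence(rng, 70))
    seqs.append(random_sequence(rng, 40) + mutate(rng, block, 0.03))
    seqs.append(mutate(rng, block, 0.10) + random_sequence(rng, 120))
    seqs.append(reverse_complement(block) + random_sequence(rng, 50))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            score, q_span, s_span, cols, ident, gaps = smith_waterman(
                seqs[i], seqs[j]
            )
            assert score == pytest.approx(oracle.score(seqs[i], seqs[j]), abs=1e-9)
            # internal consistency of the traceback bookkeeping
            recomputed = ident * 1.0 + (cols - ident - gaps) * -2.0 + gaps * -2.5
            assert score == pytest.approx(recomputed, abs=1e-9)
            assert q_span[1] - q_span[0] <= cols
            assert s_span[1] - s_span[0] <= cols


def test_align_all_reports_oracle_scores_both_strands(rng):
    """Exhaustive-parameter align_all == DP oracle on every pair and strand."""
    oracle = _oracle()
    records = [
        _rec(f"s{i}", random_sequence(rng, int(rng.integers(80, 400))))
        for i in range(10)
    ]
    block = random_sequence(rng, 180)
    records.append(_rec("h1", random_sequence(rng, 50) + block))
    records.append(_rec("h2", mutate(rng, block, 0.05) + random_sequence(rng, 60)))
    params = AlignmentParams(
        seed_k=4, evalue_max=None, min_score=0.5, max_alignments_per_pair=1
    )
    matches = align_all(records, records, params)
    best = {}
    for m in matches:
        key = (m.query_id, m.subject_id, m.subject_strand)
        best[key] = max(best.get(key, 0.0), m.score)
    for qr in records:
        for sr in records:
            fwd = oracle.score(qr.sequence, sr.sequence)
            rev = oracle.score(qr.sequence, reverse_complement(sr.sequence))
            if fwd >= 0.5:
                assert best[(qr.transcript_id, sr.transcript_id, "+")] == \
                    pytest.approx(fwd, abs=1e-9)
            if rev >= 0.5:
                assert best[(qr.transcript_id, sr.transcript_id, "-")] == \
                    pytest.approx(rev, abs=1e-9)


def test_strand_invariance(rng):
    block = random_sequence(rng, 300)
    q = _rec("q", random_sequence(rng, 50) + block + random_sequence(rng, 50))
    t_fwd = _rec("t", mutate(rng, block, 0.02))
    t_rev = _rec("t", reverse_complement(t_fwd.sequence))
    params = AlignmentParams()
    m_fwd = max(align_all([q], [t_fwd], params), key=lambda m: m.score)
    m_rev = max(align_all([q], [t_rev], params), key=lambda m: m.score)
    assert m_fwd.subject_strand == "+" and m_rev.subject_strand == "-"
    assert m_fwd.score == m_rev.score
    assert m_fwd.aligned_length == m_rev.aligned_length
    assert m_fwd.percent_identity == m_rev.percent_identity


def test_locus_level_symmetry(rng):
    block = random_sequence(rng, 200)
    a = _rec("ta", random_sequence(rng, 100) + block, locus="LA")
    b = _rec("tb", mutate(rng, block, 0.03) + random_sequence(rng, 80), locus="LB")
    matches = align_all([a, b], [a, b], AlignmentParams())
    pairs = {(m.query_locus, m.subject_locus) for m in matches}
    assert ("LA", "LB") in pairs and ("LB", "LA") in pairs
    ab = max(m.score for m in matches if (m.query_locus, m.subject_locus) == ("LA", "LB"))
    ba = max(m.score for m in matches if (m.query_locus, m.subject_locus) == ("LB", "LA"))
    assert ab == ba


def test_evalue_decreases_with_score():
    p = AlignmentParams()
    evalues = [p.evalue(s, 1000, 100000) for s in (30, 40, 50, 100)]
    assert all(a > b for a, b in zip(evalues, evalues[1:]))


class TestTabularInterchange:
    def test_field_mapping_and_minus_strand_coordinates(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "qA\tsB\t97.50\t400\t10\t0\t1\t400\t500\t101\t1e-100\t500\n"
        )
        (m,) = import_blast_tabular(path)
        assert m.aligned_length == 400
        assert m.percent_identity == pytest.approx(0.975)
        assert m.subject_strand == "-"
        assert m.s_span == (100, 500)
        assert m.q_span == (0, 400)
        assert m.evalue == 1e-100 and m.score == 500

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert import_blast_tabular(path) == []

    def test_wrong_column_count_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("qA\tsB\t97.50\t400\n")
        with pytest.raises(TabularFormatError, match=":1"):
            import_blast_tabular(path)

    def test_export_import_round_trip(self, rng, tmp_path):
        block = random_sequence(rng, 400)
        recs = [
            _rec("q1", random_sequence(rng, 100) + block),
            _rec("q2", mutate(rng, block, 0.04) + random_sequence(rng, 150)),
            _rec("q3", reverse_complement(block)[:350]),
        ]
        matches = align_all(recs, recs, AlignmentParams())
        path = tmp_path / "round.tsv"
        export_blast_tabular(matches, path)
        back = import_blast_tabular(path)
        assert len(back) == len(matches)
        for orig, twin in zip(matches, back):
            assert twin.query_id == orig.query_id
            assert twin.subject_id == orig.subject_id
            assert twin.q_span == orig.q_span
            assert twin.s_span == orig.s_span
            assert twin.subject_strand == orig.subject_strand
            assert twin.aligned_length == orig.aligned_length
            assert twin.n_identical == orig.n_identical
            assert twin.n_gaps == orig.n_gaps
            assert twin.score == pytest.approx(orig.score, rel=1e-4)
            assert twin.evalue == pytest.approx(orig.evalue, rel=1e-4)
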