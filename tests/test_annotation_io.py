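"""Annotation parsing, isoform selection and catalog round trips."""

import pytest

from lncfam.annotation_io import (
    AnnotationFormatError,
    LocusCatalog,
    TranscriptRecord,
    ValidationError,
    parse_annotation,
    parse_genbank,
    parse_gff3,
    read_catalog,
    reverse_complement,
    select_isoform,
    write_catalog_tsv,
    write_transcript_fasta,
)


def _write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n{seq}\n")


REF = (
    "ACGTACGTACGTACGTACGTCCGGAAGGTTCCAACCGGTTACGTACGTAC"
    "GTACGTACGTTTGGCCAATTGGCCAATTACGTACGTACGTACGTACGTAC"
)  # 100 nt


def _toy_gff3(tmp_path):
    """2 lncRNA loci (3 + 1 isoforms) and 1 mRNA locus on a 100 nt reference."""
    gff = tmp_path / "toy.gff3"
    fa = tmp_path / "toy.fa"
    _write_fasta(fa, {"chr1": REF})
    lines = [
        "##gff-version 3",
        "chr1\ttoy\tgene\t1\t50\t.\t+\t.\tID=LOCA;gene_biotype=lncRNA",
        "chr1\ttoy\tlnc_RNA\t1\t40\t.\t+\t.\tID=tA1;Parent=LOCA",
        "chr1\ttoy\texon\t1\t20\t.\t+\t.\tID=eA1a;Parent=tA1",
        "chr1\ttoy\texon\t31\t40\t.\t+\t.\tID=eA1b;Parent=tA1",
        "chr1\ttoy\tlnc_RNA\t1\t20\t.\t+\t.\tID=tA2;Parent=LOCA",
        "chr1\ttoy\texon\t1\t20\t.\t+\t.\tID=eA2;Parent=tA2",
        "chr1\ttoy\tlnc_RNA\t5\t40\t.\t+\t.\tID=tA3;Parent=LOCA",
        "chr1\ttoy\texon\t5\t40\t.\t+\t.\tID=eA3;Parent=tA3",
        "chr1\ttoy\tgene\t11\t40\t.\t-\t.\tID=LOCB;gene_biotype=lncRNA",
        "chr1\ttoy\tncRNA\t11\t40\t.\t-\t.\tID=tB1;Parent=LOCB;ncRNA_class=lncRNA",
        "chr1\ttoy\texon\t11\t20\t.\t-\t.\tID=eB1a;Parent=tB1",
        "chr1\ttoy\texon\t31\t40\t.\t-\t.\tID=eB1b;Parent=tB1",
        "chr1\ttoy\tgene\t51\t90\t.\t+\t.\tID=LOCC;gene_biotype=protein_coding",
        "chr1\ttoy\tmRNA\t51\t90\t.\t+\t.\tID=tC1;Parent=LOCC",
        "chr1\ttoy\texon\t51\t90\t.\t+\t.\tID=eC1;Parent=tC1",
    ]
    gff.write_text("\n".join(lines) + "\n")
    return gff, fa


def test_gff3_biotype_filter_counts(tmp_path):
    gff, fa = _toy_gff3(tmp_path)
    cat = parse_annotation(gff, biotype_filter="lncRNA", fasta=fa)
    assert cat.n_loci == 2
    assert cat.n_transcripts == 4
    full = parse_annotation(gff, fasta=fa)
    assert full.n_loci == 3
    assert full.n_transcripts == 5
    assert full.biotype_of_transcript("tC1") == "mRNA"


def test_minus_strand_transcript_is_reverse_complement_of_spliced(tmp_path):
    gff, fa = _toy_gff3(tmp_path)
    cat = parse_annotation(gff, fasta=fa)
    rec = cat.transcript("tB1")
    # exons (10,20) and (30,40), 0-based half-open, on the minus strand
    assert rec.exon_spans == ((10, 20), (30, 40))
    assert rec.length_nt == 20
    assert rec.sequence == reverse_complement(REF[10:20] + REF[30:40])


def test_gff3_requires_fasta_and_reports_bad_exons(tmp_path):
    gff, fa = _toy_gff3(tmp_path)
    with pytest.raises(AnnotationFormatError):
        parse_annotation(gff)
    bad = tmp_path / "bad.gff3"
    bad.write_text(
        "##gff-version 3\n"
        "chr1\ttoy\tgene\t1\t500\t.\t+\t.\tID=LOCX\n"
        "chr1\ttoy\tlnc_RNA\t1\t500\t.\t+\t.\tID=tX;Parent=LOCX\n"
        "chr1\ttoy\texon\t1\t500\t.\t+\t.\tID=eX;Parent=tX\n"
    )
    with pytest.raises(ValidationError, match="tX"):
        parse_gff3(bad, fa)


def test_genbank_transcript_records(tmp_path):
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    def rec(name, seq, feats):
        r = SeqRecord(Seq(seq), id=name, name=name, description="synthetic")
        r.annotations["molecule_type"] = "RNA"
        r.features = feats
        return r

    def feat(ftype, start, end, **quals):
        return SeqFeature(
            FeatureLocation(start, end), type=ftype,
            qualifiers={k: [v] for k, v in quals.items()},
        )

    records = [
        rec("XR_1.1", "ACGT" * 50, [
            feat("gene", 0, 200, db_xref="GeneID:111"),
            feat("ncRNA", 0, 200, ncRNA_class="lncRNA"),
            feat("exon", 0, 120), feat("exon", 120, 200),
        ]),
        rec("XM_2.1", "AACC" * 60, [
            feat("gene", 0, 240, db_xref="GeneID:222"),
            feat("CDS", 10, 230),
        ]),
        rec("NR_3.1", "GGTT" * 40, [
            feat("gene", 0, 160, db_xref="GeneID:333"),
            feat("rRNA", 0, 160),
        ]),
    ]
    path = tmp_path / "toy.gbff"
    SeqIO.write(records, str(path), "genbank")

    cat = parse_genbank(path)
    assert cat.n_loci == 3
    assert cat.transcript("XR_1.1").biotype == "lncRNA"
    assert cat.transcript("XR_1.1").locus_id == "LOC111"
    assert cat.transcript("XR_1.1").exon_count == 2
    assert cat.transcript("XM_2.1").biotype == "mRNA"
    assert cat.transcript("NR_3.1").biotype == "rRNA"
    lnc_only = parse_annotation(path, biotype_filter="lncRNA")
    assert lnc_only.n_loci == 1


def _catalog(lengths_by_locus):
    records = []
    for locus, lengths in lengths_by_locus.items():
        for i, length in enumerate(lengths):
            records.append(
                TranscriptRecord(
                    locus_id=locus,
                    transcript_id=f"{locus}.t{i + 1}",
                    biotype="lncRNA",
                    chrom="chr1",
                    strand="+",
                    exon_spans=((0, length),),
                    sequence="A" * length,
                )
            )
    return LocusCatalog.from_records(records)


class TestSelectIsoform:
    def test_longest_picks_the_1406_nt_variant(self):
        cat = _catalog({"LOCV": [1406, 1080, 1200]})
        picked = select_isoform(cat, "longest")
        assert picked.loci["LOCV"][0].length_nt == 1406
        assert select_isoform(cat, "shortest").loci["LOCV"][0].length_nt == 1080

    def test_single_isoform_any_mode(self):
        cat = _catalog({"LOCS": [321]})
        for mode in ("longest", "shortest"):
            assert select_isoform(cat, mode).loci["LOCS"][0].length_nt == 321

    def test_by_locus_list_is_set_intersection(self):
        cat = _catalog({f"L{i}": [100 + i] for i in range(10)})
        picked = select_isoform(
            cat, "by_locus_list", locus_ids={"L1", "L5", "L8", "L99"}
        )
        assert set(picked.loci) == {"L1", "L5", "L8"}

    def test_empty_locus_list_result_warns_not_raises(self):
        cat = _catalog({"LA": [100]})
        with pytest.warns(UserWarning):
            picked = select_isoform(cat, "by_locus_list", locus_ids={"NOPE"})
        assert picked.n_loci == 0

    def test_length_tie_broken_by_smallest_transcript_id(self):
        cat = _catalog({"LT": [500, 500]})
        assert (
            select_isoform(cat, "longest").loci["LT"][0].transcript_id == "LT.t1"
        )

    def test_longest_and_shortest_share_locus_set_and_order_lengths(self):
        cat = _catalog({"A": [10, 30, 20], "B": [5], "C": [7, 7]})
        lo = select_isoform(cat, "longest")
        sh = select_isoform(cat, "shortest")
        assert set(lo.loci) == set(sh.loci) == set(cat.loci)
        for locus in cat.loci:
            assert lo.loci[locus][0].length_nt >= sh.loci[locus][0].length_nt

    def test_selection_does_not_mutate_input(self):
        cat = _catalog({"A": [10, 30]})
        before = {k: v for k, v in cat.loci.items()}
        select_isoform(cat, "longest")
        assert cat.loci == before and cat.n_transcripts == 2


def test_catalog_round_trip_is_lossless(tmp_path, toy_genome):
    cat = parse_annotation(
        toy_genome.annotation_gff3, fasta=toy_genome.genome_fasta
    )
    tsv, fa = tmp_path / "cat.tsv", tmp_path / "cat.fa"
    write_catalog_tsv(cat, tsv)
    write_transcript_fasta(cat, fa)
    back = read_catalog(tsv, fa)
    assert back.n_loci == cat.n_loci
    assert back.n_transcripts == cat.n_transcripts
    for rec in cat.transcripts():
        twin = back.transcript(rec.transcript_id)
        assert twin.sequence == rec.sequence
        assert twin.exon_count == rec.exon_count
        assert twin.exon_spans == rec.exon_spans
        assert twin.biotype == rec.biotype


def test_transcript_record_validates_span_sum():
    with pytest.raises(ValidationError):
        TranscriptRecord(
            locus_id="L", transcript_id="t", biotype="lncRNA", chrom="c",
            strand="+", exon_spans=((0, 10),), sequence="ACGT",
        )
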