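"""Genome-annotation ingestion and lncRNA catalog construction.

Reads transcript models from a GenBank flat file or from GFF3 + genome
FASTA, builds a :class:`LocusCatalog` keyed by gene-level locus identifiers
(e.g. ``LOC9270896``), and selects one representative isoform per locus
(longest, shortest, or restricted to an externally supplied locus list).

Coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted at the parsing boundary. Exon spans are stored in
ascending genomic order; the spliced transcript sequence of a minus-strand
transcript is the reverse complement of the concatenated exon substrings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "AnnotationFormatError",
    "ValidationError",
    "TranscriptRecord",
    "LocusCatalog",
    "parse_annotation",
    "parse_gff3",
    "parse_genbank",
    "select_isoform",
    "write_catalog_tsv",
    "write_transcript_fasta",
    "read_catalog",
]

BIOTYPES = ("lncRNA", "mRNA", "rRNA", "other_ncRNA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file cannot be parsed; names the offending record."""


class ValidationError(ValueError):
    """Raised when a transcript model is internally inconsistent."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript (isoform) with its spliced sequence.

    ``exon_spans`` are 0-based half-open genomic intervals in ascending
    genomic order; for minus-strand transcripts the 5'-most exon is the
    last span. ``sequence`` is always the 5'->3' spliced transcript.
    """

    locus_id: str
    transcript_id: str
    biotype: str
    chrom: str
    strand: str
    exon_spans: tuple[tuple[int, int], ...]
    sequence: str

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exon_spans:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for start, end in self.exon_spans:
            if not (0 <= start < end):
                raise ValidationError(
                    f"{self.transcript_id}: bad exon span ({start}, {end})"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exon spans overlap or are unsorted"
                )
            prev_end = end
        span_total = sum(e - s for s, e in self.exon_spans)
        if span_total != len(self.sequence):
            raise ValidationError(
                f"{self.transcript_id}: exon spans total {span_total} nt but "
                f"sequence is {len(self.sequence)} nt"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exon_spans)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class LocusCatalog:
    """Mapping of locus_id -> isoforms, with provenance.

    Operations never mutate a catalog in place; they return new catalogs
    sharing the (immutable) transcript records.
    """

    loci: dict[str, tuple[TranscriptRecord, ...]]
    provenance: str = ""
    _by_transcript: dict[str, TranscriptRecord] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        by_tx: dict[str, TranscriptRecord] = {}
        for locus_id, isoforms in self.loci.items():
            if not isoforms:
                raise ValidationError(f"locus {locus_id} has no isoforms")
            for rec in isoforms:
                if rec.transcript_id in by_tx:
                    raise ValidationError(
                        f"duplicate transcript_id {rec.transcript_id}"
                    )
                by_tx[rec.transcript_id] = rec
        object.__setattr__(self, "_by_transcript", by_tx)

    @classmethod
    def from_records(
        cls, records: Iterable[TranscriptRecord], provenance: str = ""
    ) -> "LocusCatalog":
        loci: dict[str, list[TranscriptRecord]] = {}
        for rec in records:
            loci.setdefault(rec.locus_id, []).append(rec)
        return cls({k: tuple(v) for k, v in loci.items()}, provenance)

    # -- views ------------------------------------------------------------
    def transcripts(self) -> Iterator[TranscriptRecord]:
        for isoforms in self.loci.values():
            yield from isoforms

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_transcripts(self) -> int:
        return sum(len(v) for v in self.loci.values())

    def transcript(self, transcript_id: str) -> TranscriptRecord:
        return self._by_transcript[transcript_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def locus_of(self, transcript_id: str) -> str | None:
        rec = self._by_transcript.get(transcript_id)
        return rec.locus_id if rec is not None else None

    def biotype_of_transcript(self, transcript_id: str) -> str | None:
        rec = self._by_transcript.get(transcript_id)
        return rec.biotype if rec is not None else None

    def filter_biotype(self, biotype: str) -> "LocusCatalog":
        """New catalog keeping only transcripts of the given biotype."""
        return LocusCatalog.from_records(
            (r for r in self.transcripts() if r.biotype == biotype),
            provenance=f"{self.provenance} [biotype={biotype}]",
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

# GFF3 feature types treated as transcripts, and their biotype mapping.
_TRANSCRIPT_TYPES = {
    "mRNA": "mRNA",
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "rRNA": "rRNA",
    "ncRNA": None,  # resolved via ncRNA_class attribute
    "snoRNA": "other_ncRNA",
    "snRNA": "other_ncRNA",
    "tRNA": "other_ncRNA",
    "miRNA": "other_ncRNA",
    "antisense_RNA": "other_ncRNA",
    "transcript": "other_ncRNA",
}


def _gff3_biotype(featuretype: str, attributes: Mapping[str, Sequence[str]]) -> str:
    mapped = _TRANSCRIPT_TYPES[featuretype]
    if mapped is not None:
        return mapped
    classes = [c.lower() for c in attributes.get("ncRNA_class", [])]
    if any("lncrna" in c or "lnc_rna" in c for c in classes):
        return "lncRNA"
    return "other_ncRNA"


def _strip_prefix(identifier: str) -> str:
    for prefix in ("gene-", "gene:", "rna-", "rna:", "transcript:"):
        if identifier.startswith(prefix):
            return identifier[len(prefix):]
    return identifier


def parse_gff3(
    gff3_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    biotype_filter: str | None = None,
) -> LocusCatalog:
    """Parse a GFF3 annotation plus its genome FASTA into a catalog.

    Transcript features (mRNA, lnc_RNA, ncRNA, rRNA, ...) are attached to
    their parent gene; exon children define the spliced sequence, extracted
    from the FASTA and reverse-complemented for minus-strand transcripts.
    """
    import gffutils
    from pyfaidx import Fasta

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a zoo of error types
        raise AnnotationFormatError(f"cannot parse GFF3 {gff3_path}: {exc}") from exc

    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    records: list[TranscriptRecord] = []
    for featuretype, mapped in _TRANSCRIPT_TYPES.items():
        for tx in db.features_of_type(featuretype):
            biotype = _gff3_biotype(featuretype, tx.attributes)
            if biotype_filter is not None and biotype != biotype_filter:
                continue
            parents = list(db.parents(tx, featuretype="gene"))
            locus_id = _strip_prefix(parents[0].id) if parents else _strip_prefix(tx.id)
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
            )
            if not exons:
                exons = [(tx.start - 1, tx.end)]
            if tx.seqid not in fasta:
                raise ValidationError(
                    f"{tx.id}: chromosome {tx.seqid!r} absent from FASTA"
                )
            chrom_len = len(fasta[tx.seqid])
            if exons[-1][1] > chrom_len:
                raise ValidationError(
                    f"{tx.id}: exon end {exons[-1][1]} exceeds {tx.seqid} "
                    f"length {chrom_len}"
                )
            seq = "".join(fasta[tx.seqid][s:e] for s, e in exons)
            if tx.strand == "-":
                seq = reverse_complement(seq)
            records.append(
                TranscriptRecord(
                    locus_id=locus_id,
                    transcript_id=_strip_prefix(tx.id),
                    biotype=biotype,
                    chrom=tx.seqid,
                    strand=tx.strand if tx.strand in ("+", "-") else "+",
                    exon_spans=tuple(exons),
                    sequence=seq,
                )
            )
    return LocusCatalog.from_records(records, provenance=f"GFF3:{gff3_path}")


def parse_genbank(
    gbff_path: str | os.PathLike, biotype_filter: str | None = None
) -> LocusCatalog:
    """Parse a transcript-level GenBank flat file (one record per RNA).

    Locus identifiers come from ``GeneID`` db_xrefs (rendered ``LOC<id>``,
    the NCBI convention) with locus_tag/gene fallbacks. Exon spans are
    transcript-local in this format; genomic structure requires the
    GFF3 path.
    """
    from Bio import SeqIO

    records: list[TranscriptRecord] = []
    try:
        gb_iter = list(SeqIO.parse(str(gbff_path), "genbank"))
    except Exception as exc:
        raise AnnotationFormatError(f"cannot parse GenBank {gbff_path}: {exc}") from exc
    for rec in gb_iter:
        biotype = "other_ncRNA"
        locus_id = None
        chrom = "."
        exons: list[tuple[int, int]] = []
        has_cds = False
        for feat in rec.features:
            if feat.type == "source":
                chrom = feat.qualifiers.get("chromosome", ["."])[0]
            elif feat.type == "ncRNA":
                classes = [c.lower() for c in feat.qualifiers.get("ncRNA_class", [])]
                biotype = (
                    "lncRNA"
                    if any("lncrna" in c for c in classes)
                    else "other_ncRNA"
                )
            elif feat.type == "rRNA":
                biotype = "rRNA"
            elif feat.type == "CDS":
                has_cds = True
            elif feat.type == "exon":
                exons.append((int(feat.location.start), int(feat.location.end)))
            if locus_id is None:
                for xref in feat.qualifiers.get("db_xref", []):
                    if xref.startswith("GeneID:"):
                        locus_id = "LOC" + xref.split(":", 1)[1]
                if locus_id is None:
                    for key in ("locus_tag", "gene"):
                        if key in feat.qualifiers:
                            locus_id = feat.qualifiers[key][0]
                            break
        if has_cds and biotype == "other_ncRNA":
            biotype = "mRNA"
        if biotype_filter is not None and biotype != biotype_filter:
            continue
        seq = str(rec.seq).upper()
        if not seq:
            raise AnnotationFormatError(f"record {rec.id}: no sequence")
        if not exons:
            exons = [(0, len(seq))]
        records.append(
            TranscriptRecord(
                locus_id=locus_id or rec.id,
                transcript_id=rec.id,
                biotype=biotype,
                chrom=chrom,
                strand="+",
                exon_spans=tuple(sorted(exons)),
                sequence=seq,
            )
        )
    return LocusCatalog.from_records(records, provenance=f"GenBank:{gbff_path}")


def parse_annotation(
    source: str | os.PathLike,
    biotype_filter: str | None = None,
    fasta: str | os.PathLike | None = None,
) -> LocusCatalog:
    """Dispatch on file extension: .gb/.gbff -> GenBank, .gff/.gff3 -> GFF3+FASTA."""
    name = str(source).lower()
    if name.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        return parse_genbank(source, biotype_filter)
    if name.endswith((".gff", ".gff3")):
        if fasta is None:
            raise AnnotationFormatError(
                f"{source}: GFF3 input requires a genome FASTA for sequence extraction"
            )
        return parse_gff3(source, fasta, biotype_filter)
    raise AnnotationFormatError(f"unrecognised annotation format: {source}")


# ---------------------------------------------------------------------------
# Isoform selection
# ---------------------------------------------------------------------------

def select_isoform(
    catalog: LocusCatalog,
    mode: str = "longest",
    locus_ids: Iterable[str] | None = None,
) -> LocusCatalog:
    """Reduce a catalog to one representative isoform per locus.

    mode
        ``longest`` / ``shortest`` pick by spliced length (ties broken by
        lexicographically smallest transcript_id, for reproducibility);
        ``by_locus_list`` first drops loci absent from ``locus_ids`` and
        then keeps the longest isoform of each survivor.
    """
    if catalog.n_loci == 0:
        raise ValidationError("cannot select isoforms from an empty catalog")
    if mode == "by_locus_list":
        if locus_ids is None:
            raise ValidationError("by_locus_list requires a locus_ids set")
        wanted = set(locus_ids)
        loci = {k: v for k, v in catalog.loci.items() if k in wanted}
        if not loci:
            import warnings

            warnings.warn("by_locus_list retained no loci", stacklevel=2)
            return LocusCatalog({}, provenance=catalog.provenance)
        return select_isoform(
            LocusCatalog(loci, provenance=catalog.provenance), "longest"
        )
    if mode not in ("longest", "shortest"):
        raise ValidationError(f"unknown isoform-selection mode {mode!r}")
    sign = -1 if mode == "longest" else 1
    picked = {
        locus: (min(isoforms, key=lambda r: (sign * r.length_nt, r.transcript_id)),)
        for locus, isoforms in catalog.loci.items()
    }
    return LocusCatalog(picked, provenance=f"{catalog.provenance} [{mode}]")


# ---------------------------------------------------------------------------
# Writers / catalog round trip
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "locus_id",
    "transcript_id",
    "biotype",
    "exon_count",
    "length_nt",
    "chrom",
    "strand",
    "exon_spans",
)


def write_catalog_tsv(catalog: LocusCatalog, path: str | os.PathLike) -> None:
    """Catalog table: one row per isoform, exon spans serialised ``s-e;s-e``."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in catalog.transcripts():
            spans = ";".join(f"{s}-{e}" for s, e in rec.exon_spans)
            fh.write(
                f"{rec.locus_id}\t{rec.transcript_id}\t{rec.biotype}\t"
                f"{rec.exon_count}\t{rec.length_nt}\t{rec.chrom}\t{rec.strand}\t"
                f"{spans}\n"
            )


def write_transcript_fasta(catalog: LocusCatalog, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in catalog.transcripts():
            fh.write(f">{rec.transcript_id} locus={rec.locus_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_catalog(
    tsv_path: str | os.PathLike, fasta_path: str | os.PathLike
) -> LocusCatalog:
    """Inverse of write_catalog_tsv + write_transcript_fasta (lossless)."""
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    records = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLUMNS)] != list(_TSV_COLUMNS):
            raise AnnotationFormatError(f"{tsv_path}: unexpected catalog header")
        for line in fh:
            fields = dict(zip(_TSV_COLUMNS, line.rstrip("\n").split("\t")))
            spans = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in fields["exon_spans"].split(";")
            )
            records.append(
                TranscriptRecord(
                    locus_id=fields["locus_id"],
                    transcript_id=fields["transcript_id"],
                    biotype=fields["biotype"],
                    chrom=fields["chrom"],
                    strand=fields["strand"],
                    exon_spans=spans,  # type: ignore[arg-type]
                    sequence=seqs[fields["transcript_id"]],
                )
            )
    return LocusCatalog.from_records(records, provenance=f"catalog:{tsv_path}")
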