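"""End-to-end convenience driver: annotation files in, gene families out.

Chains the stages in the canonical order: parse annotation -> build the
lncRNA catalog and pick the longest isoform per locus -> all-vs-all
homology of lncRNA representatives against the full transcript set ->
filter cascade (rRNA, self-locus, >=100 bp) -> three-way classification ->
locus graph -> families (connected components, >=3 members) -> TE screen
-> size spectrum and degree tallies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx

from .annotation_io import (
    LocusCatalog,
    TranscriptRecord,
    parse_annotation,
    select_isoform,
)
from .family_graph import (
    FamilySpectrum,
    GeneFamily,
    build_family_graph,
    extract_families,
    family_spectrum,
    screen_te,
)
from .homology_search import AlignmentParams, HomologyMatch, align_all
from .match_filtering import (
    FilterConfig,
    MatchClassification,
    TaxonMap,
    classify_matches,
    filter_matches,
)

__all__ = ["FamilyDiscoveryResult", "discover_families"]


@dataclass
class FamilyDiscoveryResult:
    """Everything the discovery pipeline produced, stage by stage."""

    catalog: LocusCatalog  # full annotation
    lnc_representatives: LocusCatalog  # one longest isoform per lncRNA locus
    raw_matches: list[HomologyMatch]
    filtered_matches: list[HomologyMatch]
    classification: MatchClassification
    graph: nx.Graph
    families: list[GeneFamily]  # TE-screened, flagged retained
    spectrum: FamilySpectrum  # over unflagged families; tallies pre-screen

    @property
    def unflagged_families(self) -> list[GeneFamily]:
        return [f for f in self.families if not f.te_flagged]


def discover_families(
    annotation: str | os.PathLike,
    genome_fasta: str | os.PathLike | None = None,
    te_fasta: str | os.PathLike | None = None,
    external_fasta: str | os.PathLike | None = None,
    taxa: TaxonMap | None = None,
    align_params: AlignmentParams | None = None,
    filter_cfg: FilterConfig | None = None,
    min_family_size: int = 3,
) -> FamilyDiscoveryResult:
    """Run the full lncRNA gene-family discovery pipeline.

    Queries are the longest isoform of every lncRNA locus; targets are the
    longest isoform of every annotated locus (all biotypes, so rRNA and
    coding hits can be recognised) plus any external transcript FASTA
    (e.g. cross-species RNA).
    """
    params = align_params or AlignmentParams()
    cfg = filter_cfg or FilterConfig()

    catalog = parse_annotation(annotation, fasta=genome_fasta)
    lnc = select_isoform(catalog.filter_biotype("lncRNA"), "longest")
    targets_catalog = select_isoform(catalog, "longest")
    targets = list(targets_catalog.transcripts())
    if external_fasta is not None:
        targets.extend(_read_plain_fasta(external_fasta))

    raw = align_all(lnc, targets, params)
    filtered = filter_matches(raw, cfg, catalog)
    classification = classify_matches(filtered, catalog, taxa, cfg)
    graph = build_family_graph(classification.same_species_ncrna)
    families, _ = extract_families(graph, min_size=min_family_size)
    if te_fasta is not None:
        te_library = _read_plain_fasta(te_fasta)
        families = screen_te(
            families, graph, lnc, te_library, params,
            min_te_match_length=cfg.min_match_length,
        )
    spectrum = family_spectrum(families, graph)
    return FamilyDiscoveryResult(
        catalog=catalog,
        lnc_representatives=lnc,
        raw_matches=raw,
        filtered_matches=filtered,
        classification=classification,
        graph=graph,
        families=families,
        spectrum=spectrum,
    )


def _read_plain_fasta(path: str | os.PathLike) -> list[TranscriptRecord]:
    """FASTA -> single-exon transcript records (id doubles as locus)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(
            TranscriptRecord(
                locus_id=rec.id,
                transcript_id=rec.id,
                biotype="other_ncRNA",
                chrom=".",
                strand="+",
                exon_spans=((0, len(seq)),),
                sequence=seq,
            )
        )
    return records
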