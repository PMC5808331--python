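"""Filter cascade and classification for raw homology matches.

Mirrors the screening applied to BLASTN hits of lncRNA representatives:
alignments to ribosomal RNA are dropped, intra-locus (self and
isoform-isoform) hits are dropped, matches shorter than the significant
match length (default >=100 bp, boundary inclusive) are dropped, and the
survivors are split three ways: same-species ncRNA, same-species
protein-coding RNA, and matches to RNA of other species (annotated with
the species name from an accession->taxon table).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation_io import LocusCatalog
from .homology_search import HomologyMatch, write_matches_tsv

__all__ = [
    "FilterConfig",
    "TaxonMap",
    "MatchClassification",
    "filter_matches",
    "classify_matches",
    "write_classification",
]

logger = logging.getLogger(__name__)

_RRNA_KEYWORDS = ("ribosomal rna", "rrna")


@dataclass(frozen=True)
class FilterConfig:
    """Knobs of the match-filter cascade.

    min_match_length is inclusive: an alignment of exactly that many
    columns ("100 bp or more") is retained.
    """

    min_match_length: int = 100
    drop_rrna: bool = True
    drop_self_locus: bool = True
    taxon_of_interest: str = "Oryza sativa"

    def __post_init__(self) -> None:
        if self.min_match_length < 1:
            raise ValueError("min_match_length must be >= 1")


@dataclass
class TaxonMap:
    """Accession -> (taxid, species name) lookups.

    Built from the four-column accession2taxid dialect (accession,
    accession.version, taxid, gi) plus a taxid -> species-name table.
    Lookups fall back from versioned to unversioned accessions; a missing
    accession yields None and the caller decides the fallback.
    """

    accession_to_taxid: dict[str, int] = field(default_factory=dict)
    taxid_to_name: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_files(
        cls,
        accession2taxid_path: str | os.PathLike,
        names: Mapping[int, str] | str | os.PathLike,
    ) -> "TaxonMap":
        acc: dict[str, int] = {}
        with open(accession2taxid_path) as fh:
            header = fh.readline()
            if not header.lower().startswith("accession"):
                fh.seek(0)  # headerless variant
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                taxid = int(parts[2])
                acc[parts[0]] = taxid
                acc[parts[1]] = taxid
        if isinstance(names, (str, os.PathLike)):
            name_map: dict[int, str] = {}
            with open(names) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) >= 2 and parts[0].isdigit():
                        name_map[int(parts[0])] = parts[1]
        else:
            name_map = dict(names)
        return cls(acc, name_map)

    def lookup(self, accession: str) -> tuple[int, str] | None:
        taxid = self.accession_to_taxid.get(accession)
        if taxid is None and "." in accession:
            taxid = self.accession_to_taxid.get(accession.rsplit(".", 1)[0])
        if taxid is None:
            return None
        return taxid, self.taxid_to_name.get(taxid, "unknown")


def _subject_is_rrna(
    match: HomologyMatch,
    catalog: LocusCatalog,
    descriptions: Mapping[str, str] | None,
) -> bool:
    biotype = catalog.biotype_of_transcript(match.subject_id)
    if biotype is not None:
        return biotype == "rRNA"
    if descriptions:
        desc = descriptions.get(match.subject_id, "").lower()
        return any(k in desc for k in _RRNA_KEYWORDS)
    return False


def filter_matches(
    matches: Iterable[HomologyMatch],
    cfg: FilterConfig,
    catalog: LocusCatalog,
    subject_descriptions: Mapping[str, str] | None = None,
) -> list[HomologyMatch]:
    """Apply the rRNA / self-locus / match-length cascade, preserving order.

    The three filters are independent predicates, so their application
    order cannot change the result. Subjects absent from the catalog are
    judged for rRNA-ness by their description text, when provided.
    """
    out = []
    for m in matches:
        if cfg.drop_rrna and _subject_is_rrna(m, catalog, subject_descriptions):
            continue
        if cfg.drop_self_locus and m.query_locus == m.subject_locus:
            continue
        if m.aligned_length < cfg.min_match_length:
            continue
        out.append(m)
    return out


@dataclass
class MatchClassification:
    """The three-way split of filtered matches."""

    same_species_ncrna: list[HomologyMatch]
    same_species_coding: list[HomologyMatch]
    other_species: list[HomologyMatch]
    other_species_names: dict[str, str]  # subject_id -> species name

    @property
    def n_total(self) -> int:
        return (
            len(self.same_species_ncrna)
            + len(self.same_species_coding)
            + len(self.other_species)
        )


def classify_matches(
    matches: Iterable[HomologyMatch],
    catalog: LocusCatalog,
    taxa: TaxonMap | None,
    cfg: FilterConfig,
) -> MatchClassification:
    """Partition matches by subject category (exhaustive and disjoint).

    Subjects present in the catalog are same-species by construction:
    mRNA subjects go to the coding list, every non-coding biotype to the
    ncRNA list. Subjects known only by accession are resolved through the
    taxon map; accessions mapping to the taxon of interest are treated as
    same-species ncRNA unless flagged coding elsewhere, and unresolvable
    accessions fall into the other-species list as species "unknown".
    """
    ncrna: list[HomologyMatch] = []
    coding: list[HomologyMatch] = []
    other: list[HomologyMatch] = []
    species_of: dict[str, str] = {}
    for m in matches:
        biotype = catalog.biotype_of_transcript(m.subject_id)
        if biotype is not None:
            if biotype == "mRNA":
                coding.append(m.classified("self_coding"))
            elif biotype == "rRNA":
                ncrna.append(m.classified("self_rRNA"))
            else:
                ncrna.append(m.classified("self_ncRNA"))
            continue
        hit = taxa.lookup(m.subject_id) if taxa is not None else None
        if hit is None:
            logger.warning(
                "subject %s not in taxon map; classified other-species/unknown",
                m.subject_id,
            )
            species_of[m.subject_id] = "unknown"
            other.append(m.classified("cross_species"))
        else:
            _, species = hit
            if species == cfg.taxon_of_interest:
                ncrna.append(m.classified("self_ncRNA"))
            else:
                species_of[m.subject_id] = species
                other.append(m.classified("cross_species"))
    return MatchClassification(ncrna, coding, other, species_of)


def write_classification(
    cls: MatchClassification, out_dir: str | os.PathLike, prefix: str = "matches"
) -> dict[str, str]:
    """Emit the three splits as TSV files; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, subset in (
        ("same_species_ncrna", cls.same_species_ncrna),
        ("same_species_coding", cls.same_species_coding),
        ("other_species", cls.other_species),
    ):
        path = os.path.join(str(out_dir), f"{prefix}.{name}.tsv")
        write_matches_tsv(subset, path)
        paths[name] = path
    return paths
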