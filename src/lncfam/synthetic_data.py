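"""Synthetic toy genomes and splicing-event tables with known ground truth.

The generator plants every signal the discovery pipeline must handle:

* lncRNA gene families — groups of loci carrying independently mutated
  copies of a common ancestral block (default block lengths 605/382/208 nt;
  the substitution rate of 0.03 is the expected pairwise divergence between
  members, so within-family identity sits around 97%);
* locus pairs (exactly two loci sharing a block) that must stay below the
  three-member family threshold;
* TE decoy families whose shared block is a Type I transposon fragment
  drawn from the emitted TE library, so the TE screen can flag them;
* rRNA loci sharing an rRNA core, plus lncRNAs contaminated with an rRNA
  fragment, exercising the ribosomal filter;
* protein-coding genes embedding a region of a lncRNA (the
  lncRNA-matches-a-kinase situation), exercising the coding split;
* optional cross-species transcripts carrying lncRNA homology, listed in
  the accession2taxid table under a foreign taxon;
* rMATS-dialect event tables with planted significant rows (defaults echo
  the reported tallies: 217 SE / 247 RI / 85 A5SS / 131 A3SS significant
  events, of which 17/55/11/23 lie on lncRNA loci) and a configurable
  common locus core across comparisons (default 29).

Everything is a pure function of the integer seed (numpy Generator, no
hash- or locale-dependent iteration), so outputs are byte-identical
across runs and platforms.

Multi-exon genes are emitted with intronic structure, and a fraction of
lncRNA loci receive extra isoforms built by exon skipping or intron
retention, so isoform selection has real work to do.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation_io import reverse_complement
from .homology_search import ConfigurationError

__all__ = [
    "SynthesisConfig",
    "PlantedTruth",
    "SyntheticGenome",
    "EventTables",
    "generate_genome",
    "generate_event_tables",
    "generate_comparison_suite",
]

_BASES = np.array(list("ACGT"))

TAXON_OF_INTEREST = ("Oryza sativa", 4530)
_FOREIGN_TAXA = (("Zea mays", 4577), ("Sorghum bicolor", 4558))


@dataclass(frozen=True)
class SynthesisConfig:
    """Study conditions for the toy genome and event tables.

    Family sizes and block lengths default to the magnitudes the discovery
    stage must cope with (families of 3 up to 35 members; conserved blocks
    of 605, 382 and 208 nt). ``per_base_substitution_rate`` is the expected
    per-base divergence BETWEEN two family members: each member's copy of
    the ancestral block is mutated independently at half that rate.
    """

    seed: int = 1234
    n_background_lnc: int = 20
    family_sizes: tuple[int, ...] = (3, 3, 4, 5, 7, 35)
    shared_block_lengths: tuple[int, ...] = (605, 382, 208)
    per_base_substitution_rate: float = 0.03
    indel_rate: float = 0.0
    n_lnc_pairs: int = 2
    pair_block_length: int = 150
    n_te_decoy_families: int = 2
    te_decoy_family_size: int = 3
    te_fragment_length: int = 300
    n_te_sequences: int = 4
    n_rrna_loci: int = 3
    n_rrna_contaminated_lnc: int = 1
    n_coding_genes_with_shared_region: int = 3
    n_coding_background: int = 2
    n_cross_species_homologs: int = 2
    multi_isoform_fraction: float = 0.3
    gc_content: float = 0.5
    n_chromosomes: int = 3
    max_locus_length: int = 4000
    # event tables
    event_rows_per_type: int = 400
    planted_significant: tuple[tuple[str, int], ...] = (
        ("SE", 217), ("RI", 247), ("A5SS", 85), ("A3SS", 131)
    )
    lncrna_significant: tuple[tuple[str, int], ...] = (
        ("SE", 17), ("RI", 55), ("A5SS", 11), ("A3SS", 23)
    )
    comparison_labels: tuple[str, ...] = (
        "milkseed_vs_mature", "gametes", "methylase_mutant"
    )
    shared_core_size: int = 29

    def __post_init__(self) -> None:
        if any(s < 3 for s in self.family_sizes):
            raise ConfigurationError("family sizes must be >= 3")
        if any(b < 1 for b in self.shared_block_lengths):
            raise ConfigurationError("block lengths must be >= 1")
        if not 0 <= self.per_base_substitution_rate <= 0.5:
            raise ConfigurationError("substitution rate must be in [0, 0.5]")
        if max(self.shared_block_lengths, default=0) + 100 > self.max_locus_length:
            raise ConfigurationError(
                "shared block does not fit inside max_locus_length"
            )
        planted = dict(self.planted_significant)
        for etype, n_lnc in self.lncrna_significant:
            if n_lnc > planted.get(etype, 0):
                raise ConfigurationError(
                    f"{etype}: lncRNA significant count exceeds planted count"
                )
        if any(n > self.event_rows_per_type for _, n in self.planted_significant):
            raise ConfigurationError("planted count exceeds rows per table")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels for everything the generator planted."""

    family_of: tuple[tuple[str, str], ...]  # locus -> true family label
    te_decoy_family_of: tuple[tuple[str, str], ...]
    pair_of: tuple[tuple[str, str], ...]  # locus -> pair label
    rrna_loci: frozenset[str]
    rrna_contaminated: frozenset[str]
    coding_links: tuple[tuple[str, str], ...]  # (lnc locus, coding locus)
    cross_links: tuple[tuple[str, str], ...]  # (lnc locus, foreign accession)
    background_lnc: frozenset[str]
    coding_loci: frozenset[str]

    def true_family_partition(self) -> dict[str, set[str]]:
        part: dict[str, set[str]] = {}
        for locus, fam in self.family_of:
            part.setdefault(fam, set()).add(locus)
        return part

    def decoy_partition(self) -> dict[str, set[str]]:
        part: dict[str, set[str]] = {}
        for locus, fam in self.te_decoy_family_of:
            part.setdefault(fam, set()).add(locus)
        return part

    def all_lnc_loci(self) -> set[str]:
        out = {l for l, _ in self.family_of}
        out |= {l for l, _ in self.te_decoy_family_of}
        out |= {l for l, _ in self.pair_of}
        out |= set(self.background_lnc)
        out |= set(self.rrna_contaminated)
        return out


@dataclass(frozen=True)
class SyntheticGenome:
    """Paths of everything generate_genome wrote, plus the truth manifest."""

    genome_fasta: str
    annotation_gff3: str
    te_fasta: str
    accession2taxid: str
    taxon_names: str
    external_fasta: str | None
    manifest: str
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float = 0.0) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < sub_rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    seq = "".join(arr)
    if indel_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r > 1 - indel_rate / 2:
                out.append(str(_BASES[rng.integers(4)]))  # insertion
        seq = "".join(out)
    return seq


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    locus_id: str
    biotype: str  # lncRNA / mRNA / rRNA
    pre_mrna: str  # gene-level genomic sequence, transcript orientation
    isoforms: list[tuple[str, list[tuple[int, int]]]]  # (accession, gene-local spans)
    strand: str = "+"


def _make_gene(
    rng: np.random.Generator,
    locus_id: str,
    accession_prefix: str,
    acc_counter: list[int],
    transcript_seq: str,
    biotype: str,
    multi_isoform: bool,
    gc: float,
    protect: tuple[int, int] | None = None,
) -> _Gene:
    """Split a designed transcript into exons, add introns and isoforms.

    ``protect`` is a transcript span no intron may interrupt — planted
    conserved blocks stay within one exon, so a retained-intron isoform
    (which can become the longest, hence the representative) cannot split
    the block's homology signal.
    """
    length = len(transcript_seq)
    if length < 150:
        n_exons = 1
    else:
        n_exons = int(rng.integers(1, 5))
    # cut points leaving every exon >= 40 nt and avoiding the protected span
    while n_exons > 1 and length // n_exons < 40:
        n_exons -= 1
    allowed = np.arange(40, length - 39)
    if protect is not None:
        allowed = allowed[(allowed <= protect[0]) | (allowed >= protect[1])]
    n_exons = min(n_exons, len(allowed) + 1)
    cuts = sorted(rng.choice(allowed, size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    bounds = [0, *map(int, cuts), length]
    exon_seqs = [transcript_seq[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
    introns = [_rand_seq(rng, int(rng.integers(80, 251)), gc)
               for _ in range(n_exons - 1)]
    pre = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for i, ex in enumerate(exon_seqs):
        pre.append(ex)
        spans.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < n_exons - 1:
            pre.append(introns[i])
            pos += len(introns[i])

    def next_acc() -> str:
        acc_counter[0] += 1
        return f"{accession_prefix}{acc_counter[0]:07d}.1"

    isoforms = [(next_acc(), list(spans))]
    if multi_isoform and n_exons >= 2:
        if n_exons >= 3:  # skipped internal exon
            skip = int(rng.integers(1, n_exons - 1))
            isoforms.append(
                (next_acc(), [s for i, s in enumerate(spans) if i != skip])
            )
        else:  # retained intron: one exon spanning both exons and the intron
            isoforms.append((next_acc(), [(spans[0][0], spans[1][1])]))
    strand = "+" if rng.random() < 0.5 else "-"
    return _Gene(locus_id, biotype, "".join(pre), isoforms, strand)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(cfg: SynthesisConfig, out_dir: str | os.PathLike) -> SyntheticGenome:
    """Emit genome FASTA, GFF3, TE library, taxon tables and truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    gc = cfg.gc_content
    sub = cfg.per_base_substitution_rate

    te_seqs = {
        f"TE{i + 1:06d}": _rand_seq(rng, int(rng.integers(1200, 2201)), gc)
        for i in range(cfg.n_te_sequences)
    }

    locus_counter = [0]

    def next_locus() -> str:
        locus_counter[0] += 1
        return f"LOC9{locus_counter[0]:06d}"

    acc_counters = {"XR_": [0], "XM_": [0], "NR_": [0]}
    genes: list[_Gene] = []
    family_of: list[tuple[str, str]] = []
    te_decoy_of: list[tuple[str, str]] = []
    pair_of: list[tuple[str, str]] = []
    rrna_loci: set[str] = set()
    rrna_contaminated: set[str] = set()
    coding_links: list[tuple[str, str]] = []
    cross_links: list[tuple[str, str]] = []
    background: set[str] = set()
    coding_loci: set[str] = set()

    def add_lnc(
        transcript_seq: str,
        multi: bool | None = None,
        protect: tuple[int, int] | None = None,
    ) -> str:
        locus = next_locus()
        multi = (rng.random() < cfg.multi_isoform_fraction) if multi is None else multi
        genes.append(
            _make_gene(rng, locus, "XR_", acc_counters["XR_"], transcript_seq,
                       "lncRNA", multi, gc, protect=protect)
        )
        return locus

    def flanked(block: str) -> tuple[str, tuple[int, int]]:
        # half the configured rate per copy => pairwise divergence ~= sub
        f5 = _rand_seq(rng, int(rng.integers(50, 301)), gc)
        f3 = _rand_seq(rng, int(rng.integers(50, 301)), gc)
        copy = _mutate(rng, block, sub / 2, cfg.indel_rate)
        return f5 + copy + f3, (len(f5), len(f5) + len(copy))

    # -- true families ---------------------------------------------------
    for fi, size in enumerate(cfg.family_sizes):
        block_len = cfg.shared_block_lengths[fi % len(cfg.shared_block_lengths)]
        ancestral = _rand_seq(rng, block_len, gc)
        label = f"TRUEFAM{fi + 1}"
        for _ in range(size):
            seq, span = flanked(ancestral)
            family_of.append((add_lnc(seq, protect=span), label))

    # -- pairs (below the family threshold) ------------------------------
    for pi in range(cfg.n_lnc_pairs):
        block = _rand_seq(rng, cfg.pair_block_length, gc)
        label = f"PAIR{pi + 1}"
        for _ in range(2):
            seq, span = flanked(block)
            pair_of.append((add_lnc(seq, protect=span), label))

    # -- TE decoy families ------------------------------------------------
    te_ids = list(te_seqs)
    for di in range(cfg.n_te_decoy_families):
        te_id = te_ids[di % len(te_ids)]
        te_seq = te_seqs[te_id]
        start = int(rng.integers(0, len(te_seq) - cfg.te_fragment_length + 1))
        frag = te_seq[start:start + cfg.te_fragment_length]
        label = f"TEDECOY{di + 1}"
        for _ in range(cfg.te_decoy_family_size):
            seq, span = flanked(frag)
            te_decoy_of.append((add_lnc(seq, protect=span), label))

    # -- rRNA loci and rRNA-contaminated lncRNAs --------------------------
    rrna_core = _rand_seq(rng, 1500, gc) if cfg.n_rrna_loci else ""
    for _ in range(cfg.n_rrna_loci):
        locus = next_locus()
        seq = _mutate(rng, rrna_core, 0.02)
        genes.append(
            _make_gene(rng, locus, "NR_", acc_counters["NR_"], seq, "rRNA",
                       False, gc)
        )
        rrna_loci.add(locus)
    for _ in range(cfg.n_rrna_contaminated_lnc if cfg.n_rrna_loci else 0):
        start = int(rng.integers(0, len(rrna_core) - 200 + 1))
        frag = rrna_core[start:start + 200]
        seq, span = flanked(frag)
        locus = add_lnc(seq, protect=span)
        rrna_contaminated.add(locus)

    # -- background lncRNAs ----------------------------------------------
    for _ in range(cfg.n_background_lnc):
        locus = add_lnc(_rand_seq(rng, int(rng.integers(400, 1201)), gc))
        background.add(locus)

    background_list = sorted(background)

    # -- coding genes, some sharing a region with a lncRNA ----------------
    lnc_gene_by_locus = {g.locus_id: g for g in genes if g.biotype == "lncRNA"}
    for ci in range(cfg.n_coding_genes_with_shared_region):
        donor_locus = background_list[ci % len(background_list)] if background_list \
            else family_of[ci % len(family_of)][0]
        donor = lnc_gene_by_locus[donor_locus]
        donor_tx = "".join(
            donor.pre_mrna[s:e] for s, e in donor.isoforms[0][1]
        )
        win = min(180, len(donor_tx) - 1)
        start = int(rng.integers(0, len(donor_tx) - win + 1))
        shared = _mutate(rng, donor_tx[start:start + win], sub)
        body5 = _rand_seq(rng, int(rng.integers(300, 701)), gc)
        body3 = _rand_seq(rng, int(rng.integers(300, 701)), gc)
        locus = next_locus()
        genes.append(
            _make_gene(rng, locus, "XM_", acc_counters["XM_"],
                       body5 + shared + body3, "mRNA", False, gc,
                       protect=(len(body5), len(body5) + len(shared)))
        )
        coding_loci.add(locus)
        coding_links.append((donor_locus, locus))
    for _ in range(cfg.n_coding_background):
        locus = next_locus()
        genes.append(
            _make_gene(rng, locus, "XM_", acc_counters["XM_"],
                       _rand_seq(rng, int(rng.integers(800, 1601)), gc),
                       "mRNA", False, gc)
        )
        coding_loci.add(locus)

    # -- cross-species homolog transcripts (not part of the genome) -------
    external: list[tuple[str, str]] = []  # (accession, sequence)
    foreign_acc_taxid: list[tuple[str, int]] = []
    for xi in range(cfg.n_cross_species_homologs):
        donor_locus = background_list[(xi + 1) % len(background_list)] if \
            background_list else family_of[xi % len(family_of)][0]
        donor = lnc_gene_by_locus[donor_locus]
        donor_tx = "".join(donor.pre_mrna[s:e] for s, e in donor.isoforms[0][1])
        win = min(150, len(donor_tx) - 1)
        start = int(rng.integers(0, len(donor_tx) - win + 1))
        shared = _mutate(rng, donor_tx[start:start + win], sub)
        accession = f"XR_88{xi + 1:05d}.1"
        seq = (_rand_seq(rng, 300, gc) + shared + _rand_seq(rng, 300, gc))
        external.append((accession, seq))
        _, taxid = _FOREIGN_TAXA[xi % len(_FOREIGN_TAXA)]
        foreign_acc_taxid.append((accession, taxid))
        cross_links.append((donor_locus, accession))

    # -- assemble chromosomes ---------------------------------------------
    chrom_parts: list[list[str]] = [[] for _ in range(cfg.n_chromosomes)]
    chrom_pos = [0] * cfg.n_chromosomes
    gff_lines: list[str] = ["##gff-version 3"]
    for gi, gene in enumerate(genes):
        ci = gi % cfg.n_chromosomes
        gap = int(rng.integers(150, 401))
        chrom_parts[ci].append(_rand_seq(rng, gap, gc))
        chrom_pos[ci] += gap
        g0 = chrom_pos[ci]
        glen = len(gene.pre_mrna)
        genomic = gene.pre_mrna if gene.strand == "+" else \
            reverse_complement(gene.pre_mrna)
        chrom_parts[ci].append(genomic)
        chrom_pos[ci] += glen
        chrom = f"Chr{ci + 1}"

        def abs_span(span: tuple[int, int]) -> tuple[int, int]:
            s, e = span
            if gene.strand == "-":
                s, e = glen - e, glen - s
            return g0 + s, g0 + e

        feature_type = {"lncRNA": "lnc_RNA", "mRNA": "mRNA", "rRNA": "rRNA"}[
            gene.biotype
        ]
        gff_lines.append(
            f"{chrom}\tlncfam_sim\tgene\t{g0 + 1}\t{g0 + glen}\t.\t{gene.strand}"
            f"\t.\tID={gene.locus_id};gene_biotype="
            + ("lncRNA" if gene.biotype == "lncRNA" else gene.biotype)
        )
        for acc, spans in gene.isoforms:
            abs_spans = sorted(abs_span(s) for s in spans)
            t_start, t_end = abs_spans[0][0], abs_spans[-1][1]
            attrs = f"ID={acc};Parent={gene.locus_id}"
            if feature_type == "lnc_RNA":
                attrs += ";ncRNA_class=lncRNA"
            gff_lines.append(
                f"{chrom}\tlncfam_sim\t{feature_type}\t{t_start + 1}\t{t_end}"
                f"\t.\t{gene.strand}\t.\t{attrs}"
            )
            for ei, (s, e) in enumerate(abs_spans, start=1):
                gff_lines.append(
                    f"{chrom}\tlncfam_sim\texon\t{s + 1}\t{e}\t.\t{gene.strand}"
                    f"\t.\tID=exon-{acc}-{ei};Parent={acc}"
                )

    # trailing tail so no exon abuts the chromosome end
    for ci in range(cfg.n_chromosomes):
        chrom_parts[ci].append(_rand_seq(rng, 200, gc))

    # -- write outputs -----------------------------------------------------
    genome_fasta = os.path.join(out_dir, "genome.fa")
    with open(genome_fasta, "w") as fh:
        for ci in range(cfg.n_chromosomes):
            fh.write(f">Chr{ci + 1}\n")
            seq = "".join(chrom_parts[ci])
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    gff_path = os.path.join(out_dir, "annotation.gff3")
    with open(gff_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")

    te_path = os.path.join(out_dir, "te_library.fa")
    with open(te_path, "w") as fh:
        for te_id, seq in te_seqs.items():
            fh.write(f">{te_id} TypeI_transposon\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    external_path = None
    if external:
        external_path = os.path.join(out_dir, "external_rna.fa")
        with open(external_path, "w") as fh:
            for acc, seq in external:
                fh.write(f">{acc} foreign lncRNA homolog\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    taxid_interest = TAXON_OF_INTEREST[1]
    acc2taxid_path = os.path.join(out_dir, "accession2taxid.tsv")
    with open(acc2taxid_path, "w") as fh:
        fh.write("accession\taccession.version\ttaxid\tgi\n")
        gi = 1000
        for gene in genes:
            for acc, _ in gene.isoforms:
                bare = acc.rsplit(".", 1)[0]
                fh.write(f"{bare}\t{acc}\t{taxid_interest}\t{gi}\n")
                gi += 1
        for acc, taxid in foreign_acc_taxid:
            bare = acc.rsplit(".", 1)[0]
            fh.write(f"{bare}\t{acc}\t{taxid}\t{gi}\n")
            gi += 1

    names_path = os.path.join(out_dir, "taxid_names.tsv")
    with open(names_path, "w") as fh:
        fh.write(f"{TAXON_OF_INTEREST[1]}\t{TAXON_OF_INTEREST[0]}\n")
        for name, taxid in _FOREIGN_TAXA:
            fh.write(f"{taxid}\t{name}\n")

    truth = PlantedTruth(
        family_of=tuple(family_of),
        te_decoy_family_of=tuple(te_decoy_of),
        pair_of=tuple(pair_of),
        rrna_loci=frozenset(rrna_loci),
        rrna_contaminated=frozenset(rrna_contaminated),
        coding_links=tuple(coding_links),
        cross_links=tuple(cross_links),
        background_lnc=frozenset(background),
        coding_loci=frozenset(coding_loci),
    )

    manifest_path = os.path.join(out_dir, "truth_manifest.tsv")
    _write_manifest(truth, manifest_path)

    return SyntheticGenome(
        genome_fasta=genome_fasta,
        annotation_gff3=gff_path,
        te_fasta=te_path,
        accession2taxid=acc2taxid_path,
        taxon_names=names_path,
        external_fasta=external_path,
        manifest=manifest_path,
        truth=truth,
    )


def _write_manifest(truth: PlantedTruth, path: str) -> None:
    rows: list[tuple[str, str, str]] = []
    for locus, fam in truth.family_of:
        rows.append((locus, "lnc_family", fam))
    for locus, fam in truth.te_decoy_family_of:
        rows.append((locus, "lnc_te_decoy", fam))
    for locus, pair in truth.pair_of:
        rows.append((locus, "lnc_pair", pair))
    for locus in sorted(truth.rrna_contaminated):
        rows.append((locus, "lnc_rrna_contaminated", ""))
    for locus in sorted(truth.background_lnc - truth.rrna_contaminated):
        rows.append((locus, "lnc_background", ""))
    for locus in sorted(truth.rrna_loci):
        rows.append((locus, "rrna", ""))
    for locus in sorted(truth.coding_loci):
        linked = {c: l for l, c in truth.coding_links}
        rows.append((locus, "mrna", linked.get(locus, "")))
    with open(path, "w") as fh:
        fh.write("locus_id\tcategory\tlabel\n")
        for row in sorted(rows):
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

_COMMON_COLS = ["ID", "GeneID", "geneSymbol", "chr", "strand"]
_COORD_COLS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
            "2ndExonEnd", "upstreamES", "upstreamEE", "downstreamES",
            "downstreamEE"],
}
_TAIL_COLS = ["IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
              "IncFormLen", "SkipFormLen", "PValue", "FDR", "IncLevel1",
              "IncLevel2", "IncLevelDifference"]


@dataclass(frozen=True)
class EventTables:
    """One comparison's emitted tables plus its planted truth."""

    label: str
    paths: tuple[tuple[str, str], ...]  # event_type -> path
    significant_ids: tuple[tuple[str, tuple[str, ...]], ...]
    significant_loci: frozenset[str]
    lnc_counts: tuple[tuple[str, int], ...]

    def path_map(self) -> dict[str, str]:
        return dict(self.paths)


def _fmt_levels(rng: np.random.Generator, n: int = 3) -> tuple[str, float]:
    vals = np.round(rng.uniform(0, 1, size=n), 3)
    return ",".join(f"{v:.3f}" for v in vals), float(np.mean(vals))


def generate_event_tables(
    cfg: SynthesisConfig,
    out_dir: str | os.PathLike,
    label: str = "milkseed_vs_mature",
    lnc_loci: Sequence[str] = (),
    other_loci: Sequence[str] | None = None,
    core_loci: Sequence[str] = (),
    rng: np.random.Generator | None = None,
    include_mxe: bool = True,
) -> EventTables:
    """Write one comparison's rMATS-dialect tables with planted significance.

    Exactly ``cfg.planted_significant[etype]`` rows per table satisfy
    p < 0.005 and FDR < 0.05; of those, ``cfg.lncrna_significant[etype]``
    are assigned loci from ``lnc_loci``. Filler rows fail at least one
    threshold, including exact-boundary rows (p = 0.005, FDR = 0.05) and
    rows with PValue printed as NA. ``core_loci`` are guaranteed to appear
    among the significant loci (used for cross-comparison intersections).
    """
    rng = rng or np.random.default_rng(cfg.seed + 7)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    planted = dict(cfg.planted_significant)
    lnc_planted = dict(cfg.lncrna_significant)
    if other_loci is None:
        other_loci = [f"LOC4{i:06d}" for i in range(1, 600)]
    other_loci = [l for l in other_loci if l not in set(core_loci)]
    lnc_pool = [l for l in lnc_loci if l not in set(core_loci)]

    paths: list[tuple[str, str]] = []
    sig_ids: list[tuple[str, tuple[str, ...]]] = []
    sig_loci: set[str] = set()
    lnc_counts: dict[str, int] = {}
    types = list(EVENT_TYPES_ORDER) if include_mxe else list(
        EVENT_TYPES_ORDER[:-1]
    )
    core_remaining = list(core_loci)
    for etype in types:
        n_rows = cfg.event_rows_per_type if etype != "MXE" else 60
        n_sig = planted.get(etype, 0)
        n_lnc = min(lnc_planted.get(etype, 0), n_sig) if lnc_loci else 0
        rows = []
        type_sig_ids = []
        for i in range(n_rows):
            event_id = i + 1
            significant = i < n_sig
            is_lnc = significant and i < n_lnc
            if significant:
                p = 10 ** rng.uniform(-8, math.log10(0.00499))
                fdr = float(rng.uniform(1e-6, 0.0499))
            else:
                mode = rng.random()
                if mode < 0.35:
                    p = float(rng.uniform(0.005, 1.0))
                    fdr = float(rng.uniform(0, 1.0))
                elif mode < 0.7:
                    p = 10 ** rng.uniform(-8, math.log10(0.00499))
                    fdr = float(rng.uniform(0.05, 1.0))
                elif mode < 0.8:
                    p = float("nan")
                    fdr = float(rng.uniform(0, 1.0))
                elif mode < 0.9:
                    p = 0.005  # exact boundary: strict filter must exclude
                    fdr = 0.01
                else:
                    p = 0.001
                    fdr = 0.05  # exact boundary on FDR
            if is_lnc:
                locus = lnc_pool[int(rng.integers(len(lnc_pool)))] if lnc_pool \
                    else lnc_loci[int(rng.integers(len(lnc_loci)))]
            elif significant and core_remaining:
                locus = core_remaining.pop()
            elif significant:
                locus = other_loci[int(rng.integers(len(other_loci)))]
            else:
                pool = list(other_loci) + list(lnc_loci)
                locus = pool[int(rng.integers(len(pool)))]
            if significant:
                sig_loci.add(locus)
                type_sig_ids.append(f"{etype}:{event_id}")
            inc1, m1 = _fmt_levels(rng)
            inc2, m2 = _fmt_levels(rng)
            coords = [int(x) for x in rng.integers(1000, 2_000_000,
                                                   size=len(_COORD_COLS[etype]))]
            p_str = "NA" if (isinstance(p, float) and math.isnan(p)) else f"{p:.6g}"
            rows.append(
                [str(event_id), f'"{locus}"', f'"{locus}"',
                 f"Chr{int(rng.integers(1, cfg.n_chromosomes + 1))}",
                 "+" if rng.random() < 0.5 else "-",
                 *map(str, coords),
                 ",".join(map(str, rng.integers(0, 200, size=3))),
                 ",".join(map(str, rng.integers(0, 200, size=3))),
                 ",".join(map(str, rng.integers(0, 200, size=3))),
                 ",".join(map(str, rng.integers(0, 200, size=3))),
                 str(int(rng.integers(50, 300))), str(int(rng.integers(50, 300))),
                 p_str, f"{fdr:.6g}", inc1, inc2, f"{m1 - m2:.3f}"]
            )
        path = os.path.join(out_dir, f"{label}.{etype}.MATS.JC.txt")
        header = _COMMON_COLS + _COORD_COLS[etype] + _TAIL_COLS
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths.append((etype, path))
        sig_ids.append((etype, tuple(type_sig_ids)))
        if etype != "MXE":
            lnc_counts[etype] = n_lnc
    return EventTables(
        label=label,
        paths=tuple(paths),
        significant_ids=tuple(sig_ids),
        significant_loci=frozenset(sig_loci),
        lnc_counts=tuple(sorted(lnc_counts.items())),
    )


EVENT_TYPES_ORDER = ("SE", "RI", "A5SS", "A3SS", "MXE")


def generate_comparison_suite(
    cfg: SynthesisConfig,
    out_dir: str | os.PathLike,
    lnc_loci: Sequence[str] = (),
) -> tuple[list[EventTables], frozenset[str]]:
    """Emit one table set per comparison label with a planted common core.

    The core loci (default 29) are significant in every comparison; each
    comparison additionally draws private significant loci from disjoint
    pools, so the full-intersection region of the locus sets equals the
    core exactly.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    core = [f"LOC3{i:06d}" for i in range(1, cfg.shared_core_size + 1)]
    suites = []
    for k, label in enumerate(cfg.comparison_labels):
        private = [f"LOC{5 + k}{i:06d}" for i in range(1, 600)]
        suites.append(
            generate_event_tables(
                cfg,
                out_dir,
                label=label,
                lnc_loci=lnc_loci if k == 0 else (),
                other_loci=private,
                core_loci=core,
                rng=np.random.default_rng(cfg.seed + 31 * (k + 1)),
            )
        )
    return suites, frozenset(core)
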