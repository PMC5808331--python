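"""Locus-level homology graph, gene-family extraction, and TE screening.

A gene family is three or more lncRNA loci connected (transitively) by
qualifying homology matches — the connected components of the undirected
locus graph, the minimal-assumption reading of "sharing significant
matches". Loci with exactly one or exactly two distinct match partners are
tallied separately (they fall below the family threshold), and families
whose shared material is transposon-derived are flagged by alignment
against a Type I transposon library and excluded from the reported
size spectrum.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .annotation_io import LocusCatalog, TranscriptRecord
from .homology_search import AlignmentParams, HomologyMatch, align_all

__all__ = [
    "GeneFamily",
    "FamilySpectrum",
    "build_family_graph",
    "extract_families",
    "degree_tallies",
    "family_spectrum",
    "screen_te",
    "rand_index",
    "write_families_tsv",
    "write_spectrum_tsv",
]


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: frozenset[str]
    edge_count: int
    te_flagged: bool = False
    te_reason: str | None = None
    representative_block: tuple[str, tuple[int, int]] | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FamilySpectrum:
    """Family-size histogram plus the below-threshold degree tallies."""

    size_counts: tuple[tuple[int, int], ...]  # (family size, n families), sorted
    n_degree_one: int  # loci that matched a single other lncRNA
    n_degree_two: int  # loci that matched exactly two others
    max_size: int

    @property
    def n_families(self) -> int:
        return sum(c for _, c in self.size_counts)

    @property
    def n_family_loci(self) -> int:
        return sum(s * c for s, c in self.size_counts)

    def as_dict(self) -> dict[int, int]:
        return dict(self.size_counts)


def build_family_graph(nc_matches: Iterable[HomologyMatch]) -> nx.Graph:
    """Undirected locus graph: one edge per unordered locus pair.

    Multiple matches (reciprocal hits, secondary HSPs) collapse onto one
    edge annotated with the best aligned_length/identity and, for the TE
    screen, the matched span on each incident locus' representative
    transcript (from the best match).
    """
    g = nx.Graph()
    for m in nc_matches:
        a, b = m.query_locus, m.subject_locus
        if a == b:
            continue
        g.add_node(a)
        g.add_node(b)
        data = g.get_edge_data(a, b)
        key = (m.aligned_length, m.percent_identity)
        if data is None or key > (data["aligned_length"], data["identity"]):
            g.add_edge(
                a,
                b,
                aligned_length=m.aligned_length,
                identity=m.percent_identity,
                spans={a: m.q_span, b: m.s_span},
                n_matches=1 if data is None else data["n_matches"] + 1,
            )
        else:
            data["n_matches"] += 1
    return g


def degree_tallies(graph: nx.Graph) -> tuple[int, int]:
    """(#loci with exactly one partner, #loci with exactly two partners)."""
    degs = [d for _, d in graph.degree()]
    return degs.count(1), degs.count(2)


def family_spectrum(
    families: Sequence[GeneFamily], graph: nx.Graph | None = None
) -> FamilySpectrum:
    """Spectrum over unflagged families; degree tallies from the full graph."""
    kept = [f for f in families if not f.te_flagged]
    counts = Counter(f.size for f in kept)
    d1, d2 = degree_tallies(graph) if graph is not None else (0, 0)
    return FamilySpectrum(
        size_counts=tuple(sorted(counts.items())),
        n_degree_one=d1,
        n_degree_two=d2,
        max_size=max((f.size for f in kept), default=0),
    )


def extract_families(
    graph: nx.Graph, min_size: int = 3
) -> tuple[list[GeneFamily], FamilySpectrum]:
    """Connected components of size >= min_size, as GeneFamily records.

    Families are numbered deterministically (by decreasing size, then by
    smallest member id). The spectrum's degree tallies are computed on the
    full graph, i.e. before any TE screening.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    comps = [c for c in nx.connected_components(graph) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    families = []
    for i, comp in enumerate(comps, start=1):
        sub = graph.subgraph(comp)
        best_edge = max(
            sub.edges(data=True), key=lambda e: e[2]["aligned_length"]
        )
        rep_locus = best_edge[0]
        families.append(
            GeneFamily(
                family_id=f"FAM{i:04d}",
                members=frozenset(comp),
                edge_count=sub.number_of_edges(),
                representative_block=(
                    rep_locus,
                    tuple(best_edge[2]["spans"][rep_locus]),
                ),
            )
        )
    return families, family_spectrum(families, graph)


# ---------------------------------------------------------------------------
# Transposable-element screening
# ---------------------------------------------------------------------------

def _family_span(graph: nx.Graph, family: GeneFamily, locus: str) -> tuple[int, int]:
    """Envelope of the locus' matched spans over its intra-family edges."""
    starts, ends = [], []
    for nbr in graph.neighbors(locus):
        if nbr in family.members:
            span = graph.edges[locus, nbr]["spans"].get(locus)
            if span is not None:
                starts.append(span[0])
                ends.append(span[1])
    if not starts:
        return (0, 0)
    return (min(starts), max(ends))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def screen_te(
    families: Sequence[GeneFamily],
    graph: nx.Graph,
    catalog: LocusCatalog,
    te_library: Iterable[TranscriptRecord] | LocusCatalog,
    params: AlignmentParams | None = None,
    member_fraction: float = 0.5,
    span_coverage: float = 0.5,
    min_te_match_length: int = 100,
) -> list[GeneFamily]:
    """Flag families whose shared material is transposon-derived.

    A member counts as TE-hit when its representative transcript has a TE
    library alignment of >= min_te_match_length columns covering
    >= span_coverage of the member's family-supporting matched span; a
    family is flagged when >= member_fraction of members are TE-hit.
    Flagged families are retained (with reason) but excluded from the
    spectrum by family_spectrum().
    """
    te_records = (
        list(te_library.transcripts())
        if isinstance(te_library, LocusCatalog)
        else list(te_library)
    )
    if not te_records:
        import warnings

        warnings.warn("empty TE library; screen_te is a no-op", stacklevel=2)
        return list(families)
    p = params or AlignmentParams()

    out = []
    for fam in families:
        n_hit = 0
        for locus in fam.members:
            reps = catalog.loci.get(locus)
            if not reps:
                continue
            rep = reps[0]
            fam_span = _family_span(graph, fam, locus)
            span_len = fam_span[1] - fam_span[0]
            if span_len <= 0:
                continue
            te_matches = align_all([rep], te_records, p)
            for m in te_matches:
                if (
                    m.aligned_length >= min_te_match_length
                    and _overlap(m.q_span, fam_span) >= span_coverage * span_len
                ):
                    n_hit += 1
                    break
        if n_hit >= member_fraction * fam.size:
            out.append(
                replace(
                    fam,
                    te_flagged=True,
                    te_reason=(
                        f"{n_hit}/{fam.size} members have a TE match >= "
                        f"{min_te_match_length} bp covering >= "
                        f"{span_coverage:.0%} of the family-supporting span"
                    ),
                )
            )
        else:
            out.append(fam)
    return out


# ---------------------------------------------------------------------------
# Partition comparison
# ---------------------------------------------------------------------------

def rand_index(
    partition_a: Mapping[str, str] | Iterable[Iterable[str]],
    partition_b: Mapping[str, str] | Iterable[Iterable[str]],
    universe: Iterable[str],
) -> float:
    """Rand index of two partial clusterings over a common universe.

    Partitions may be given as label maps or as collections of groups;
    universe elements absent from a partition count as singletons. Pair
    counting is exact (no sampling): RI = (agreeing pairs) / (all pairs).
    """

    def as_labels(p) -> dict[str, str]:
        if isinstance(p, Mapping):
            return dict(p)
        labels = {}
        for i, group in enumerate(p):
            for x in group:
                labels[x] = f"g{i}"
        return labels

    la, lb = as_labels(partition_a), as_labels(partition_b)
    items = sorted(set(universe))
    n = len(items)
    if n < 2:
        return 1.0
    agree = 0
    total = 0
    for x, y in combinations(items, 2):
        same_a = la.get(x, f"~{x}") == la.get(y, f"~{y}")
        same_b = lb.get(x, f"~{x}") == lb.get(y, f"~{y}")
        agree += same_a == same_b
        total += 1
    return agree / total


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_families_tsv(
    families: Sequence[GeneFamily], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tsize\tmembers\tte_flagged\tte_reason\n")
        for f in families:
            members = ",".join(sorted(f.members))
            fh.write(
                f"{f.family_id}\t{f.size}\t{members}\t"
                f"{int(f.te_flagged)}\t{f.te_reason or ''}\n"
            )


def write_spectrum_tsv(spectrum: FamilySpectrum, path: str | os.PathLike) -> None:
    """Two columns matching the family-size histogram axes."""
    with open(path, "w") as fh:
        fh.write("family_size\tn_families\n")
        for size, count in spectrum.size_counts:
            fh.write(f"{size}\t{count}\n")
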