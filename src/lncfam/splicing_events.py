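"""Differential-splicing event tables: ingestion, significance filter,
cross-comparison intersection, and lncRNA flagging.

Consumes the rMATS junction-count tabular dialect (``SE.MATS.JC.txt`` and
friends) — the statistical model behind those tables is a published tool
and is not re-implemented here. The significance rule is strict on both
thresholds (p < 0.005 and FDR < 0.05) by default; rows with missing
p-values fail every threshold. For cross-comparison intersections events
are deduplicated to loci (a locus with both an SE and an RI event counts
once); per-event tallies are kept for the per-type counts.
"""

from __future__ import annotations

import math
import os
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import LocusCatalog

__all__ = [
    "EVENT_TYPES",
    "REPORTED_EVENT_TYPES",
    "EventTableError",
    "SpliceEventRecord",
    "ComparisonResult",
    "IntersectionResult",
    "read_events",
    "filter_significant",
    "count_by_type",
    "build_comparison",
    "intersect_comparisons",
    "flag_lncrna_events",
    "write_events_rmats",
    "write_events_tsv",
]

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")
#: MXE is parsed but excluded from the four-type analysis report.
REPORTED_EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS")

_REQUIRED_COLUMNS = ("GeneID", "PValue", "FDR", "IncLevelDifference")


class EventTableError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceEventRecord:
    """One alternative-splicing event row."""

    event_id: str
    event_type: str
    locus_id: str
    chrom: str
    strand: str
    p_value: float  # nan when the caller printed NA
    fdr: float
    inclusion_difference: float
    inc_levels_1: tuple[float, ...] = ()
    inc_levels_2: tuple[float, ...] = ()


def _infer_event_type(path: str) -> str:
    name = os.path.basename(path)
    for etype in EVENT_TYPES:
        if re.search(rf"(^|[._]){etype}([._])", name):
            return etype
    raise EventTableError(f"cannot infer event type from filename {name!r}")


def _parse_levels(value) -> tuple[float, ...]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    out = []
    for part in str(value).split(","):
        part = part.strip()
        out.append(float("nan") if part in ("NA", "", "nan") else float(part))
    return tuple(out)


def _normalise_locus(gene_id: str) -> str:
    gene_id = str(gene_id).strip().strip('"').strip("'")
    if gene_id.startswith("gene:") or gene_id.startswith("gene-"):
        gene_id = gene_id[5:]
    return gene_id


def read_events(
    paths: Iterable[str | os.PathLike] | Mapping[str, str | os.PathLike],
) -> list[SpliceEventRecord]:
    """Parse per-type tab-separated event tables into records.

    ``paths`` is either a mapping event_type -> path or a list of paths
    whose event types are inferred from the filename (SE/RI/A5SS/A3SS/MXE).
    """
    if isinstance(paths, Mapping):
        items = [(etype, str(p)) for etype, p in paths.items()]
    else:
        items = [(_infer_event_type(str(p)), str(p)) for p in paths]
    records: list[SpliceEventRecord] = []
    for etype, path in items:
        if etype not in EVENT_TYPES:
            raise EventTableError(f"unknown event type {etype!r}")
        df = pd.read_csv(path, sep="\t", dtype={"GeneID": str})
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise EventTableError(f"{path}: missing required column {col!r}")
        for _, row in df.iterrows():
            records.append(
                SpliceEventRecord(
                    event_id=f"{etype}:{row.get('ID', _normalise_locus(row['GeneID']))}",
                    event_type=etype,
                    locus_id=_normalise_locus(row["GeneID"]),
                    chrom=str(row.get("chr", ".")),
                    strand=str(row.get("strand", "+")),
                    p_value=pd.to_numeric(row["PValue"], errors="coerce"),
                    fdr=pd.to_numeric(row["FDR"], errors="coerce"),
                    inclusion_difference=pd.to_numeric(
                        row["IncLevelDifference"], errors="coerce"
                    ),
                    inc_levels_1=_parse_levels(row.get("IncLevel1")),
                    inc_levels_2=_parse_levels(row.get("IncLevel2")),
                )
            )
    return records


def filter_significant(
    records: Iterable[SpliceEventRecord],
    p_max: float = 0.005,
    fdr_max: float = 0.05,
    strict: bool = True,
) -> list[SpliceEventRecord]:
    """Rows meeting both significance cutoffs (strict ``<`` by default).

    NaN p-values or FDRs fail regardless of thresholds. The operation is
    idempotent and monotone in both thresholds.
    """
    if not (0 < p_max <= 1 and 0 < fdr_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")

    def passes(r: SpliceEventRecord) -> bool:
        if math.isnan(r.p_value) or math.isnan(r.fdr):
            return False
        if strict:
            return r.p_value < p_max and r.fdr < fdr_max
        return r.p_value <= p_max and r.fdr <= fdr_max

    return [r for r in records if passes(r)]


def count_by_type(
    records: Iterable[SpliceEventRecord],
    types: Sequence[str] = REPORTED_EVENT_TYPES,
    per_locus: bool = False,
) -> dict[str, int]:
    """Events (or distinct loci) per event type."""
    if per_locus:
        seen: dict[str, set[str]] = {t: set() for t in types}
        for r in records:
            if r.event_type in seen:
                seen[r.event_type].add(r.locus_id)
        return {t: len(s) for t, s in seen.items()}
    counts = Counter(r.event_type for r in records)
    return {t: counts.get(t, 0) for t in types}


@dataclass(frozen=True)
class ComparisonResult:
    """Significant-event summary of one pairwise comparison."""

    label: str
    per_type_counts: tuple[tuple[str, int], ...]
    loci: frozenset[str]
    lncrna_loci: frozenset[str]

    def counts(self) -> dict[str, int]:
        return dict(self.per_type_counts)


def build_comparison(
    label: str,
    significant: Iterable[SpliceEventRecord],
    lnc_catalog: LocusCatalog | None = None,
) -> ComparisonResult:
    significant = list(significant)
    loci = frozenset(r.locus_id for r in significant)
    lnc = (
        frozenset(l for l in loci if l in lnc_catalog)
        if lnc_catalog is not None
        else frozenset()
    )
    return ComparisonResult(
        label=label,
        per_type_counts=tuple(sorted(count_by_type(significant).items())),
        loci=loci,
        lncrna_loci=lnc,
    )


@dataclass(frozen=True)
class IntersectionResult:
    """Locus membership across comparisons plus region counts.

    ``region_counts`` keys are tuples of booleans aligned with ``labels``
    (True = locus significant in that comparison); only non-empty patterns
    appear. ``shared_all`` is the full-intersection locus set.
    """

    labels: tuple[str, ...]
    membership: pd.DataFrame  # loci x labels, bool
    region_counts: tuple[tuple[tuple[bool, ...], int], ...]
    shared_all: frozenset[str]

    def region(self, pattern: tuple[bool, ...]) -> int:
        return dict(self.region_counts).get(pattern, 0)


def intersect_comparisons(results: Sequence[ComparisonResult]) -> IntersectionResult:
    """Venn/UpSet-style intersection of significant locus sets.

    Every locus significant in at least one comparison is assigned to
    exactly one region (its presence pattern), so region counts sum to the
    union size.
    """
    if len(results) < 2:
        raise ValueError("need at least two comparisons to intersect")
    labels = tuple(r.label for r in results)
    union = sorted(set().union(*(r.loci for r in results)))
    membership = pd.DataFrame(
        {r.label: [l in r.loci for l in union] for r in results},
        index=pd.Index(union, name="locus_id"),
        dtype=bool,
    )
    patterns = Counter(tuple(row) for row in membership.itertuples(index=False))
    shared_all = frozenset(
        l for l in union if all(l in r.loci for r in results)
    )
    return IntersectionResult(
        labels=labels,
        membership=membership,
        region_counts=tuple(sorted(patterns.items(), reverse=True)),
        shared_all=shared_all,
    )


def flag_lncrna_events(
    significant: Iterable[SpliceEventRecord],
    lnc_catalog: LocusCatalog,
    types: Sequence[str] = REPORTED_EVENT_TYPES,
) -> dict[str, int]:
    """Per-type counts of significant events whose locus is a lncRNA."""
    counts: dict[str, int] = {t: 0 for t in types}
    for r in significant:
        if r.event_type in counts and r.locus_id in lnc_catalog:
            counts[r.event_type] += 1
    return counts


def write_events_rmats(
    records: Iterable[SpliceEventRecord],
    out_dir: str | os.PathLike,
    label: str = "events",
) -> dict[str, str]:
    """Write records back out as per-type tables read_events can re-read.

    Lossless for every populated field (event ids keep their numeric part;
    NaN statistics are printed as NA, the dialect's missing marker).
    """
    os.makedirs(out_dir, exist_ok=True)
    by_type: dict[str, list[SpliceEventRecord]] = {}
    for r in records:
        by_type.setdefault(r.event_type, []).append(r)

    def fmt(x: float) -> str:
        return "NA" if (x is None or math.isnan(x)) else repr(float(x))

    paths = {}
    for etype, rows in by_type.items():
        path = os.path.join(str(out_dir), f"{label}.{etype}.MATS.JC.txt")
        with open(path, "w") as fh:
            fh.write(
                "ID\tGeneID\tchr\tstrand\tPValue\tFDR\tIncLevel1\tIncLevel2\t"
                "IncLevelDifference\n"
            )
            for r in rows:
                rid = r.event_id.split(":", 1)[-1]
                lv1 = ",".join("NA" if math.isnan(v) else f"{v}" for v in r.inc_levels_1)
                lv2 = ",".join("NA" if math.isnan(v) else f"{v}" for v in r.inc_levels_2)
                fh.write(
                    f"{rid}\t{r.locus_id}\t{r.chrom}\t{r.strand}\t{fmt(r.p_value)}\t"
                    f"{fmt(r.fdr)}\t{lv1}\t{lv2}\t{fmt(r.inclusion_difference)}\n"
                )
        paths[etype] = path
    return paths


def write_events_tsv(
    records: Iterable[SpliceEventRecord], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "event_id\tevent_type\tlocus_id\tchrom\tstrand\tp_value\tfdr\t"
            "inclusion_difference\n"
        )
        for r in records:
            fh.write(
                f"{r.event_id}\t{r.event_type}\t{r.locus_id}\t{r.chrom}\t"
                f"{r.strand}\t{r.p_value!r}\t{r.fdr!r}\t{r.inclusion_difference!r}\n"
            )
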