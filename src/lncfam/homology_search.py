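"""All-vs-all local nucleotide homology search.

The engine pairs a shared-k-mer prefilter (a pair of sequences is aligned
only if query and target share at least one exact k-mer on either strand)
with an exact Smith-Waterman dynamic program under a linear gap penalty.
Secondary, non-overlapping alignments of the same pair are produced by
masking the query span of each reported alignment and re-running the DP
(greedy by score; ties resolved by leftmost query start via the row-major
argmax). Significance is assessed with Karlin-Altschul statistics,
E = K * m * n * exp(-lambda * S), using the ungapped constants for the
default +1/-2 scoring and search space m = query length, n = total target
length.

Default scoring mirrors megablast-style parameters: match +1, mismatch -2,
linear gap penalty 2.5 per gap base, seed k = 11, E-value cutoff 1e-6.
All are configurable through :class:`AlignmentParams`.

``N`` bases are encoded as a fifth symbol that mismatches everything,
including another ``N``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .annotation_io import LocusCatalog, TranscriptRecord, reverse_complement

__all__ = [
    "AlignmentParams",
    "HomologyMatch",
    "ConfigurationError",
    "TabularFormatError",
    "align_all",
    "smith_waterman",
    "import_blast_tabular",
    "export_blast_tabular",
    "write_matches_tsv",
]


class ConfigurationError(ValueError):
    pass


class TabularFormatError(ValueError):
    pass


# Ungapped Karlin-Altschul parameters for match +1 / mismatch -2 (the BLASTN
# table values); adequate for thresholding under near-linear gap costs.
_KA_LAMBDA = 1.28
_KA_K = 0.46


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and significance thresholds for align_all.

    gap_penalty is the (positive) cost per gap base, applied linearly —
    the "gap open -2.5 equivalent" of megablast defaults.
    """

    seed_k: int = 11
    match: float = 1.0
    mismatch: float = -2.0
    gap_penalty: float = 2.5
    evalue_max: float | None = 1e-6
    min_score: float | None = None
    max_alignments_per_pair: int = 4
    ka_lambda: float = _KA_LAMBDA
    ka_k: float = _KA_K

    def evalue(self, score: float, query_len: int, db_len: int) -> float:
        return self.ka_k * query_len * db_len * math.exp(-self.ka_lambda * score)

    def score_cutoff(self, query_len: int, db_len: int) -> float:
        """Smallest score worth reporting for this query/database size."""
        cutoffs = []
        if self.evalue_max is not None:
            cutoffs.append(
                math.log(self.ka_k * query_len * db_len / self.evalue_max)
                / self.ka_lambda
            )
        if self.min_score is not None:
            cutoffs.append(self.min_score)
        if not cutoffs:
            cutoffs.append(1e-9)  # report any positive-scoring alignment
        return max(cutoffs)


@dataclass(frozen=True)
class HomologyMatch:
    """One local alignment between two transcripts.

    Spans are 0-based half-open on transcript coordinates; s_span is always
    on the forward strand of the subject, with subject_strand recording
    whether the alignment used its reverse complement.
    """

    query_id: str
    subject_id: str
    query_locus: str
    subject_locus: str
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    aligned_length: int
    n_identical: int
    n_gaps: int
    score: float
    evalue: float
    subject_strand: str
    subject_class: str = "unclassified"

    @property
    def percent_identity(self) -> float:
        return self.n_identical / self.aligned_length

    def classified(self, subject_class: str) -> "HomologyMatch":
        return replace(self, subject_class=subject_class)


# ---------------------------------------------------------------------------
# Smith-Waterman kernel
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (incl. N) -> 4, which never matches."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap):  # pragma: no cover - numba
    n, m = q.shape[0], s.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == s[j - 1] and qi != 4:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] + mismatch
            u = H[i - 1, j] - gap
            if u > h:
                h = u
            l = H[i, j - 1] - gap
            if l > h:
                h = l
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, best, bi, bj


def _traceback(H, q, s, bi, bj, match, mismatch, gap):
    """Walk back from (bi, bj); returns spans, columns, identities, gaps."""
    i, j = bi, bj
    columns = 0
    identical = 0
    gaps = 0
    eps = 1e-6
    while i > 0 and j > 0 and H[i, j] > eps:
        is_match = q[i - 1] == s[j - 1] and q[i - 1] != 4
        sub = match if is_match else mismatch
        if abs(H[i, j] - (H[i - 1, j - 1] + sub)) < eps:
            columns += 1
            if is_match:
                identical += 1
            i -= 1
            j -= 1
        elif abs(H[i, j] - (H[i - 1, j] - gap)) < eps:
            columns += 1
            gaps += 1
            i -= 1
        else:
            columns += 1
            gaps += 1
            j -= 1
    return (i, bi), (j, bj), columns, identical, gaps


def smith_waterman(
    query: str, subject: str, params: AlignmentParams | None = None
) -> tuple[float, tuple[int, int], tuple[int, int], int, int, int]:
    """Optimal local alignment of two sequences (single best).

    Returns (score, q_span, s_span, aligned_length, n_identical, n_gaps);
    score 0.0 with empty spans if no positive-scoring alignment exists.
    """
    p = params or AlignmentParams()
    q = encode_sequence(query)
    s = encode_sequence(subject)
    H, best, bi, bj = _sw_fill(q, s, p.match, p.mismatch, p.gap_penalty)
    if best <= 0.0:
        return 0.0, (0, 0), (0, 0), 0, 0, 0
    q_span, s_span, columns, identical, gaps = _traceback(
        H, q, s, bi, bj, p.match, p.mismatch, p.gap_penalty
    )
    return best, q_span, s_span, columns, identical, gaps


def _kmer_set(encoded: np.ndarray, k: int) -> set[int]:
    """Integer-packed k-mers over A/C/G/T (windows containing N are skipped)."""
    n = encoded.shape[0]
    if n < k:
        return set()
    valid = encoded < 4
    packed = set()
    code = 0
    run = 0
    for i in range(n):
        if not valid[i]:
            run = 0
            code = 0
            continue
        code = ((code << 2) | int(encoded[i])) & ((1 << (2 * k)) - 1)
        run += 1
        if run >= k:
            packed.add(code)
    return packed


def _as_records(seqs) -> list[TranscriptRecord]:
    if isinstance(seqs, LocusCatalog):
        return list(seqs.transcripts())
    return list(seqs)


def _pair_alignments(q_enc, s_enc, params, cutoff):
    """All non-overlapping alignments of one (query, oriented-subject) pair.

    Greedy Waterman-Eggert-style declumping: report the best alignment,
    mask its query span with the never-matching symbol, repeat.
    """
    out = []
    q_work = q_enc
    for _ in range(params.max_alignments_per_pair):
        H, best, bi, bj = _sw_fill(
            q_work, s_enc, params.match, params.mismatch, params.gap_penalty
        )
        if best < cutoff or best <= 0.0:
            break
        q_span, s_span, columns, identical, gaps = _traceback(
            H, q_work, s_enc, bi, bj, params.match, params.mismatch, params.gap_penalty
        )
        out.append((best, q_span, s_span, columns, identical, gaps))
        if q_work is q_enc:
            q_work = q_enc.copy()
        q_work[q_span[0] : q_span[1]] = 4
    return out


def align_all(
    queries: Iterable[TranscriptRecord] | LocusCatalog,
    targets: Iterable[TranscriptRecord] | LocusCatalog,
    params: AlignmentParams | None = None,
) -> list[HomologyMatch]:
    """All significant local alignments of every query against every target.

    Both target strands are searched. Exact self-alignments
    (query_id == subject_id) are emitted too; downstream filtering removes
    them. When queries and targets are the same transcript set, each
    unordered pair is aligned once and the reciprocal match is produced by
    mirroring (exact, since local alignment is symmetric).
    """
    p = params or AlignmentParams()
    q_records = _as_records(queries)
    t_records = _as_records(targets)
    for rec in q_records + t_records:
        if len(rec.sequence) == 0:
            raise ConfigurationError(f"{rec.transcript_id}: empty sequence")
    shortest = min(len(r.sequence) for r in q_records + t_records)
    if p.seed_k > shortest:
        raise ConfigurationError(
            f"seed_k={p.seed_k} exceeds shortest sequence length {shortest}"
        )

    db_len = sum(len(r.sequence) for r in t_records)
    t_ids = [r.transcript_id for r in t_records]
    symmetric = [r.transcript_id for r in q_records] == t_ids

    enc_q = {r.transcript_id: encode_sequence(r.sequence) for r in q_records}
    enc_t: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for r in t_records:
        fwd = enc_q.get(r.transcript_id)
        if fwd is None:
            fwd = encode_sequence(r.sequence)
        rev = encode_sequence(reverse_complement(r.sequence))
        enc_t[r.transcript_id] = (fwd, rev)
    kmers_q = {tid: _kmer_set(enc, p.seed_k) for tid, enc in enc_q.items()}
    kmers_t = {
        tid: (_kmer_set(f, p.seed_k), _kmer_set(r, p.seed_k))
        for tid, (f, r) in enc_t.items()
    }

    matches: list[HomologyMatch] = []
    for qi, q_rec in enumerate(q_records):
        q_enc = enc_q[q_rec.transcript_id]
        q_kmers = kmers_q[q_rec.transcript_id]
        cutoff = p.score_cutoff(len(q_rec.sequence), db_len)
        t_start = qi if symmetric else 0
        for t_rec in t_records[t_start:]:
            s_fwd, s_rev = enc_t[t_rec.transcript_id]
            k_fwd, k_rev = kmers_t[t_rec.transcript_id]
            s_len = len(t_rec.sequence)
            for strand, s_enc, s_kmers in (("+", s_fwd, k_fwd), ("-", s_rev, k_rev)):
                if q_kmers and s_kmers and q_kmers.isdisjoint(s_kmers):
                    continue
                for best, q_span, s_span, cols, ident, gaps in _pair_alignments(
                    q_enc, s_enc, p, cutoff
                ):
                    if strand == "-":
                        s_span = (s_len - s_span[1], s_len - s_span[0])
                    m = HomologyMatch(
                        query_id=q_rec.transcript_id,
                        subject_id=t_rec.transcript_id,
                        query_locus=q_rec.locus_id,
                        subject_locus=t_rec.locus_id,
                        q_span=q_span,
                        s_span=s_span,
                        aligned_length=cols,
                        n_identical=ident,
                        n_gaps=gaps,
                        score=best,
                        evalue=p.evalue(best, len(q_rec.sequence), db_len),
                        subject_strand=strand,
                    )
                    matches.append(m)
                    if symmetric and t_rec.transcript_id != q_rec.transcript_id:
                        matches.append(
                            HomologyMatch(
                                query_id=t_rec.transcript_id,
                                subject_id=q_rec.transcript_id,
                                query_locus=t_rec.locus_id,
                                subject_locus=q_rec.locus_id,
                                q_span=m.s_span,
                                s_span=m.q_span,
                                aligned_length=cols,
                                n_identical=ident,
                                n_gaps=gaps,
                                score=best,
                                evalue=p.evalue(best, len(t_rec.sequence), db_len),
                                subject_strand=strand,
                            )
                        )
    return matches


# ---------------------------------------------------------------------------
# 12-column tabular interchange (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

_OUTFMT6_NCOLS = 12


def import_blast_tabular(
    path: str | os.PathLike,
    locus_map: dict[str, str] | None = None,
) -> list[HomologyMatch]:
    """Read outfmt-6 rows (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore) into HomologyMatch records.

    1-based closed coordinates are converted to 0-based half-open;
    sstart > send marks a minus-strand subject; pident is rescaled to a
    fraction. Without a locus_map, transcript ids stand in for locus ids.
    """
    locus_map = locus_map or {}
    matches = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_NCOLS:
                raise TabularFormatError(
                    f"{path}:{lineno}: expected {_OUTFMT6_NCOLS} columns, "
                    f"got {len(fields)}"
                )
            (qid, sid, pident, length, mism, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            length_i = int(length)
            sstart_i, send_i = int(sstart), int(send)
            if sstart_i > send_i:
                strand = "-"
                s_span = (send_i - 1, sstart_i)
            else:
                strand = "+"
                s_span = (sstart_i - 1, send_i)
            n_ident = int(round(float(pident) * length_i / 100.0))
            matches.append(
                HomologyMatch(
                    query_id=qid,
                    subject_id=sid,
                    query_locus=locus_map.get(qid, qid),
                    subject_locus=locus_map.get(sid, sid),
                    q_span=(int(qstart) - 1, int(qend)),
                    s_span=s_span,
                    aligned_length=length_i,
                    n_identical=n_ident,
                    n_gaps=length_i - n_ident - int(mism),
                    score=float(bitscore),
                    evalue=float(evalue),
                    subject_strand=strand,
                )
            )
    return matches


def export_blast_tabular(
    matches: Sequence[HomologyMatch], path: str | os.PathLike
) -> None:
    """Write matches in the 12-column dialect import_blast_tabular reads."""
    with open(path, "w") as fh:
        for m in matches:
            if m.subject_strand == "-":
                sstart, send = m.s_span[1], m.s_span[0] + 1
            else:
                sstart, send = m.s_span[0] + 1, m.s_span[1]
            pident = 100.0 * m.n_identical / m.aligned_length
            mism = m.aligned_length - m.n_identical - m.n_gaps
            fh.write(
                f"{m.query_id}\t{m.subject_id}\t{pident:.3f}\t{m.aligned_length}\t"
                f"{mism}\t{m.n_gaps}\t{m.q_span[0] + 1}\t{m.q_span[1]}\t"
                f"{sstart}\t{send}\t{m.evalue:.6g}\t{m.score:.6g}\n"
            )


def write_matches_tsv(matches: Sequence[HomologyMatch], path: str | os.PathLike) -> None:
    """Richer TSV: the 12 tabular columns plus locus ids and subject_class."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\tsubject_id\tquery_locus\tsubject_locus\tpercent_identity\t"
            "aligned_length\tq_start\tq_end\ts_start\ts_end\tstrand\tscore\t"
            "evalue\tsubject_class\n"
        )
        for m in matches:
            fh.write(
                f"{m.query_id}\t{m.subject_id}\t{m.query_locus}\t{m.subject_locus}\t"
                f"{m.percent_identity:.4f}\t{m.aligned_length}\t{m.q_span[0]}\t"
                f"{m.q_span[1]}\t{m.s_span[0]}\t{m.s_span[1]}\t{m.subject_strand}\t"
                f"{m.score:.6g}\t{m.evalue:.6g}\t{m.subject_class}\n"
            )
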