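"""All-vs-all matching of two unigene sets with filtered local alignment.

Smith–Waterman local alignment with affine gaps (match +1 / mismatch −2 /
gap open 5 / gap extend 2, so a gap of length L costs 5 + 2L) is run via
Bio.Align.PairwiseAligner; suboptimal, non-overlapping HSPs are recovered by
recursively re-aligning the query segments left and right of each reported
HSP, which is what lets one large indel split a homologous pair into two
collinear HSPs. E-values follow the Karlin–Altschul form
E = m·n·K·exp(−λ·S) with published ungapped constants for the scoring
scheme; the E-value filter's behaviour, not exact BLAST-equal numbers, is
the contract. A canonical k-mer prefilter restricts which subjects are
aligned at all; alignment of the surviving candidates is optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, revcomp

# ---------------------------------------------------------------- scoring


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; gap of length L costs gap_open + gap_extend * L."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2


@dataclass(frozen=True)
class KarlinAltschul:
    """Ungapped λ/K for +1/−2 scoring at uniform base composition."""

    lam: float = 1.33
    k: float = 0.621


def bit_score(raw_score: float, ka: KarlinAltschul = KarlinAltschul()) -> float:
    return (ka.lam * raw_score - math.log(ka.k)) / math.log(2.0)


def evalue(bit: float, m: int, n: int) -> float:
    """Expected chance hits: E = m·n·2^(−bit_score)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return m * n * 2.0 ** (-bit)


def min_raw_score(max_evalue: float, m: int, n: int, ka: KarlinAltschul = KarlinAltschul()) -> float:
    """Smallest raw score whose E-value at (m, n) is ≤ max_evalue."""
    return math.log(m * n * ka.k / max_evalue) / ka.lam


# ------------------------------------------------------------------ types


@dataclass
class AlignmentHSP:
    """One local alignment segment.

    Coordinates are 0-based half-open on the forward strands as stored;
    for strand "-" the subject row of ``columns`` is in reverse-complement
    orientation while (s_start, s_end) stay forward.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    q_row: str
    s_row: str
    raw_score: float
    bit_score: float = 0.0
    evalue: float = math.inf
    s_len: int = 0
    n_columns: int = field(init=False)
    n_matches: int = field(init=False)
    identity: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.q_row) != len(self.s_row):
            raise ValueError("aligned rows differ in length")
        self.n_columns = len(self.q_row)
        self.n_matches = sum(
            1
            for a, b in zip(self.q_row, self.s_row)
            if a == b and a not in "-N"
        )
        self.identity = self.n_matches / self.n_columns if self.n_columns else 0.0

    def subject_fwd_pos(self, oriented_pos: int) -> int:
        """Map an oriented subject coordinate to the forward strand."""
        if self.strand == "+":
            return oriented_pos
        return self.s_len - 1 - oriented_pos

    @property
    def oriented_s_start(self) -> int:
        return self.s_start if self.strand == "+" else self.s_len - self.s_end


@dataclass(frozen=True)
class MatchFilter:
    min_identity: float = 0.96
    max_evalue: float = 1e-10
    min_hsp_len: int = 33

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1) or self.max_evalue <= 0 or self.min_hsp_len < 1:
            raise ValueError("invalid MatchFilter")


@dataclass
class MatchedPair:
    query_id: str
    subject_id: str
    hsps: list[AlignmentHSP]
    matched_columns: int
    strand: str
    query_seq: str = ""
    subject_seq: str = ""


# ------------------------------------------------------------- alignment


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    al.substitution_matrix = mat
    # biopython charges open on the first gap position: open+(L-1)*extend
    al.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    al.extend_gap_score = -scoring.gap_extend
    return al


def _score_rows(q_row: str, s_row: str, scoring: Scoring) -> float:
    raw = 0.0
    in_gap = False
    for a, b in zip(q_row, s_row):
        if a == "-" or b == "-":
            raw -= scoring.gap_extend + (scoring.gap_open if not in_gap else 0)
            in_gap = True
        else:
            in_gap = False
            raw += scoring.match if (a == b and a != "N") else scoring.mismatch
    return raw


def _trim_terminal_gaps(q_row: str, s_row: str) -> tuple[str, str, int, int]:
    """Strip gap columns from either end; return rows plus trimmed column counts."""
    lo, hi = 0, len(q_row)
    while lo < hi and (q_row[lo] == "-" or s_row[lo] == "-"):
        lo += 1
    while hi > lo and (q_row[hi - 1] == "-" or s_row[hi - 1] == "-"):
        hi -= 1
    return q_row[lo:hi], s_row[lo:hi], lo, len(q_row) - hi


def _split_at_large_gaps(
    q_row: str, s_row: str, split_gap: int
) -> list[tuple[str, str, int, int]]:
    """Split an alignment at gap runs of length ≥ split_gap.

    Optimal Smith–Waterman happily bridges even a multi-hundred-nt gap when
    the flanking matches pay for it, whereas seeded aligners terminate
    extension there and report two HSPs — which is the topology the
    small/large indel dichotomy is defined on. Returns
    (q_row, s_row, q_offset, s_offset) segments with offsets counted in
    non-gap characters of each row from the start of the input alignment.
    """
    runs = []  # (start_col, end_col) of gap runs to split at
    i = 0
    n = len(q_row)
    while i < n:
        if q_row[i] == "-" or s_row[i] == "-":
            row = q_row if q_row[i] == "-" else s_row
            j = i
            while j < n and row[j] == "-":
                j += 1
            if j - i >= split_gap:
                runs.append((i, j))
            i = j
        else:
            i += 1
    segments = []
    prev = 0
    bounds = runs + [(n, n)]
    q_off = s_off = 0
    for (a, b) in bounds:
        qseg, sseg = q_row[prev:a], s_row[prev:a]
        qseg, sseg, lo, _hi = _trim_terminal_gaps(qseg, sseg)
        q_pre = sum(1 for c in q_row[prev : prev + lo] if c != "-")
        s_pre = sum(1 for c in s_row[prev : prev + lo] if c != "-")
        if qseg:
            segments.append((qseg, sseg, q_off + q_pre, s_off + s_pre))
        q_off += sum(1 for c in q_row[prev:b] if c != "-")
        s_off += sum(1 for c in s_row[prev:b] if c != "-")
        prev = b
    return segments


def _extract_hsps(
    qseq: str,
    s_oriented: str,
    aligner: Align.PairwiseAligner,
    min_raw: float,
    min_segment: int,
) -> list[tuple[int, int, int, int, str, str, float]]:
    """Greedy query-interval splitting around each optimal local HSP."""
    out: list[tuple] = []
    stack = [(0, len(qseq))]
    while stack:
        qs, qe = stack.pop()
        if qe - qs < min_segment:
            continue
        alns = aligner.align(qseq[qs:qe], s_oriented)
        try:
            best = alns[0]
        except IndexError:
            continue
        if best.score < min_raw:
            continue
        coords = best.coordinates
        t0, t1 = int(coords[0][0]), int(coords[0][-1])
        s0, s1 = int(coords[1][0]), int(coords[1][-1])
        out.append((qs + t0, qs + t1, s0, s1, str(best[0]), str(best[1]), float(best.score)))
        stack.append((qs, qs + t0))
        stack.append((qs + t1, qe))
    return out


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: Scoring = Scoring(),
    ka: KarlinAltschul = KarlinAltschul(),
    min_raw: float | None = None,
    n_db: int | None = None,
    min_segment: int = 10,
    split_gap: int = 23,
) -> list[AlignmentHSP]:
    """Optimal local HSP plus non-overlapping suboptimal HSPs, both strands.

    ``n_db`` is the effective database length used for E-values (defaults
    to the subject length). ``min_raw`` defaults to the raw score whose
    E-value is 10 (a permissive floor; callers filter further). Alignments
    are split at internal gap runs of ≥ ``split_gap`` columns, so an event
    of that size separates a pair into two collinear HSPs.
    """
    if not query.seq or not subject.seq:
        raise ValueError("empty sequence in local_align")
    m = len(query.seq)
    n = n_db if n_db is not None else len(subject.seq)
    if min_raw is None:
        min_raw = min_raw_score(10.0, m, n, ka)
    aligner = _aligner(scoring)
    hsps: list[AlignmentHSP] = []
    slen = len(subject.seq)
    for strand, s_oriented in (("+", subject.seq), ("-", revcomp(subject.seq))):
        for (q0, q1, s0, s1, qrow, srow, raw) in _extract_hsps(
            query.seq, s_oriented, aligner, min_raw, min_segment
        ):
            for (qseg, sseg, q_off, s_off) in _split_at_large_gaps(qrow, srow, split_gap):
                raw_seg = _score_rows(qseg, sseg, scoring)
                if raw_seg < min_raw:
                    continue
                q_lo = q0 + q_off
                q_hi = q_lo + sum(1 for c in qseg if c != "-")
                so_lo = s0 + s_off
                so_hi = so_lo + sum(1 for c in sseg if c != "-")
                if strand == "+":
                    s_start, s_end = so_lo, so_hi
                else:
                    s_start, s_end = slen - so_hi, slen - so_lo
                bit = bit_score(raw_seg, ka)
                hsps.append(
                    AlignmentHSP(
                        query_id=query.id,
                        subject_id=subject.id,
                        q_start=q_lo,
                        q_end=q_hi,
                        s_start=s_start,
                        s_end=s_end,
                        strand=strand,
                        q_row=qseg,
                        s_row=sseg,
                        raw_score=raw_seg,
                        bit_score=bit,
                        evalue=evalue(bit, m, n),
                        s_len=slen,
                    )
                )
    hsps.sort(key=lambda h: (-h.raw_score, h.q_start))
    return hsps


def hsp_from_rows(
    query_id: str,
    subject_id: str,
    q_row: str,
    s_row: str,
    q_start: int = 0,
    s_start: int = 0,
    strand: str = "+",
    s_len: int | None = None,
    scoring: Scoring = Scoring(),
    ka: KarlinAltschul = KarlinAltschul(),
    m: int | None = None,
    n: int | None = None,
) -> AlignmentHSP:
    """Build an HSP directly from a gapped row pair (testing/constructed data)."""
    raw = _score_rows(q_row, s_row, scoring)
    q_len = sum(1 for c in q_row if c != "-")
    s_span = sum(1 for c in s_row if c != "-")
    if s_len is None:
        s_len = s_start + s_span
    bit = bit_score(raw, ka)
    mm = m if m is not None else q_len
    nn = n if n is not None else s_len
    if strand == "+":
        ss, se = s_start, s_start + s_span
    else:
        se = s_len - s_start
        ss = se - s_span
    return AlignmentHSP(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q_start,
        q_end=q_start + q_len,
        s_start=ss,
        s_end=se,
        strand=strand,
        q_row=q_row,
        s_row=s_row,
        raw_score=raw,
        bit_score=bit,
        evalue=evalue(bit, mm, nn),
        s_len=s_len,
    )


# ------------------------------------------------------------- match sets


def _best_chain(hsps: list[AlignmentHSP], max_overlap: int = 5) -> list[AlignmentHSP]:
    """Highest-scoring collinear chain of HSPs (increasing on both query
    and oriented subject coordinates, overlapping by at most a few nt).

    Repeated sequence produces extra local alignments that overlap a true
    HSP on the subject side; keeping only the best chain restores the
    one-junction-per-event topology the indel caller relies on. Ambiguous
    junction placement can duplicate a base or two between adjacent HSPs,
    hence the small overlap allowance.
    """
    if len(hsps) <= 1:
        return list(hsps)
    hs = sorted(hsps, key=lambda h: (h.q_start, h.oriented_s_start))
    n = len(hs)
    score = [h.bit_score for h in hs]
    prev = [-1] * n
    for j in range(n):
        oj = hs[j].oriented_s_start
        for i in range(j):
            oi_end = hs[i].oriented_s_start + (hs[i].s_end - hs[i].s_start)
            if (
                hs[i].q_end <= hs[j].q_start + max_overlap
                and oi_end <= oj + max_overlap
                and hs[i].q_start < hs[j].q_start
                and hs[i].oriented_s_start < oj
            ):
                cand = score[i] + hs[j].bit_score
                if cand > score[j]:
                    score[j] = cand
                    prev[j] = i
    j = max(range(n), key=lambda k: score[k])
    chain = []
    while j != -1:
        chain.append(hs[j])
        j = prev[j]
    return chain[::-1]


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for p in range(len(seq) - k + 1):
        km = seq[p : p + k]
        if "N" not in km:
            out.add(min(km, revcomp(km)))
    return out


def match_sets(
    A: Sequence,
    B: Sequence,
    filt: MatchFilter | None = None,
    scoring: Scoring = Scoring(),
    ka: KarlinAltschul = KarlinAltschul(),
    seed_k: int = 16,
    min_seed_hits: int = 1,
    prefilter: bool = True,
    split_gap: int = 23,
) -> tuple[list[MatchedPair], dict]:
    """Best-hit matching of query set A against subject set B.

    Items of A and B need ``id`` and ``seq`` attributes (unigenes or plain
    sequence records). Per query, the single best subject is kept (total
    bit score over qualifying HSPs; ties broken by higher identity, then
    lexicographically smaller subject id), with all qualifying HSPs on the
    pair's better strand. The coverage summary divides total matched
    alignment columns by the total length of the matched queries.
    """
    if not A or not B:
        raise ValueError("match_sets requires nonempty sets")
    filt = filt or MatchFilter()
    n_db = sum(len(s.seq) for s in B)

    index: dict[str, set[int]] = {}
    if prefilter:
        for j, subj in enumerate(B):
            for km in _canonical_kmers(subj.seq, seed_k):
                index.setdefault(km, set()).add(j)

    pairs: list[MatchedPair] = []
    total_cols = 0
    total_qlen = 0
    for query in A:
        if prefilter:
            counts: dict[int, int] = {}
            for km in _canonical_kmers(query.seq, seed_k):
                for j in index.get(km, ()):
                    counts[j] = counts.get(j, 0) + 1
            cand = [j for j, c in counts.items() if c >= min_seed_hits]
        else:
            cand = list(range(len(B)))
        m = len(query.seq)
        floor = min_raw_score(filt.max_evalue, m, n_db, ka)
        best_key = None
        best_pair = None
        for j in sorted(cand):
            subj = B[j]
            hsps = local_align(
                SequenceRecord(query.id, query.seq),
                SequenceRecord(subj.id, subj.seq),
                scoring=scoring,
                ka=ka,
                min_raw=floor,
                n_db=n_db,
                min_segment=max(10, filt.min_hsp_len),
                split_gap=split_gap,
            )
            qual = [
                h
                for h in hsps
                if h.n_columns >= filt.min_hsp_len
                and h.identity >= filt.min_identity
                and h.evalue <= filt.max_evalue
            ]
            if not qual:
                continue
            by_strand: dict[str, list[AlignmentHSP]] = {}
            for h in qual:
                by_strand.setdefault(h.strand, []).append(h)
            chains = {s: _best_chain(v) for s, v in by_strand.items()}
            strand = max(
                chains, key=lambda s: (sum(h.bit_score for h in chains[s]), s)
            )
            sel = sorted(chains[strand], key=lambda h: h.q_start)
            tot_bit = sum(h.bit_score for h in sel)
            tot_cols = sum(h.n_columns for h in sel)
            ident = sum(h.n_matches for h in sel) / tot_cols
            key = (tot_bit, ident, _NegStr(subj.id))
            if best_key is None or key > best_key:
                best_key = key
                best_pair = MatchedPair(
                    query_id=query.id,
                    subject_id=subj.id,
                    hsps=sel,
                    matched_columns=tot_cols,
                    strand=strand,
                    query_seq=query.seq,
                    subject_seq=subj.seq,
                )
        if best_pair is not None:
            pairs.append(best_pair)
            total_cols += best_pair.matched_columns
            total_qlen += len(best_pair.query_seq)

    summary = {
        "total_queries": len(A),
        "total_subjects": len(B),
        "matched_unigene_count": len(pairs),
        "matched_columns": total_cols,
        "matched_query_length": total_qlen,
        "coverage_pct": (100.0 * total_cols / total_qlen) if total_qlen else 0.0,
    }
    return pairs, summary


class _NegStr(str):
    """String whose ordering is reversed, for lexicographic-min tie-breaks."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def match_table(pairs: Iterable[MatchedPair]) -> pd.DataFrame:
    """Per-pair match table with 1-based inclusive coordinates."""
    rows = []
    for p in pairs:
        ident = sum(h.n_matches for h in p.hsps) / p.matched_columns
        rows.append(
            (
                p.query_id,
                p.subject_id,
                len(p.hsps),
                p.matched_columns,
                round(ident, 6),
                round(sum(h.bit_score for h in p.hsps), 3),
                min(h.evalue for h in p.hsps),
                p.strand,
                min(h.q_start for h in p.hsps) + 1,
                max(h.q_end for h in p.hsps),
                min(h.s_start for h in p.hsps) + 1,
                max(h.s_end for h in p.hsps),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "subject_id",
            "n_hsps",
            "matched_columns",
            "identity",
            "bit_score",
            "evalue",
            "strand",
            "q_start",
            "q_end",
            "s_start",
            "s_end",
        ],
    )
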