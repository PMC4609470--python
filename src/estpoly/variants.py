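"""Directional SNP and indel calling from matched unigene pairs.

Variants are called with the subject as the reference: a SNP pattern
"G->A" means the subject carries G and the query A; an insertion is
sequence present in the query and absent from the subject. Small indels
are maximal gap runs inside one HSP (one event per run, whatever its
length); large indels are events that split a matched pair into two
collinear HSPs, and are sized from the difference between the query-side
and subject-side gaps separating those HSPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .match import AlignmentHSP, MatchedPair
from .seqio import revcomp

TRANSITIONS = ({"A", "G"}, {"C", "T"})
PATTERNS = [
    "C->T", "T->C", "G->A", "A->G",  # transitions
    "A->T", "T->A", "C->G", "G->C", "G->T", "T->G", "A->C", "C->A",
]


def snp_class(subject_base: str, query_base: str) -> str:
    return "transition" if {subject_base, query_base} in TRANSITIONS else "transversion"


@dataclass(frozen=True)
class SNPRecord:
    query_id: str
    subject_id: str
    s_pos: int  # subject forward-strand coordinate, 0-based
    subject_base: str
    query_base: str
    pattern: str  # "X->Y", subject as reference
    cls: str  # transition | transversion


@dataclass(frozen=True)
class IndelRecord:
    query_id: str
    subject_id: str
    kind: str  # insertion | deletion (relative to subject)
    size_class: str  # small | large
    length: int
    s_pos: int  # subject forward coordinate of the 5' breakpoint
    seq: str  # inserted or deleted segment
    flank5: str  # up to 10 nt 5' of the event, from the continuous carrier
    flank3: str


def call_snps(pair: MatchedPair) -> list[SNPRecord]:
    """One record per aligned column where both rows differ, non-gap, non-N.

    Bases are reported in alignment orientation (query forward frame);
    subject coordinates are mapped back to the forward strand.
    """
    out: list[SNPRecord] = []
    for hsp in pair.hsps:
        s_pos = hsp.oriented_s_start
        for qc, sc in zip(hsp.q_row, hsp.s_row):
            if sc != "-":
                cur = s_pos
                s_pos += 1
            if qc == "-" or sc == "-" or qc == "N" or sc == "N":
                continue
            if qc != sc:
                out.append(
                    SNPRecord(
                        query_id=pair.query_id,
                        subject_id=pair.subject_id,
                        s_pos=hsp.subject_fwd_pos(cur),
                        subject_base=sc,
                        query_base=qc,
                        pattern=f"{sc}->{qc}",
                        cls=snp_class(sc, qc),
                    )
                )
    return out


def _flanks(seq: str, lo: int, hi: int, window: int = 10) -> tuple[str, str]:
    """Up to `window` nt either side of seq[lo:hi], truncated at the ends."""
    return seq[max(0, lo - window) : lo], seq[hi : hi + window]


def _oriented_query(pair: MatchedPair) -> str:
    return pair.query_seq


def _oriented_subject(pair: MatchedPair) -> str:
    return pair.subject_seq if pair.strand == "+" else revcomp(pair.subject_seq)


def call_small_indels(pair: MatchedPair, flank_window: int = 10) -> list[IndelRecord]:
    """One indel per maximal in-HSP gap run.

    A gap run in the subject row is an insertion (the query carries the
    segment); a run in the query row is a deletion. Flanks come from the
    gap-free sequence around the event — the full query for insertions,
    the full subject (in alignment orientation) for deletions — truncated
    at sequence ends.
    """
    out: list[IndelRecord] = []
    q_seq = _oriented_query(pair)
    s_seq = _oriented_subject(pair)
    s_len = len(pair.subject_seq)
    for hsp in pair.hsps:
        q_pos = hsp.q_start
        s_pos = hsp.oriented_s_start
        cols = list(zip(hsp.q_row, hsp.s_row))
        i = 0
        n = len(cols)
        while i < n:
            qc, sc = cols[i]
            if sc == "-":  # insertion run
                j = i
                while j < n and cols[j][1] == "-":
                    j += 1
                run = j - i
                lo = q_pos
                seg = q_seq[lo : lo + run]
                f5, f3 = _flanks(q_seq, lo, lo + run, flank_window)
                out.append(
                    IndelRecord(
                        pair.query_id, pair.subject_id, "insertion", "small",
                        run, _fwd_breakpoint(hsp, s_pos, s_len),
                        seg, f5, f3,
                    )
                )
                q_pos += run
                i = j
            elif qc == "-":  # deletion run
                j = i
                while j < n and cols[j][0] == "-":
                    j += 1
                run = j - i
                lo = s_pos
                seg = s_seq[lo : lo + run]
                f5, f3 = _flanks(s_seq, lo, lo + run, flank_window)
                out.append(
                    IndelRecord(
                        pair.query_id, pair.subject_id, "deletion", "small",
                        run, _fwd_breakpoint(hsp, s_pos, s_len),
                        seg, f5, f3,
                    )
                )
                s_pos += run
                i = j
            else:
                q_pos += 1
                s_pos += 1
                i += 1
    return out


def _fwd_breakpoint(hsp: AlignmentHSP, oriented_pos: int, s_len: int) -> int:
    """Forward-strand subject coordinate of an oriented breakpoint."""
    if hsp.strand == "+":
        return oriented_pos
    return s_len - oriented_pos


def detect_large_indels(
    pair: MatchedPair,
    slop: int = 5,
    min_large: int = 23,
    flank_window: int = 51,
) -> list[IndelRecord]:
    """Events that split a matched pair into two collinear HSPs.

    For each consecutive collinear HSP pair let gq and gs be the unaligned
    query- and subject-side gaps between them. If one side is (nearly)
    contiguous — min(gq, gs) ≤ slop — and the other side jumps by at least
    min_large, the event is one large indel of length max − min: an
    insertion when the query side jumps, a deletion otherwise. Flanks come
    from the sequence that retains continuity across the breakpoint (the
    subject for insertions, the query for deletions).
    """
    out: list[IndelRecord] = []
    hsps = sorted(pair.hsps, key=lambda h: h.q_start)
    q_seq = _oriented_query(pair)
    s_seq = _oriented_subject(pair)
    s_len = len(pair.subject_seq)
    for h1, h2 in zip(hsps, hsps[1:]):
        if h1.strand != h2.strand:
            continue
        gq = h2.q_start - h1.q_end
        o1_end = h1.oriented_s_start + (h1.s_end - h1.s_start)
        o2_start = h2.oriented_s_start
        gs = o2_start - o1_end
        # a slightly negative gap is junction raggedness, not non-collinearity
        if gq < -slop or gs < -slop:
            continue
        if min(gq, gs) > slop or max(gq, gs) < min_large:
            continue
        length = max(gq, gs) - min(gq, gs)
        # canonicalize on the downstream HSP start so flank5|segment|flank3
        # is exactly contiguous in the continuity-retaining sequence
        if gq > gs:
            kind = "insertion"
            seg = q_seq[h2.q_start - length : h2.q_start]
            f5 = s_seq[max(0, o2_start - flank_window) : o2_start]
            f3 = s_seq[o2_start : o2_start + flank_window]
            brk = o2_start
        else:
            kind = "deletion"
            seg = s_seq[o2_start - length : o2_start]
            f5 = q_seq[max(0, h2.q_start - flank_window) : h2.q_start]
            f3 = q_seq[h2.q_start : h2.q_start + flank_window]
            brk = o2_start - length
        out.append(
            IndelRecord(
                pair.query_id, pair.subject_id, kind, "large",
                length, _fwd_breakpoint(h1, brk, s_len), seg, f5, f3,
            )
        )
    return out


def call_variants(
    pairs: Sequence[MatchedPair],
    slop: int = 5,
    min_large: int = 23,
    flank_window: int = 10,
    large_flank: int = 51,
) -> tuple[list[SNPRecord], list[IndelRecord], list[IndelRecord]]:
    """SNPs, small indels and large indels over all matched pairs.

    Large-indel flanks are extracted to ``large_flank`` nt (long enough to
    expose the longest boundary-repeat motifs); profile statistics only
    ever read the innermost 10 positions.
    """
    snps: list[SNPRecord] = []
    small: list[IndelRecord] = []
    large: list[IndelRecord] = []
    for pair in pairs:
        snps.extend(call_snps(pair))
        small.extend(call_small_indels(pair, flank_window))
        large.extend(detect_large_indels(pair, slop, min_large, large_flank))
    return snps, small, large


def variant_table(
    snps: Iterable[SNPRecord], indels: Iterable[IndelRecord]
) -> pd.DataFrame:
    """Combined variant table (1-based subject coordinates)."""
    rows = []
    for v in snps:
        rows.append(
            (v.query_id, v.subject_id, v.s_pos + 1, "SNP", "", 1,
             v.subject_base, v.query_base, v.pattern, v.cls, "", "")
        )
    for d in indels:
        rows.append(
            (d.query_id, d.subject_id, d.s_pos + 1,
             "INS" if d.kind == "insertion" else "DEL",
             d.size_class, d.length,
             d.seq if d.kind == "deletion" else "-",
             d.seq if d.kind == "insertion" else "-",
             "", "", d.flank5, d.flank3)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "subject_id", "s_pos", "type", "size_class", "length",
            "ref", "alt", "pattern", "cls", "flank5", "flank3",
        ],
    )
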