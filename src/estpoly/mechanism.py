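"""Mechanistic classification of large indels.

Large indels fall into three disjoint groups mirroring how the breakpoint
neighbourhood looks: (1) boundary_repeat — the gained or lost segment
duplicates a motif abutting the breakpoint, the signature of replication
slippage; (2) modified_flanks — substitutions cluster right at the
breakpoint; (3) identical_flanks — the aligned flanks are clean. The
groups are checked in that order of precedence (most specific signal
first); events matching none are left unclassified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .match import MatchedPair
from .variants import IndelRecord


@dataclass
class IndelClass:
    indel: IndelRecord
    group: str  # identical_flanks | boundary_repeat | modified_flanks | unclassified
    motif: str = ""
    motif_len: int = 0
    n_flank_snps: int = 0


def find_boundary_repeat(
    indel: IndelRecord, max_motif: int = 51, jitter: int = 6
) -> tuple[str, int] | None:
    """Longest motif the indel segment shares with its abutting flank.

    A motif m (1 ≤ |m| ≤ max_motif) qualifies when the segment starts
    with m and the 5' flank ends with m, or the segment ends with m and
    the 3' flank begins with m — i.e. the event duplicates (or removes a
    copy of) its boundary. Because alignment places an ambiguous junction
    anywhere chance base matches allow, motifs of ≥ 6 nt are also
    accepted when the tandem junction sits within ``jitter`` nt of the
    reported breakpoint; shorter motifs must sit flush (a jittered search
    would find 3–5 nt "repeats" by chance too often). A homopolymer
    motif is reported at unit length 1, matching how single-base
    slippage runs are counted.
    """
    seq = indel.seq
    # the junction context is contiguous in the sequence carrying the event
    ctx = indel.flank5 + seq + indel.flank3
    a = len(indel.flank5)  # 5' breakpoint offset in ctx
    b = a + len(seq)  # 3' breakpoint offset
    top = min(max_motif, len(seq))
    for L in range(top, 0, -1):
        shifts = range(-jitter, jitter + 1) if L >= 6 else (0,)
        for brk in (a, b):
            for d in shifts:
                j = brk + d
                if j - L < 0 or j + L > len(ctx):
                    continue
                # the tandem must straddle the breakpoint: one copy reaches
                # into the flank, otherwise it is an internal repeat
                if brk == a and j - L >= a:
                    continue
                if brk == b and j + L <= b:
                    continue
                if ctx[j - L : j] == ctx[j : j + L]:
                    m = ctx[j : j + L]
                    if len(set(m)) == 1:
                        return m[0], 1
                    return m, L
    return None


def _flank_snp_count(pair: MatchedPair, indel: IndelRecord, window: int) -> tuple[int, bool]:
    """Mismatches within `window` columns of the breakpoint, and whether
    those windows are free of both mismatches and gaps."""
    hsps = sorted(pair.hsps, key=lambda h: h.q_start)
    # locate the consecutive HSP pair whose junction produced this indel
    h1 = h2 = None
    best = None
    for a, b in zip(hsps, hsps[1:]):
        o1_end = a.oriented_s_start + (a.s_end - a.s_start)
        brk = o1_end if a.strand == "+" else a.s_len - o1_end
        dist = abs(brk - indel.s_pos)
        if best is None or dist < best:
            best, h1, h2 = dist, a, b
    if h1 is None:
        h1 = h2 = hsps[0]
    cols = list(zip(h1.q_row, h1.s_row))[-window:]
    if h2 is not h1:
        cols += list(zip(h2.q_row, h2.s_row))[:window]
    n_snps = sum(
        1 for q, s in cols if q != "-" and s != "-" and q != s and "N" not in (q, s)
    )
    clean = all(q != "-" and s != "-" and (q == s or "N" in (q, s)) for q, s in cols)
    return n_snps, clean


def classify_indels(
    large_indels: Sequence[IndelRecord],
    pairs: Sequence[MatchedPair] | Mapping[tuple[str, str], MatchedPair],
    flank_window: int = 10,
    max_motif: int = 51,
) -> list[IndelClass]:
    """Assign each large indel to exactly one mechanistic group."""
    if not isinstance(pairs, Mapping):
        pair_map = {(p.query_id, p.subject_id): p for p in pairs}
    else:
        pair_map = dict(pairs)
    out: list[IndelClass] = []
    for indel in large_indels:
        pair = pair_map.get((indel.query_id, indel.subject_id))
        n_snps, clean = (
            _flank_snp_count(pair, indel, flank_window) if pair else (0, False)
        )
        hit = find_boundary_repeat(indel, max_motif)
        if hit is not None:
            motif, mlen = hit
            out.append(IndelClass(indel, "boundary_repeat", motif, mlen, n_snps))
        elif n_snps >= 1:
            out.append(IndelClass(indel, "modified_flanks", "", 0, n_snps))
        elif clean:
            out.append(IndelClass(indel, "identical_flanks", "", 0, 0))
        else:
            out.append(IndelClass(indel, "unclassified", "", 0, n_snps))
    return out


def classification_table(classes: Iterable[IndelClass]) -> pd.DataFrame:
    rows = [
        (
            c.indel.query_id,
            c.indel.subject_id,
            c.indel.s_pos + 1,
            c.indel.kind,
            c.indel.length,
            c.group,
            c.motif,
            c.motif_len,
            c.n_flank_snps,
        )
        for c in classes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "subject_id", "s_pos", "kind", "length",
            "group", "motif", "motif_len", "n_flank_snps",
        ],
    )


def group_counts(classes: Iterable[IndelClass]) -> dict:
    counts: dict[str, dict[str, int]] = {}
    for c in classes:
        g = counts.setdefault(c.group, {"insertion": 0, "deletion": 0})
        g[c.indel.kind] += 1
    return counts


def write_group_counts(classes: Sequence[IndelClass], path: str | Path) -> None:
    Path(path).write_text(json.dumps(group_counts(classes), indent=2) + "\n")
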