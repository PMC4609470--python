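"""Greedy overlap clustering of cleaned reads into unigenes.

Reads are clustered by single linkage under a qualifying-overlap relation
(end-to-end dovetail or containment overlap of at least ``min_overlap`` nt
at identity at least ``min_overlap_identity``, either orientation), and each
cluster of two or more members is collapsed to a majority-vote consensus
anchored on its longest member. This is a deliberately simple, fully
deterministic stand-in for a production OLC assembler: the two thresholds
are the assembly parameters that matter downstream, not base-level error
correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord, revcomp


@dataclass(frozen=True)
class ClusterConfig:
    min_overlap: int = 50
    min_overlap_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.min_overlap < 1 or not (0 < self.min_overlap_identity <= 1):
            raise ValueError("invalid ClusterConfig")


@dataclass(frozen=True)
class OverlapHit:
    """Best qualifying overlap of b (possibly reverse-complemented) on a.

    offset: start of the oriented b within a's forward coordinates
    (negative when b overhangs a's 5' end); orientation: strand of b
    relative to a.
    """

    length: int
    identity: float
    offset: int
    orientation: str  # "+" | "-"


@dataclass
class Unigene:
    id: str
    seq: str
    members: list[str]
    kind: str  # "contig" | "singleton"
    # (member_id, offset in consensus coords, strand) — singletons (id, 0, "+")
    layout: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_N = ord("N")


def _scan_offsets(a: np.ndarray, b: np.ndarray, cfg: ClusterConfig):
    """Yield (offset, length, identity) for every offset with enough overlap."""
    la, lb = len(a), len(b)
    for off in range(-(lb - cfg.min_overlap), la - cfg.min_overlap + 1):
        lo_a, hi_a = max(0, off), min(la, off + lb)
        length = hi_a - lo_a
        if length < cfg.min_overlap:
            continue
        wa = a[lo_a:hi_a]
        wb = b[lo_a - off : hi_a - off]
        matches = int(np.count_nonzero((wa == wb) & (wa != _N)))
        yield off, length, matches / length


def find_overlap(
    a: SequenceRecord, b: SequenceRecord, cfg: ClusterConfig | None = None
) -> OverlapHit | None:
    """Exhaustive offset scan for the best dovetail/containment overlap.

    Both orientations of ``b`` are considered; N matches nothing. Returns
    the highest-identity qualifying overlap (ties: longer overlap, then
    forward orientation, then smaller offset), or None.
    """
    cfg = cfg or ClusterConfig()
    arr_a = _seq_array(a.seq)
    best: tuple | None = None
    for orientation, bs in (("+", b.seq), ("-", revcomp(b.seq))):
        arr_b = _seq_array(bs)
        for off, length, ident in _scan_offsets(arr_a, arr_b, cfg):
            if ident < cfg.min_overlap_identity:
                continue
            key = (ident, length, orientation == "+", -off)
            if best is None or key > best[0]:
                best = (key, OverlapHit(length, ident, off, orientation))
    return None if best is None else best[1]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _kmer_candidates(records: Sequence[SequenceRecord], k: int) -> set[tuple[int, int]]:
    """Pairs of record indices sharing at least one canonical k-mer."""
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        seen = set()
        for p in range(len(rec.seq) - k + 1):
            km = rec.seq[p : p + k]
            if "N" in km:
                continue
            canon = min(km, revcomp(km))
            if canon not in seen:
                seen.add(canon)
                index.setdefault(canon, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for ids in index.values():
        if len(ids) < 2:
            continue
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                pairs.add((ids[x], ids[y]))
    return pairs


def _compose_strand(s1: str, s2: str) -> str:
    return "+" if s1 == s2 else "-"


def _member_frames(
    cluster: list[int],
    anchor: int,
    edges: dict[tuple[int, int], tuple[int, str]],
    lengths: dict[int, int],
) -> dict[int, tuple[int, str]]:
    """BFS offsets/strands of every member relative to the anchor."""
    adj: dict[int, list[int]] = {i: [] for i in cluster}
    for (i, j) in edges:
        if i in adj and j in adj:
            adj[i].append(j)
            adj[j].append(i)
    frames = {anchor: (0, "+")}
    queue = [anchor]
    while queue:
        i = queue.pop(0)
        o_i, s_i = frames[i]
        for j in sorted(adj[i]):
            if j in frames:
                continue
            if (i, j) in edges:
                off, orient = edges[(i, j)]
            else:
                # stored edge places oriented-i within j; invert it
                off, orient = edges[(j, i)]
                off, orient = _invert_edge(off, orient, lengths[j], lengths[i])
            if s_i == "+":
                o_j = o_i + off
            else:
                o_j = o_i + lengths[i] - off - lengths[j]
            frames[j] = (o_j, _compose_strand(s_i, orient))
            queue.append(j)
    return frames


def _invert_edge(off: int, orient: str, la: int, lb: int) -> tuple[int, str]:
    """Given b placed at `off` in a (orientation `orient`), place a in b."""
    if orient == "+":
        return -off, "+"
    return off + lb - la, "-"


def cluster_unigenes(
    records: Sequence[SequenceRecord],
    cfg: ClusterConfig | None = None,
    library: str | None = None,
    seed_k: int = 12,
) -> list[Unigene]:
    """Single-linkage overlap clustering with majority-vote consensus.

    Candidate pairs are restricted to those sharing a canonical ``seed_k``-mer
    (an exact-word prefilter; overlap verification itself is exhaustive).
    Deterministic given input order: consensus ties take the base of the
    longest member, then the lexicographically smallest base; unigene IDs
    are assigned in order of first member appearance.
    """
    cfg = cfg or ClusterConfig()
    n = len(records)
    lengths = {i: len(records[i].seq) for i in range(n)}
    uf = _UnionFind(n)
    edges: dict[tuple[int, int], tuple[int, str]] = {}
    for i, j in sorted(_kmer_candidates(records, seed_k)):
        hit = find_overlap(records[i], records[j], cfg)
        if hit is not None:
            uf.union(i, j)
            edges[(i, j)] = (hit.offset, hit.orientation)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)

    lib = library
    if lib is None:
        lib = records[0].source or "lib" if records else "lib"

    unigenes: list[Unigene] = []
    counter = 0
    # order clusters by first member appearance
    for root in sorted(clusters, key=lambda r: min(clusters[r])):
        members = clusters[root]
        counter += 1
        uid = f"{lib}_u{counter}"
        if len(members) == 1:
            rec = records[members[0]]
            unigenes.append(
                Unigene(uid, rec.seq, [rec.id], "singleton", [(rec.id, 0, "+")])
            )
            continue
        anchor = min(members, key=lambda i: (-lengths[i], records[i].id))
        frames = _member_frames(members, anchor, edges, lengths)
        shift = min(o for o, _ in frames.values())
        layout = {
            i: (frames[i][0] - shift, frames[i][1]) for i in members if i in frames
        }
        span = max(o + lengths[i] for i, (o, _) in layout.items())
        # majority vote per column
        order = sorted(layout, key=lambda i: (-lengths[i], records[i].id))
        oriented = {
            i: records[i].seq if layout[i][1] == "+" else revcomp(records[i].seq)
            for i in layout
        }
        consensus = []
        for col in range(span):
            votes: dict[str, int] = {}
            for i in order:
                o = layout[i][0]
                if o <= col < o + lengths[i]:
                    base = oriented[i][col - o]
                    if base != "N":
                        votes[base] = votes.get(base, 0) + 1
            if not votes:
                consensus.append("N")
                continue
            top = max(votes.values())
            tied = {b for b, c in votes.items() if c == top}
            if len(tied) == 1:
                consensus.append(tied.pop())
                continue
            choice = None
            for i in order:  # longest member covering the column breaks the tie
                o = layout[i][0]
                if o <= col < o + lengths[i] and oriented[i][col - o] in tied:
                    choice = oriented[i][col - o]
                    break
            consensus.append(choice if choice is not None else min(tied))
        member_ids = [records[i].id for i in sorted(members)]
        unigenes.append(
            Unigene(
                uid,
                "".join(consensus),
                member_ids,
                "contig",
                [(records[i].id, layout[i][0], layout[i][1]) for i in sorted(members)],
            )
        )
    return unigenes


def membership_table(unigenes: Iterable[Unigene]) -> pd.DataFrame:
    rows = [
        (u.id, mid, off, strand)
        for u in unigenes
        for (mid, off, strand) in u.layout
    ]
    return pd.DataFrame(rows, columns=["unigene_id", "member_id", "offset", "strand"])


def cluster_summary(unigenes: Sequence[Unigene], bin_width: int = 100) -> dict:
    lengths = [len(u) for u in unigenes]
    hist: dict[str, int] = {}
    for L in lengths:
        lo = (L // bin_width) * bin_width
        key = f"{lo}-{lo + bin_width - 1}"
        hist[key] = hist.get(key, 0) + 1
    return {
        "n_unigenes": len(unigenes),
        "n_contigs": sum(1 for u in unigenes if u.kind == "contig"),
        "n_singletons": sum(1 for u in unigenes if u.kind == "singleton"),
        "length_histogram": dict(sorted(hist.items(), key=lambda kv: int(kv[0].split("-")[0]))),
    }


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
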