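"""Synthetic divergence generator with exact ground truth.

An ancestral unigene set is drawn (lengths 700–1000 nt at ~54 % GC by
default) and two descendant libraries diverge from it: per-site
substitutions with a controlled transition/transversion balance, small
indels with a strongly 1-nt-dominated length distribution, and rarer
large indels (tens to hundreds of nt). A tunable fraction of indels is
slippage-like: the gained or lost segment duplicates a motif abutting the
breakpoint. Every event is recorded in a truth table with ancestral
coordinates, so recovery by the analysis pipeline can be scored exactly
and the descendants can be reconstructed from the ancestors (liftover
closure).

Rate conventions: ``sub_rate`` is per branch per site (the pairwise SNP
rate is ~2×); ``small_indel_rate`` (per site) and ``large_indel_rate``
(per sequence) are PAIRWISE rates — each event lands on one randomly
chosen branch — because the quantities the pipeline estimates are
pairwise. ``ins_del_odds`` is the probability an event reads as an
insertion in the query-vs-subject comparison (library A is the query).

RNG stream order per unigene (single seeded generator, byte-identical
reruns): ancestor length, ancestor bases, large events, small events,
per-event draws (direction, branch, mechanism, length/motif, position),
branch-A substitutions, branch-B substitutions, gain segments in
descending position order (A then B).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord

_BASES = np.array(list("ACGT"))
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": ("C", "T"), "C": ("A", "G"), "G": ("C", "T"), "T": ("A", "G")}

# Table-style small-indel length weights, dominated by 1-nt events
_SMALL_LEN_WEIGHTS = (1.319, 0.109, 0.076, 0.031, 0.010, 0.019, 0.004, 0.003, 0.005, 0.001)


@dataclass(frozen=True)
class SynthParams:
    n_unigenes: int = 500
    len_range: tuple[int, int] = (700, 1000)
    gc_target: float = 0.54
    sub_rate: float = 0.005665  # per branch; pairwise SNP rate ≈ 2×
    tstv_ratio: float = 1.45
    small_indel_rate: float = 0.00158  # pairwise, per site
    small_len_dist: tuple[float, ...] = _SMALL_LEN_WEIGHTS
    large_indel_rate: float = 0.07  # pairwise, expected events per sequence
    large_len_range: tuple[int, int] = (23, 574)
    ins_del_odds: float = 1331 / 2120
    small_odds_by_length: Mapping[int, float] | None = None
    repeat_fraction: float = 0.4
    motif_len_range: tuple[int, int] = (1, 51)
    reads_per_unigene: int = 0
    read_overlap: int = 100
    seed: int = 0
    end_margin: int = 60  # keep events clear of sequence ends
    event_spacing: int = 15  # min separation between planted events

    def __post_init__(self) -> None:
        for p in (self.gc_target, self.sub_rate, self.small_indel_rate,
                  self.ins_del_odds, self.repeat_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.len_range, self.large_len_range, self.motif_len_range):
            if lo > hi:
                raise ValueError("range bounds out of order")
        if self.len_range[0] < 2 * self.end_margin + 50:
            raise ValueError("sequences too short for any alignable core")
        if abs(sum(self.small_len_dist)) <= 0:
            raise ValueError("empty small_len_dist")


@dataclass
class TruthTable:
    """Ground truth: pairwise variants, ancestors, and per-branch edits."""

    variants: pd.DataFrame
    ancestors: list[str]
    edits: list[dict]  # per unigene: {"A": {"subs": [...], "indels": [...]}, "B": ...}

    def planted_counts(self) -> dict:
        v = self.variants
        small = v[(v.kind != "snp") & (v.size_class == "small")]
        large = v[(v.kind != "snp") & (v.size_class == "large")]
        return {
            "snps": int((v.kind == "snp").sum()),
            "transitions": int((v.cls == "transition").sum()),
            "transversions": int((v.cls == "transversion").sum()),
            "small_insertions": int((small.kind == "insertion").sum()),
            "small_deletions": int((small.kind == "deletion").sum()),
            "large_insertions": int((large.kind == "insertion").sum()),
            "large_deletions": int((large.kind == "deletion").sum()),
        }

    def planted_columns(self) -> int:
        """Expected matched alignment columns: ancestral sites, plus the
        extra columns small gains introduce, minus large-event spans
        (which fall between HSPs)."""
        total = sum(len(a) for a in self.ancestors)
        v = self.variants
        indels = v[v.kind != "snp"]
        small_gain = indels[(indels.size_class == "small") & (indels.op == "gain")]
        total += int(small_gain.length.sum())
        total -= int(indels[indels.size_class == "large"].length.sum())
        return total


@dataclass
class SimResult:
    library_a: list[SequenceRecord]
    library_b: list[SequenceRecord]
    truth: TruthTable
    reads_a: list[SequenceRecord] = field(default_factory=list)
    reads_b: list[SequenceRecord] = field(default_factory=list)


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=p)


def _substitute(
    rng: np.random.Generator, arr: np.ndarray, sub_rate: float, tstv_ratio: float
) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    out = arr.copy()
    mask = rng.random(len(arr)) < sub_rate
    idx = np.flatnonzero(mask)
    ts_p = tstv_ratio / (1.0 + tstv_ratio)
    is_ts = rng.random(len(idx)) < ts_p
    pick = rng.integers(0, 2, size=len(idx))
    subs = []
    for j, pos in enumerate(idx):
        old = str(arr[pos])
        new = _TS[old] if is_ts[j] else _TV[old][pick[j]]
        out[pos] = new
        subs.append((int(pos), old, new))
    return out, subs


def _draw_position(
    rng: np.random.Generator,
    L: int,
    need_left: int,
    length: int,
    blocked: list[tuple[int, int]],
    margin: int,
    spacing: int,
    tries: int = 50,
) -> int | None:
    lo = margin + need_left
    hi = L - margin - length
    if hi <= lo:
        return None
    for _ in range(tries):
        pos = int(rng.integers(lo, hi))
        a, b = pos - need_left - spacing, pos + length + spacing
        if all(b <= s or a >= e for s, e in blocked):
            blocked.append((a, b))
            return pos
    return None


def _apply_indels(
    seq: np.ndarray, indels: Sequence[tuple[str, int, int, str]]
) -> np.ndarray:
    """Apply (op, pos, length, segment) edits in descending position order."""
    s = seq
    for op, pos, length, seg in sorted(indels, key=lambda e: -e[1]):
        if op == "gain":
            s = np.concatenate([s[:pos], np.array(list(seg)), s[pos:]])
        else:
            s = np.concatenate([s[:pos], s[pos + length:]])
    return s


def apply_edits(ancestor: str, branch_edits: dict) -> str:
    """Replay one branch's recorded edits against its ancestor."""
    arr = np.array(list(ancestor))
    for pos, _old, new in branch_edits["subs"]:
        arr[pos] = new
    arr = _apply_indels(arr, branch_edits["indels"])
    return "".join(arr)


def _fragment(
    rec: SequenceRecord, n_reads: int, overlap: int
) -> list[SequenceRecord]:
    L = len(rec.seq)
    if n_reads <= 1 or L <= overlap:
        return [SequenceRecord(f"{rec.id}_r1", rec.seq, rec.source)]
    read_len = -(-(L + (n_reads - 1) * overlap) // n_reads)  # ceil
    reads = []
    for j in range(n_reads):
        start = round(j * (L - read_len) / (n_reads - 1)) if n_reads > 1 else 0
        start = max(0, min(start, L - read_len))
        reads.append(
            SequenceRecord(f"{rec.id}_r{j + 1}", rec.seq[start : start + read_len], rec.source)
        )
    return reads


def simulate_pair(p: SynthParams) -> SimResult:
    """Generate two diverged libraries plus the exact truth table."""
    rng = np.random.default_rng(p.seed)
    weights = np.asarray(p.small_len_dist, dtype=float)
    weights = weights / weights.sum()
    lib_a: list[SequenceRecord] = []
    lib_b: list[SequenceRecord] = []
    reads_a: list[SequenceRecord] = []
    reads_b: list[SequenceRecord] = []
    ancestors: list[str] = []
    edits: list[dict] = []
    rows: list[dict] = []

    for i in range(p.n_unigenes):
        qid, sid = f"A_u{i:04d}", f"B_u{i:04d}"
        L = int(rng.integers(p.len_range[0], p.len_range[1] + 1))
        anc = _rand_bases(rng, L, p.gc_target)

        # ---- draw indel events in ancestral coordinates
        events: list[dict] = []
        blocked: list[tuple[int, int]] = []
        n_large = int(rng.poisson(p.large_indel_rate))
        n_small = int(rng.binomial(L, p.small_indel_rate))
        for kind_class, count in (("large", n_large), ("small", n_small)):
            for _ in range(count):
                if kind_class == "small":
                    length = int(rng.choice(np.arange(1, len(weights) + 1), p=weights))
                else:
                    max_len = min(p.large_len_range[1], L - 2 * p.end_margin - 50)
                    if max_len < p.large_len_range[0]:
                        continue
                    length = int(rng.integers(p.large_len_range[0], max_len + 1))
                odds = p.ins_del_odds
                if kind_class == "small" and p.small_odds_by_length:
                    odds = p.small_odds_by_length.get(length, odds)
                pw_kind = "insertion" if rng.random() < odds else "deletion"
                branch = "A" if rng.random() < 0.5 else "B"
                slip = rng.random() < p.repeat_fraction
                if kind_class == "small":
                    mlen = length if slip else 0
                else:
                    mlen = (
                        int(rng.integers(p.motif_len_range[0],
                                         min(p.motif_len_range[1], length) + 1))
                        if slip
                        else 0
                    )
                pos = _draw_position(
                    rng, L, max(mlen, 1), length, blocked, p.end_margin, p.event_spacing
                )
                if pos is None:
                    continue
                op = "gain" if (pw_kind == "insertion") == (branch == "A") else "loss"
                events.append(
                    dict(pos=pos, length=length, pw_kind=pw_kind, branch=branch,
                         op=op, size_class=kind_class,
                         mechanism="slippage" if slip else "plain", motif_len=mlen)
                )

        # ---- slippage losses need the tandem copy present in the ancestor
        for ev in events:
            if ev["op"] == "loss" and ev["mechanism"] == "slippage":
                m = ev["motif_len"]
                pos = ev["pos"]
                anc[pos : pos + m] = anc[pos - m : pos]
        anc_str = "".join(anc)
        ancestors.append(anc_str)

        # ---- substitutions per branch
        arr_a, subs_a = _substitute(rng, anc, p.sub_rate, p.tstv_ratio)
        arr_b, subs_b = _substitute(rng, anc, p.sub_rate, p.tstv_ratio)

        # ---- pairwise SNP truth: compare substituted branches, drop sites
        # later removed by a loss event
        loss_iv = [
            (ev["pos"], ev["pos"] + ev["length"]) for ev in events if ev["op"] == "loss"
        ]
        diff = np.flatnonzero(arr_a != arr_b)
        for pos in diff:
            if any(s <= pos < e for s, e in loss_iv):
                continue
            qb, sb = str(arr_a[pos]), str(arr_b[pos])
            rows.append(
                dict(unigene=i, query_id=qid, subject_id=sid, kind="snp",
                     size_class="", length=1, anc_pos=int(pos),
                     pattern=f"{sb}->{qb}",
                     cls="transition" if {qb, sb} in ({"A", "G"}, {"C", "T"})
                     else "transversion",
                     mechanism="substitution", motif_len=0, op="", branch="")
            )

        # ---- indel segments and application
        indels_a: list[tuple[str, int, int, str]] = []
        indels_b: list[tuple[str, int, int, str]] = []
        for ev in sorted(events, key=lambda e: -e["pos"]):
            carrier = arr_a if ev["branch"] == "A" else arr_b
            pos, length = ev["pos"], ev["length"]
            if ev["op"] == "gain":
                if ev["mechanism"] == "slippage":
                    m = ev["motif_len"]
                    motif = "".join(carrier[pos - m : pos])
                    tail = "".join(_rand_bases(rng, length - m, p.gc_target))
                    seg = motif + tail
                else:
                    seg = "".join(_rand_bases(rng, length, p.gc_target))
                (indels_a if ev["branch"] == "A" else indels_b).append(
                    ("gain", pos, length, seg)
                )
            else:
                seg = "".join(carrier[pos : pos + length])
                (indels_a if ev["branch"] == "A" else indels_b).append(
                    ("loss", pos, length, seg)
                )
            rows.append(
                dict(unigene=i, query_id=qid, subject_id=sid, kind=ev["pw_kind"],
                     size_class=ev["size_class"], length=length, anc_pos=pos,
                     pattern="", cls="", mechanism=ev["mechanism"],
                     motif_len=ev["motif_len"], op=ev["op"], branch=ev["branch"])
            )

        seq_a = "".join(_apply_indels(arr_a, indels_a))
        seq_b = "".join(_apply_indels(arr_b, indels_b))
        lib_a.append(SequenceRecord(qid, seq_a, "A"))
        lib_b.append(SequenceRecord(sid, seq_b, "B"))
        edits.append(
            {
                "A": {"subs": subs_a, "indels": indels_a},
                "B": {"subs": subs_b, "indels": indels_b},
            }
        )
        if p.reads_per_unigene > 0:
            reads_a.extend(_fragment(lib_a[-1], p.reads_per_unigene, p.read_overlap))
            reads_b.extend(_fragment(lib_b[-1], p.reads_per_unigene, p.read_overlap))

    columns = ["unigene", "query_id", "subject_id", "kind", "size_class", "length",
               "anc_pos", "pattern", "cls", "mechanism", "motif_len", "op", "branch"]
    variants = pd.DataFrame(rows, columns=columns)
    truth = TruthTable(variants=variants, ancestors=ancestors, edits=edits)
    return SimResult(lib_a, lib_b, truth, reads_a, reads_b)


# ---------------------------------------------------------------- recovery


def recovery_report(
    params: SynthParams,
    truth: TruthTable,
    result,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Planted vs. estimated rates for a pipeline run on simulated data.

    ``result`` is a pipeline result exposing ``summary``
    (PolymorphismSummary) and ``classes`` (large-indel classifications).
    Planted values are the REALIZED truth-table counts scaled by the
    planted column total, so the report isolates pipeline detection error
    from sampling noise. The boundary-repeat row is restricted to large
    indels with motifs ≥ 3 nt, below which chance boundary matches
    dominate.
    """
    planted = truth.planted_counts()
    cols_p = truth.planted_columns()
    s = result.summary
    kb_p = 1000.0 / cols_p
    kb_e = 1000.0 / s.matched_length

    rows = []

    def add(name: str, plant: float, est: float) -> None:
        if plant == 0:
            rel = 0.0 if est == 0 else float("inf")
        else:
            rel = abs(est - plant) / plant
        rows.append((name, plant, est, rel, rel <= tolerance))

    add("snp_per_kb", planted["snps"] * kb_p, s.freq_per_kb["snp"])
    add("transition_per_kb", planted["transitions"] * kb_p, s.freq_per_kb["transition"])
    add("transversion_per_kb", planted["transversions"] * kb_p,
        s.freq_per_kb["transversion"])
    add("insertion_per_kb", planted["small_insertions"] * kb_p,
        s.indel_freq_per_kb["insertion"])
    add("deletion_per_kb", planted["small_deletions"] * kb_p,
        s.indel_freq_per_kb["deletion"])
    add("indel_per_kb",
        (planted["small_insertions"] + planted["small_deletions"]) * kb_p,
        s.indel_freq_per_kb["indel"])
    if planted["small_deletions"] > 0 and s.small_deletions > 0:
        add("ins_del_ratio",
            planted["small_insertions"] / planted["small_deletions"],
            s.small_insertions / s.small_deletions)
    v = truth.variants
    large = v[(v.kind != "snp") & (v.size_class == "large")]
    classes = getattr(result, "classes", None)
    if len(large) > 0 and classes:
        plant_frac = float(((large.mechanism == "slippage") & (large.motif_len >= 3)).mean())
        est_frac = sum(
            1 for c in classes if c.group == "boundary_repeat" and c.motif_len >= 3
        ) / len(classes)
        add("boundary_repeat_fraction", plant_frac, est_frac)
    return pd.DataFrame(
        rows, columns=["parameter", "planted", "estimated", "rel_error", "passed"]
    )


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.variants.to_csv(path, sep="\t", index=False)


def write_params(params: SynthParams, path: str | Path) -> None:
    d = asdict(params)
    d["small_odds_by_length"] = (
        dict(params.small_odds_by_length) if params.small_odds_by_length else None
    )
    Path(path).write_text(json.dumps(d, indent=2, default=list) + "\n")
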