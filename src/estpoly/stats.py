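"""Polymorphism summary statistics.

Frequencies are reported per 1000 nt of matched sequence, where the
denominator is the total number of alignment columns of qualifying HSPs
summed over best-hit pairs (gap columns included — the same denominator
the identity filter uses). Only small indels enter the per-kb indel
frequencies; large indels feed the size/ratio spectra and the mechanistic
classification instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .match import MatchedPair
from .variants import IndelRecord, PATTERNS, SNPRecord


@dataclass
class PolymorphismSummary:
    matched_length: int
    snp_total: int
    transitions: int
    transversions: int
    per_pattern: dict[str, int]
    freq_per_kb: dict[str, float]
    small_insertions: int
    small_deletions: int
    indel_freq_per_kb: dict[str, float]
    per_length_indels: dict[int, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "matched_length": self.matched_length,
            "snp_total": self.snp_total,
            "transitions": self.transitions,
            "transversions": self.transversions,
            "per_pattern": self.per_pattern,
            "freq_per_kb": self.freq_per_kb,
            "small_insertions": self.small_insertions,
            "small_deletions": self.small_deletions,
            "indel_freq_per_kb": self.indel_freq_per_kb,
            "per_length_indels": {
                str(k): v for k, v in self.per_length_indels.items()
            },
        }


def summarize(
    pairs: Sequence[MatchedPair],
    variants: Iterable[SNPRecord | IndelRecord],
) -> PolymorphismSummary:
    """Counts and per-1000-nt frequencies over the matched regions."""
    matched_length = sum(p.matched_columns for p in pairs)
    if matched_length == 0:
        raise ValueError("summarize with zero matched length")
    per_pattern = {p: 0 for p in PATTERNS}
    ti = tv = 0
    small_ins = small_del = 0
    per_length: dict[int, dict[str, int]] = {
        L: {"ins": 0, "del": 0} for L in range(1, 11)
    }
    for v in variants:
        if isinstance(v, SNPRecord):
            per_pattern[v.pattern] += 1
            if v.cls == "transition":
                ti += 1
            else:
                tv += 1
        elif v.size_class == "small":
            if v.kind == "insertion":
                small_ins += 1
            else:
                small_del += 1
            if v.length in per_length:
                per_length[v.length]["ins" if v.kind == "insertion" else "del"] += 1
    snp_total = ti + tv
    kb = 1000.0 / matched_length
    freq = {"snp": snp_total * kb, "transition": ti * kb, "transversion": tv * kb}
    freq.update({p: c * kb for p, c in per_pattern.items()})
    indel_freq = {
        "insertion": small_ins * kb,
        "deletion": small_del * kb,
        "indel": (small_ins + small_del) * kb,
    }
    return PolymorphismSummary(
        matched_length=matched_length,
        snp_total=snp_total,
        transitions=ti,
        transversions=tv,
        per_pattern=per_pattern,
        freq_per_kb=freq,
        small_insertions=small_ins,
        small_deletions=small_del,
        indel_freq_per_kb=indel_freq,
        per_length_indels=per_length,
    )


@dataclass
class RatioSpectrum:
    """Insertion/deletion counts and ratio per length bin.

    bins rows: (label, representative length, n_ins, n_del, ratio|None);
    the ratio is undefined (None) where n_del = 0 and such bins are
    excluded from the correlation. `degenerate` flags a zero-variance
    ratio vector, for which r² is reported as 0.
    """

    bins: list[tuple[str, float, int, int, float | None]]
    pearson_r2: float | None
    direction: int  # sign of the correlation; 0 when undefined
    degenerate: bool = False


DEFAULT_LARGE_BINS: tuple[tuple[int, int | None], ...] = (
    (23, 70),
    (71, 200),
    (201, None),
)


def _spectrum(
    lengths_ins: Sequence[int],
    lengths_del: Sequence[int],
    bins: Sequence[tuple[int, int | None]],
    labels: Sequence[str],
) -> RatioSpectrum:
    rows: list[tuple[str, float, int, int, float | None]] = []
    xs, ys = [], []
    for (lo, hi), label in zip(bins, labels):
        sel_i = [L for L in lengths_ins if L >= lo and (hi is None or L <= hi)]
        sel_d = [L for L in lengths_del if L >= lo and (hi is None or L <= hi)]
        n_i, n_d = len(sel_i), len(sel_d)
        ratio = (n_i / n_d) if n_d > 0 else None
        observed = sel_i + sel_d
        rep = float(np.mean(observed)) if observed else (lo + hi) / 2.0 if hi else float(lo)
        rows.append((label, rep, n_i, n_d, ratio))
        if ratio is not None:
            xs.append(rep)
            ys.append(ratio)
    if len(xs) < 3:
        return RatioSpectrum(rows, None, 0)
    if np.std(ys) == 0 or np.std(xs) == 0:
        return RatioSpectrum(rows, 0.0, 0, degenerate=True)
    r, _ = sps.pearsonr(xs, ys)
    return RatioSpectrum(rows, float(r * r), int(np.sign(r)))


def ratio_spectrum(
    indels: Iterable[IndelRecord],
    small_bins: Sequence[int] = tuple(range(1, 11)),
    large_bins: Sequence[tuple[int, int | None]] = DEFAULT_LARGE_BINS,
) -> tuple[RatioSpectrum, RatioSpectrum]:
    """Size spectra for small and large indels.

    The correlation relates each bin's representative length (the exact
    length for small bins; the mean observed event length for large bins)
    to its insertion/deletion count ratio, over bins where the ratio is
    defined.
    """
    ins_small, del_small, ins_large, del_large = [], [], [], []
    for v in indels:
        if v.size_class == "small":
            (ins_small if v.kind == "insertion" else del_small).append(v.length)
        else:
            (ins_large if v.kind == "insertion" else del_large).append(v.length)
    small = _spectrum(
        ins_small,
        del_small,
        [(L, L) for L in small_bins],
        [str(L) for L in small_bins],
    )
    large = _spectrum(
        ins_large,
        del_large,
        list(large_bins),
        [f"{lo}-{hi}" if hi else f">{lo - 1}" for lo, hi in large_bins],
    )
    return small, large


@dataclass
class FlankProfile:
    """GC fraction at each of the ten positions either side of an indel.

    positions: −10..−1 (5' flank, −1 abutting the event) and 1..10
    (3' flank). Each maps to GC fractions for insertions, deletions and
    all indels (count-weighted); `means` holds per-category whole-flank
    mean GC.
    """

    positions: dict[int, dict[str, float]]
    means: dict[str, float]


def flank_profile(indels: Iterable[IndelRecord]) -> FlankProfile:
    gc = {k: {c: 0 for c in ("insertion", "deletion")} for k in range(-10, 11) if k != 0}
    tot = {k: {c: 0 for c in ("insertion", "deletion")} for k in range(-10, 11) if k != 0}
    for v in indels:
        # flank5: last character sits at position −1
        for i, base in enumerate(reversed(v.flank5)):
            k = -(i + 1)
            if k < -10 or base == "N":
                continue
            tot[k][v.kind] += 1
            if base in "GC":
                gc[k][v.kind] += 1
        for i, base in enumerate(v.flank3):
            k = i + 1
            if k > 10 or base == "N":
                continue
            tot[k][v.kind] += 1
            if base in "GC":
                gc[k][v.kind] += 1
    positions: dict[int, dict[str, float]] = {}
    for k in gc:
        row: dict[str, float] = {}
        for cat in ("insertion", "deletion"):
            row[cat] = gc[k][cat] / tot[k][cat] if tot[k][cat] else float("nan")
        n_all = tot[k]["insertion"] + tot[k]["deletion"]
        row["all"] = (
            (gc[k]["insertion"] + gc[k]["deletion"]) / n_all if n_all else float("nan")
        )
        positions[k] = row
    means: dict[str, float] = {}
    for cat in ("insertion", "deletion"):
        g = sum(gc[k][cat] for k in gc)
        t = sum(tot[k][cat] for k in tot)
        means[cat] = g / t if t else float("nan")
    g_all = sum(gc[k][c] for k in gc for c in ("insertion", "deletion"))
    t_all = sum(tot[k][c] for k in tot for c in ("insertion", "deletion"))
    means["all"] = g_all / t_all if t_all else float("nan")
    return FlankProfile(positions=positions, means=means)


def functional_bins(
    variants: Sequence[SNPRecord | IndelRecord],
    pairs: Sequence[MatchedPair],
    category_map: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-functional-category polymorphism frequencies.

    ``category_map`` maps query unigene IDs to one or more categories (a
    unigene carrying several categories is counted in each). Categories
    with no matched unigenes are emitted with zero matched length and
    flagged, not dropped.
    """
    if isinstance(category_map, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for uid, cat in category_map.itertuples(index=False):
            mapping.setdefault(str(uid), []).append(str(cat))
    else:
        mapping = {k: list(v) for k, v in category_map.items()}
    categories = sorted({c for cats in mapping.values() for c in cats})
    rows = []
    for cat in categories:
        uids = {u for u, cats in mapping.items() if cat in cats}
        sub_pairs = [p for p in pairs if p.query_id in uids]
        sub_vars = [v for v in variants if v.query_id in uids]
        matched = sum(p.matched_columns for p in sub_pairs)
        if matched == 0:
            rows.append((cat, 0, 0, 0.0, 0.0, 0.0, 0, 0.0, True))
            continue
        s = summarize(sub_pairs, sub_vars)
        rows.append(
            (
                cat,
                len(sub_pairs),
                s.snp_total,
                s.freq_per_kb["snp"],
                s.freq_per_kb["transition"],
                s.freq_per_kb["transversion"],
                s.small_insertions + s.small_deletions,
                s.indel_freq_per_kb["indel"],
                False,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category", "n_unigenes", "n_snps", "snp_per_kb",
            "transition_per_kb", "transversion_per_kb",
            "n_small_indels", "indel_per_kb", "zero_matched",
        ],
    )


# ------------------------------------------------------------- reporting


def summary_tables(summary: PolymorphismSummary) -> dict[str, pd.DataFrame]:
    """SNP-pattern and indel-length tables mirroring the report layout."""
    snp_rows = [
        ("transition" if {p[0], p[3]} in ({"A", "G"}, {"C", "T"}) else "transversion",
         p, summary.per_pattern[p], summary.freq_per_kb[p])
        for p in PATTERNS
    ]
    snp = pd.DataFrame(snp_rows, columns=["class", "pattern", "count", "per_kb"])
    kb = 1000.0 / summary.matched_length
    indel_rows = [
        (L, d["ins"], d["del"], (d["ins"] + d["del"]) * kb)
        for L, d in sorted(summary.per_length_indels.items())
    ]
    indel = pd.DataFrame(
        indel_rows, columns=["length", "insertions", "deletions", "per_kb"]
    )
    return {"snp_patterns": snp, "small_indel_lengths": indel}


def write_summary_json(summary: PolymorphismSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def plot_flank_profile(profile: FlankProfile, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = sorted(profile.positions)
    fig, ax = plt.subplots(figsize=(7, 4))
    for cat, marker in (("insertion", "o"), ("deletion", "s"), ("all", "^")):
        ax.plot(ks, [100 * profile.positions[k][cat] for k in ks], marker=marker, label=cat)
    ax.set_xlabel("position relative to indel (nt)")
    ax.set_ylabel("GC content (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ratio_spectrum(spectrum: RatioSpectrum, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [rep for (_, rep, _, _, r) in spectrum.bins if r is not None]
    ys = [r for (_, _, _, _, r) in spectrum.bins if r is not None]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, ys, "o-")
    ax.set_xlabel("indel length (nt)")
    ax.set_ylabel("insertion / deletion ratio")
    if spectrum.pearson_r2 is not None:
        ax.set_title(f"$R^2$ = {spectrum.pearson_r2:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
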