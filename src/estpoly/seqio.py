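"""FASTA I/O, sequence cleaning and base-composition summaries.

Single-pass cDNA reads are trimmed to a fixed-length 5' prefix (the
high-quality part of a Sanger read), short reads are discarded, and base
composition is summarised both pooled over a library and per record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALLOWED = frozenset("ACGTN")
# IUPAC ambiguity codes collapse to N; anything else is illegal.
_AMBIGUITY = frozenset("RYSWKMBDHVN")
_NORMALIZE = str.maketrans({c: "N" for c in _AMBIGUITY - {"N"}})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DataError(ValueError):
    """A malformed or inconsistent input record."""


def normalize_seq(seq: str, context: str = "") -> str:
    """Uppercase, map IUPAC ambiguity codes to N, reject anything else."""
    s = seq.upper().translate(_NORMALIZE)
    bad = set(s) - ALLOWED
    if bad:
        where = f" in {context}" if context else ""
        raise DataError(f"illegal character(s) {sorted(bad)}{where}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (an EST read or a unigene)."""

    id: str
    seq: str
    source: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CleaningConfig:
    """Read-cleaning thresholds.

    max_prefix_len: keep only this many nt from the reading start.
    min_len: reads shorter than this (after trimming) are dropped;
        length exactly min_len is kept.
    adapters: sequences stripped repeatedly from either end.
    """

    max_prefix_len: int = 800
    min_len: int = 100
    adapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.max_prefix_len > self.min_len > 0):
            raise ValueError("require max_prefix_len > min_len > 0")


def read_fasta(path: str | Path, source: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving order.

    Raises DataError for an empty sequence, a duplicate ID, or illegal
    characters, naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DataError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq)
        if not seq:
            raise DataError(f"empty sequence for FASTA id {entry.id!r} in {path}")
        records.append(
            SequenceRecord(id=entry.id, seq=normalize_seq(seq, entry.id), source=source)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = (
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _strip_adapters(seq: str, adapters: Sequence[str]) -> str:
    changed = True
    while changed:
        changed = False
        for ad in adapters:
            if ad and seq.startswith(ad):
                seq = seq[len(ad):]
                changed = True
            if ad and seq.endswith(ad):
                seq = seq[: len(seq) - len(ad)]
                changed = True
    return seq


def clean_sequences(
    records: Sequence[SequenceRecord], cfg: CleaningConfig | None = None
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Adapter-strip, prefix-trim and length-filter reads.

    Returns the kept records (input order preserved) and a per-record
    disposition report with columns id, input_len, kept_len, disposition,
    reason. Cleaning never fails; it drops and reports.
    """
    cfg = cfg or CleaningConfig()
    kept: list[SequenceRecord] = []
    rows = []
    for rec in records:
        seq = _strip_adapters(rec.seq, cfg.adapters)
        seq = seq[: cfg.max_prefix_len]
        if len(seq) < cfg.min_len:
            rows.append((rec.id, len(rec.seq), 0, "dropped", "below min_len"))
            continue
        reason = ""
        if len(seq) != len(rec.seq):
            reason = "trimmed"
        kept.append(SequenceRecord(id=rec.id, seq=seq, source=rec.source))
        rows.append((rec.id, len(rec.seq), len(seq), "kept", reason))
    report = pd.DataFrame(
        rows, columns=["id", "input_len", "kept_len", "disposition", "reason"]
    )
    return kept, report


def gc_content(records: Sequence[SequenceRecord]) -> tuple[float, np.ndarray]:
    """GC fraction of a library.

    Returns ``(pooled, per_record)``: the length-weighted pooled fraction
    (total G+C over total A+C+G+T, N excluded everywhere) and a per-record
    vector (NaN for an all-N record). A library whose records contain no
    unambiguous base at all is an error.
    """
    if not records:
        raise ValueError("gc_content of empty input")
    gc = np.zeros(len(records))
    acgt = np.zeros(len(records))
    for i, rec in enumerate(records):
        gc[i] = rec.seq.count("G") + rec.seq.count("C")
        acgt[i] = gc[i] + rec.seq.count("A") + rec.seq.count("T")
    if acgt.sum() == 0:
        raise ValueError("no unambiguous bases in input")
    with np.errstate(invalid="ignore"):
        per_record = np.where(acgt > 0, gc / np.where(acgt > 0, acgt, 1), np.nan)
    return float(gc.sum() / acgt.sum()), per_record


def write_cleaning_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
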