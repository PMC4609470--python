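"""End-to-end chaining of the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .match import MatchedPair, MatchFilter, Scoring, match_sets
from .mechanism import IndelClass, classify_indels
from .seqio import SequenceRecord
from .stats import (
    FlankProfile,
    PolymorphismSummary,
    RatioSpectrum,
    flank_profile,
    ratio_spectrum,
    summarize,
)
from .variants import IndelRecord, SNPRecord, call_variants


@dataclass
class PipelineResult:
    pairs: list[MatchedPair]
    coverage: dict
    snps: list[SNPRecord]
    small_indels: list[IndelRecord]
    large_indels: list[IndelRecord]
    summary: PolymorphismSummary
    small_spectrum: RatioSpectrum
    large_spectrum: RatioSpectrum
    flanks: FlankProfile
    classes: list[IndelClass] = field(default_factory=list)


def run_pipeline(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    filt: MatchFilter | None = None,
    scoring: Scoring = Scoring(),
    slop: int = 5,
    min_large: int = 23,
    flank_window: int = 10,
    prefilter: bool = True,
) -> PipelineResult:
    """Match two unigene sets, call variants, and compute all statistics."""
    filt = filt or MatchFilter()
    pairs, coverage = match_sets(
        queries, subjects, filt, scoring=scoring, prefilter=prefilter,
        split_gap=min_large,
    )
    snps, small, large = call_variants(
        pairs, slop=slop, min_large=min_large, flank_window=flank_window
    )
    summary = summarize(pairs, [*snps, *small])
    sm_spec, lg_spec = ratio_spectrum([*small, *large])
    flanks = flank_profile(small + large)
    classes = classify_indels(large, pairs, flank_window=flank_window)
    return PipelineResult(
        pairs=pairs,
        coverage=coverage,
        snps=snps,
        small_indels=small,
        large_indels=large,
        summary=summary,
        small_spectrum=sm_spec,
        large_spectrum=lg_spec,
        flanks=flanks,
        classes=classes,
    )
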