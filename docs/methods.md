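# Methods

This note documents the model behind each stage of the pipeline, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Problem setting

Two cDNA/EST libraries are compared to quantify the sequence divergence
between the transcriptomes they sample — the typical use case being a
derived line against its parent, where the divergence measures mutations
induced by a genomic shock such as asymmetric somatic hybridization. All
quantities are *pairwise and directional*: one library is the query, the
other is the subject/reference, and a substitution is written
subject→query (`G->A` = subject G, query A), an insertion is sequence the
query gained, a deletion sequence the query lost.

## Cleaning and clustering

Single-pass Sanger reads are reliable only near the 5' end, so cleaning
keeps at most the first 800 nt (`max_prefix_len`) and discards reads
shorter than 100 nt (`min_len`; a read of exactly 100 nt is kept — the
threshold is "shorter than"). Ambiguity codes collapse to N; N never
counts as a match, a G/C, or a substitution.

Clustering into unigenes uses single-linkage under a qualifying-overlap
relation: the best end-to-end (dovetail or containment) overlap of
≥ 50 nt at ≥ 95 % identity, with the reverse complement of the second
read also considered. Overlap search is an exhaustive offset scan —
every relative placement of the two reads is scored — so the reported
overlap is exact, not heuristic; a canonical 12-mer prefilter only
decides *which pairs* are scanned. Consensus is majority vote per column
over members laid out relative to the longest member (re-oriented to its
strand); ties take the base of the longest covering member, then the
lexicographically smallest base, making the output deterministic under
input shuffling. This is deliberately a minimal assembler: no error
correction, no scaffolding. It reconstructs error-free tilings exactly
(tested), which is all the downstream statistics need from it.

## Matching

Each query unigene is aligned against subject candidates by local
Smith–Waterman with affine gaps, scores +1 match, −2 mismatch, and gap
cost 5 + 2·L for a gap of L nt — the classic nucleotide-BLAST scoring.
The engine runs on Bio.Align.PairwiseAligner (C implementation); its
optimal scores are verified in the tests against an independently written
exhaustive dynamic-programming oracle.

Three behaviours of seeded aligners that the statistics depend on are
reproduced explicitly on top of the optimal alignment:

* **Suboptimal HSPs** are recovered by recursively re-aligning the query
  segments left and right of each reported HSP.
* **Large-gap splitting.** A truly optimal alignment will bridge even a
  multi-hundred-nt gap whenever the flanking matches pay for it, whereas
  extension in seeded aligners terminates there and two HSPs result —
  and the small/large indel dichotomy is *defined* on that topology.
  Alignments are therefore split at internal gap runs of ≥ `split_gap`
  columns (default 23, the large-indel threshold).
* **Chaining.** Duplicated sequence (e.g. the two copies of a
  slippage motif) produces extra local alignments overlapping a true HSP
  on the subject side. Per query/subject pair, only the highest-scoring
  collinear chain of HSPs is kept (weighted chaining DP, allowing ≤ 5 nt
  of junction overlap, since ambiguous junction placement can duplicate
  a base or two between adjacent HSPs).

E-values use the Karlin–Altschul form E = m·n·K·e^(−λS) with the
published ungapped constants for +1/−2 scoring (λ = 1.33, K = 0.621),
m the query length and n the total subject-set length. The filter's
*behaviour* (E ≤ 10⁻¹⁰, identity ≥ 0.96 with gap columns in the
denominator, HSP length ≥ 33 columns) is the contract; exact equality
with any particular BLAST build's E-values is not claimed. One best
subject per query is kept (total bit score, ties by identity then
lexicographic subject id) — secondary hits are discarded precisely to
keep paralogs out of the divergence estimate.

A canonical 16-mer prefilter selects alignment candidates. At the
≤ 4 % divergence the identity filter admits, homologs share hundreds of
exact 16-mers while unrelated ~850-nt pairs share essentially none, so
the prefilter changes nothing but runtime; it can be disabled
(`prefilter=False`) for exhaustive all-vs-all alignment.

## Variant calling

* **SNPs**: one record per aligned column with two differing, non-gap,
  non-N bases, classified transition ({A,G} or {C,T}) vs. transversion,
  into the 12 directional patterns.
* **Small indels**: each *maximal* run of gap columns inside an HSP is
  one event of length = run length (so Table-style per-length counts are
  well defined); gap in the subject row = insertion, in the query row =
  deletion. Flanks (10 nt) come from the sequence that carries the
  segment contiguously.
* **Large indels**: for each consecutive collinear HSP pair, with gq and
  gs the query- and subject-side gaps between them, an event is called
  when min(gq,gs) ≤ `slop` (5 nt of junction raggedness; slightly
  negative gaps are tolerated the same way) and max(gq,gs) ≥ `min_large`
  (23 nt). Length = max − min; query jump = insertion. Coordinates,
  segment and flanks are all derived from the downstream HSP start, so
  flank5|segment|flank3 is exactly contiguous in the
  continuity-retaining sequence (the subject for insertions, the query
  for deletions). Large-indel flanks are extracted to 51 nt — long
  enough to expose the longest boundary motifs — while profile
  statistics read only the innermost 10 positions.

In-alignment gap runs of 11–22 nt are labelled small: size class is
decided purely by alignment topology, with the split threshold at 23 nt.

## Statistics

The frequency denominator is the total number of alignment columns of
qualifying HSPs over best-hit pairs, gap columns included — the same
denominator the identity filter uses, making the two self-consistent.
Only small indels enter the per-kb indel frequencies; large indels feed
the spectra and classification. The insertion:deletion ratio spectrum
uses per-length bins 1–10 nt for small indels and 23–70 / 71–200 /
> 200 nt for large ones; the Pearson correlation relates each bin's
representative length (the exact length for small bins, the mean
observed event length for large bins, since the top bin is open-ended)
to its ratio over bins with ≥ 1 deletion, on the raw scale (no log
transform). Fewer than three defined bins → correlation undefined; a
zero-variance ratio vector → r² reported as 0 with a `degenerate` flag.
Flanking GC is tallied per position −10…−1 and 1…10 with truncated
flanks contributing only to the positions they cover. Functional binning
re-runs the summary on each category's unigenes (a unigene in several
categories counts in each; empty categories are flagged, not errors).

## Mechanistic classification of large indels

Groups, in precedence order: **boundary_repeat** — the junction context
(flank5 + segment + flank3) contains a tandem duplication of a 1–51 nt
motif straddling a breakpoint; **modified_flanks** — ≥ 1 substitution
within 10 alignment columns of the junction; **identical_flanks** —
those windows are free of mismatches and gaps; otherwise unclassified.
Repeats are the most specific signal, hence checked first.

Two numerical choices matter. (1) Alignment places an ambiguous junction
wherever chance base matches allow, so motifs of ≥ 6 nt are also
accepted when the tandem junction lies within ± 6 nt of the reported
breakpoint (shorter motifs must sit flush; a jittered search for 3–5 nt
words would fire by chance too often), and one copy must reach into the
flank — a tandem entirely inside the segment is an internal repeat, not
a boundary signature. (2) A homopolymer motif is reported at unit
length 1, matching how single-base slippage runs are conventionally
counted. Note that with 1-nt motifs admitted, roughly half of all
*random* junctions carry a "repeat" — that is a property of the
definition, not a bug; analyses that need a conservative slippage signal
should restrict to motif_len ≥ 3, as the recovery report does.

## Synthetic divergence generator

Ancestral unigenes are drawn i.i.d. at `gc_target` (default 0.54) with
lengths uniform in 700–1000 nt; two descendants diverge independently.
Defaults are chosen so the *pairwise* divergence matches the regime the
analysis is meant for: per-branch substitution rate 0.005665 (pairwise
SNP ≈ 11.3/kb) at transition:transversion 1.45; pairwise small-indel
rate 1.58 per kb with a 1-nt-dominated length distribution
(1.319/0.109/0.076/0.031/0.010/0.019/0.004/0.003/0.005/0.001 relative
weights for 1–10 nt) and insertion odds 1331/2120 ≈ 0.63; large indels
(23–574 nt, uniform) at 0.07 expected events per sequence; 40 % of
indels slippage-generated with motifs of 1–51 nt. Indel rates are
defined pairwise — each event lands on a randomly chosen branch with the
branch-level operation chosen so the query-vs-subject direction comes
out right — because every quantity the pipeline estimates is pairwise.

Slippage gains duplicate the motif immediately upstream of the event
site (copied from the carrying branch after substitution, as a real
slippage event would); slippage losses first install the tandem copy in
the ancestor, so the surviving branch retains the repeat the classifier
looks for. Substitutions are applied before indels; every edit is
recorded with ancestral coordinates, and the truth table's edits replay
to byte-identical descendants (liftover closure, tested across 20
seeds). Events keep 60 nt clear of sequence ends and 15 nt of mutual
separation so that planted events cannot merge into one alignment
feature; pairwise SNP truth is computed by direct comparison of the two
substituted branches (so coincident double hits are counted as what they
produce) minus sites later removed by a deletion.

What the generator does *not* emulate: sequencing error and chimeric
reads, expression-level weighting of transcripts, paralogous gene
families (every query has exactly one true homolog), codon structure or
selection, and indel hotspots. Passing recovery tests therefore
demonstrates estimator correctness under the stated generative model,
not robustness to paralogy or base-calling artifacts; the identity and
best-hit filters that would handle paralogs in real data are exercised
only lightly.

## Recovery reporting and problem sizes

`recovery_report` compares estimates against the *realized* planted
counts (scaled by the planted column total), isolating pipeline
detection error from sampling noise. The boundary-repeat row is
restricted to large indels with motifs ≥ 3 nt, below which chance
matches dominate (see above). The end-to-end validation runs at 500
unigenes (~0.43 Mnt per library, ≈ 20 s on one CPU); module-level
simulation tests use 15–200 unigenes, chosen so the whole suite stays
interactive while keeping planted-event counts large enough for the
3-standard-error bands they assert.

## Known limitations

* The clusterer's consensus assumes member layouts compose consistently
  through the overlap graph; highly repetitive reads could violate this
  (real assemblers resolve it with layout refinement).
* Strand-mixed matched pairs are resolved by keeping the better strand's
  chain; genuine inversions within a unigene pair are out of scope.
* E-value constants are fixed ungapped published values, adequate for
  filtering but not for reporting BLAST-comparable E-values.
* Junction placement inside repeats is ambiguous at the ±few-nt level;
  breakpoint coordinates are canonical (downstream-HSP-anchored), not
  biologically resolved.
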