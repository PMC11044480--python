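# Methods

This note documents the models, rules and defaults behind `mobilome`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real data.

## Alignment core

All stages share one pairwise-alignment engine.

**Long-read mapping** is seed–chain–extend. Seeds are exact k-mers
(default k = 13) indexed over the forward reference; query k-mers are
sampled at every third position (`seed_stride = 3`) — dense enough that,
at ≤ 10% read error, the expected gap between surviving seeds is a few
bases, while lookup cost drops threefold. Chaining is a co-linear DP with
gap ceiling `max_seed_gap = 500` bp and per-link diagonal drift ≤
`band_width = 100` bp; predecessor lookup is O(1) through a per-diagonal
bucket registry, which stays fast even when the target holds dozens of
tandem copies of the query (the rolling-circle case — each copy occupies
its own diagonal). Extension is anchored: runs of seeds on one diagonal
become exact-match columns and only the short stretches between them are
aligned by banded affine DP (match +1, mismatch −2, gap open 2, extend 1;
a length-L gap costs 2 + L). Read ends beyond the outermost seeds are
extended up to 64 bp and then score-trimmed, so non-homologous tails
(e.g. a read running into a TE insertion) stay soft-clipped rather than
force-aligned.

Identity is always `100 × matches / alignment columns` (gap columns
included, as in PAF "BLAST identity"), so adding gaps can only lower it.
`global_identity` orders its arguments canonically before aligning —
co-optimal alignments can differ in match count, and the canonical order
makes the function exactly symmetric. Its band starts at the length
difference plus slack and doubles (with a warning) until the score stops
improving, so the result equals the unbanded optimum.

**Secondary-alignment policy.** A chain whose read interval is mostly
(≥ 50%) explained by a stronger chain mapping to a distant locus (> 4
alignment spans away, or another sequence) is an alternative placement —
typically another copy of the same family — and is suppressed. Nearby
placements (tandem monomers, the two LTRs of one element) are kept. This
mirrors the usual best-N secondary handling of long-read mappers and is
what keeps per-element read counts attributable.

Tie-breaks are deterministic everywhere: primary = highest score, then
lowest (target, position); DP traceback prefers diagonal, then
target-gap, then query-gap.

## Synthetic data: what it emulates

`SimConfig` defaults encode the study design the pipeline is meant for:

- two LTR-RTE families, three copies each, on a 2 Mb chromosome; element =
  LTR (400–600 bp) + internal (3800–4600 bp, grown if needed to hold the
  planted ORFs) + LTR, flanked by a 5 bp target-site duplication
  (Copia-typical; configurable 4–6);
- planted reading frames of 1302 codons (family 1) and 352 + 1173 codons
  (family 2), each fenced by an in-frame stop so the scan recovers the
  exact planted length;
- copy 0 of each family equals the family consensus and is the designated
  active element; other copies carry 3% substitutions (within-family
  identity ≈ 94%, between families < 80%);
- eccDNA libraries of 5,000 reads per condition; the treatment library
  over-represents active elements 10-fold; circle classes default to a
  mix of solo-LTR (0.25), full-length with one LTR (0.35), with two LTRs
  (0.25) and truncated (0.15);
- reads are tandem repeats of the circle from a uniform random phase,
  lognormal length (default µ = 8.0, σ = 0.4 ≈ 3.3 kb — chosen for
  testability, not nanopore realism; structure-analysis scenarios use
  µ = 9.6 so full-length circles yield ≥ 2 monomers per read), corrupted
  by per-base independent substitution/insertion/deletion errors (default
  0.05/0.025/0.025 ≈ 10% total edit rate, verified against an independent
  alignment library);
- WGS reads come from a donor haplotype with background SNPs at
  10⁻⁴/bp, a 20-fold-elevated introgressed segment, and full-element
  insertions with TSDs. Insertion junctions are planted only where the
  (breakpoint, TSD) representation is unique, and a 70 bp neighbourhood
  is kept SNP-free, so planted truth is exactly identifiable — degenerate
  junctions exist in real data and are then inherently ambiguous, which
  the caller cannot and should not resolve;
- a three-genome panel carries copies of the active elements at 2%, 8%
  and 20% divergence (the 2% genome playing the wild relative of origin).

Not simulated, hence not demonstrated by passing tests: nanopore
error-profile structure (homopolymer bias, quality correlation), RCA
chimeras/branching artifacts, diploid genotypes, structural variation
other than TE insertions. Base qualities are constant because nothing
downstream uses them. Every generator is byte-deterministic under a
fixed seed.

## Differential activity

Reads count once each, toward the element their primary alignment
overlaps most (ties to the leftmost element), requiring ≥ 100 bp overlap.
Normalisation divides by total sequenced reads per library (not mapped
reads) per 100,000. The per-element two-sided Fisher exact test is
corrected by Benjamini–Hochberg over the elements with more than 10
supporting reads (Bonferroni available); "manual curation" is replaced by
these explicit, reproducible filters. Directionality is enforced after
testing: significance additionally requires the normalised treatment
count to exceed control, so depleted elements are never called active.
The null simulation (same mixture in both conditions) keeps the observed
significant fraction within the nominal level.

## Concatemer decomposition and structure classes

Monomer copies are the tandem hits of the element on the read. Copies are
deduplicated per read region (the two identical LTRs of an element are
alternative placements of the same fragment; they are recognised by
aligning the candidate element regions against each other at ≥ 80%
identity and merged, otherwise apparent spacing doubles when placements
alternate). Monomer length is the median target spacing between
successive copies showing the same element region, compared at a shared
element offset — exact on error-free reads for every phase, and within
±2% at 10% error. Full monomers are period windows covered ≥ 90%;
junctions are supported when coverage around the boundary has no gap
> 50 bp (the concatemer's advantage: a truncation supported across a
junction is biology, an unsupported one is breakage). The consensus is a
per-column majority over up to 20 full monomers (≥ 2 required), ties
resolving to the anchor monomer.

Classification projects one monomer window onto the element:
internal-region coverage ≤ 0.1 with an LTR present → `solo_LTR`;
≥ 0.9 with one/two LTR copies → `full_1LTR`/`full_2LTR`; in between →
`truncated`; anything else → `other`. LTR copies are counted over
distinct *read* positions, because a phase-split monomer projects its
single LTR onto both element LTRs. Uncovered internal runs ≥ 20 bp within
the covered span are reported as deletions. Only reads with at least one
full monomer are classified in the pipeline: a lone partial monomer of a
long circle is indistinguishable from a truncated circle.

## Divergence pileup

Monomer copies pile onto element coordinates through their alignment
columns; bases within 2 columns of an indel are masked (the long-read
analogue of base-alignment-quality masking — those are the columns
alignment jitter misplaces), while coverage flags use unmasked columns. A
SNP needs depth ≥ 5, majority agreement ≥ 0.8 and a non-reference
majority base. `ltr_covered` is false when mean LTR depth < 1; a ≥ 20 bp
zero-depth run inside an otherwise covered LTR is an LTR deletion. The
synthetic divergence generator plants its substitutions in the internal
region: a site inside one LTR is diluted by the other, identical LTR
during pileup and stops being exactly countable — the generator keeps
truth identifiable rather than pretending the ambiguity away.

## Origin assignment

The consensus LTR is mapped against each panel genome with
divergence-tolerant seeding (k = 11, every position — a 20%-diverged
homolog still yields dense hits). The matched locus is then re-derived:
the query is globally aligned to a padded window, target overhangs
(terminal gap runs plus ≤ 3 chance-matched columns outside them) are
stripped, and the reported identity is an optimal band-auto-widened
global alignment of query vs locus — it reproduces a full-matrix oracle
on that pair exactly. Assignment requires the floor (96%) and a ≥ 1-point
margin over the runner-up; ties break by genome name; when every identity
is below the floor the call is `ambiguous`, never forced.

## WGS: SNPs, introgressions, TEIs

The naive pileup caller (haploid design: allele fraction ≥ 0.7 at depth
≥ 5) stands in for a production variant caller; a VCF reader accepts
external calls. Windowed density uses fixed tiling (1 Mb default; the
desk-scale pipeline uses smaller windows), scales the last partial window
by its true width, and takes the genome median over full windows.
Introgressions are maximal runs of windows ≥ 5× the median, tolerating
one sub-threshold window, at least three windows long; with a zero
median an absolute threshold (default 50 SNPs/Mb) applies, with a
warning. The 5×/3-window rule is a declared default — the underlying
call criterion is not standardised — and both knobs are exposed.

TEI calling collects, per read: insertion cigar operations ≥ 500 bp;
same-chromosome/strand alignment pairs whose read interval skips
≥ 500 bp while the reference barely advances (all pairs are examined, not
just read-adjacent ones, because the insert itself often aligns to its
source locus in between); and, for reads with no spanning pair, clipped
ends that re-align to the TE library. Junction segments are re-anchored
by exact flank 30-mers where possible, since alignment endpoints can be
a few bases off when micro-homology lets a flank absorb element bases
with indels. Clusters within 50 bp with ≥ 3 supporting reads become
calls; the breakpoint and TSD come from fitting the explicit donor model
`ref[..p] + element + ref[p−tsd..p] + ref[p..]` to the evidence reads
(median over up to 5 fits). One-sided clip evidence pins the breakpoint
(left side) or the element→reference boundary `p − tsd` (right side);
the TSD is only reported when both sides are observed. Family assignment
needs ≥ 80% identity over ≥ 80% of the shorter of (element, fragment).
Positions are 0-based internally (base immediately left of the
insertion) and 1-based in output.

## Numerical and engineering choices

- Numba-compiled kernels (banded Gotoh, chain DP, seed lookup) keep the
  pure-Python surface; first call in a session pays a few seconds of
  JIT compilation.
- Coordinates are 0-based half-open internally; BED stays 0-based,
  GFF3/VCF-style outputs are 1-based.
- IUPAC ambiguity codes match only themselves; k-mers containing them are
  never seeds.
- Degenerate inputs: empty queries, empty panels and empty libraries
  raise; a read with no hit to its element decomposes to an empty (not
  erroneous) result.
- Desk-scale sizing: the shipped scenarios use 0.4–2 Mb chromosomes,
  thousands of reads and a 50 Mb variant-level introgression model —
  sizes chosen so the full suite and the acceptance script run in
  minutes on one CPU while every statistical operating condition
  (enrichment fold, error rates, depths, read counts) matches the study
  design the defaults encode.

## Known limitations

- The error model is per-base independent; homopolymer-biased callers or
  aligners are not stress-tested.
- The built-in aligner targets ≤ ~10–20% divergence; it is a desk-scale
  reference path, not a production mapper.
- TSDs are only recovered when spanning (or two-sided clip) evidence
  exists; single-sided evidence leaves the TSD undetermined by
  construction.
- Family assignment of TEIs uses the provided element library; novel
  families outside it are reported `unassigned`.
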