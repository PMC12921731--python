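# Methods

This note documents the models, conventions and design choices behind
`teloscan`, in the package's own terms.

## The template language and the scanner

Telomerase extends chromosome ends by copying a short template inside its
RNA subunit (TR). For a telomere terminal repeat unit *u* (default
`TTAGGC`, the *Caenorhabditis* unit), any sequence that can act as a
template must read as a circular permutation of `revcomp(u)`: formally,
the *template language* is the set of substrings of `revcomp(u)^∞`. A
template region consists of a template part (one full unit, copied into
DNA) and an annealing part that base-pairs with the existing telomeric
overhang; with the default length bounds of 8–20 nt for the whole region
and a 6 nt unit, annealing parts are 2–14 nt.

`find_template_sites` computes, for every position, the longest
in-language run starting there via a dynamic program over the six phases
of the repeated reverse complement (`run[p][i] = 1 + run[p+1 mod 6][i+1]`
when the residue matches phase *p*, else 0), then keeps runs that cannot
be extended on either side. `N` matches no phase. Runs shorter than the
lower bound are dropped; runs longer than the upper bound are returned
flagged `overlong` and excluded from candidate calls — such runs are
telomeric repeat arrays, not TR templates. A selectable truncation mode
instead clips overlong runs to the upper bound (marked non-maximal).
Overlapping maximal runs of different phase are reported separately; no
merging across single mismatches is attempted. Tests cross-check the
scanner against an exhaustive substring oracle that grows runs by literal
substring search and filters maximal ones by explicit containment.

**Coordinates.** Internally everything is 0-based half-open. Rendered
reports use 1-based inclusive positions, under which printed length
equals `end − start + 1`; the bundled published candidate table conforms
to this identity (e.g. the confirmed TR: 7,933,766..7,934,092 → 327 nt).

**Decomposition orientation.** The published figures mark the
template/annealing split but not its orientation within the motif; the
package defaults to the template part at the 5' end of the motif
(annealing at 3'), which makes the template part of the confirmed
*C. elegans* motif `TAAGCCTAAG` read `TAAGCC`, consistent with the
reported cross-species core. The orientation is a keyword option.

**U/T handling.** All sequence ingest normalizes RNA `U` to DNA `T`;
motifs are reported in DNA letters.

## The candidate filter cascade

Stages run in a fixed order; each returns a subset of its input, and the
driver logs survivor counts and records the stage at which each
transcript fell:

1. **Coverage** — mean per-base depth in the total-RNA library ≥ 10. The
   original screen names "minimum base coverage of ten" without naming
   the statistic; mean is the default here, with a per-base-minimum mode.
2. **Redundancy** — transcripts whose interval is fully contained in
   another retained transcript on the same strand are removed; among
   identical intervals the lexicographically smallest id is kept.
   Implemented as a start-sorted sweep, cross-checked against a
   quadratic containment oracle.
3. **Annotation overlap** — any transcript sharing ≥ 1 bp with an
   annotated CDS or ncRNA gene is removed, strand-agnostic by default
   (a novel-ncRNA screen must also reject antisense overlap); a stranded
   mode exists. CDS annotation is de-duplicated to unique
   (chrom, start, end, strand) loci first.
4. **Coding potential** — a transcript is removed when *either* of two
   classifier scores exceeds 0.5 (score ≤ 0.5 counts as non-coding).
   Unscored transcripts are kept and flagged.
5. **Length** — at most 1000 nt.
6. **Template** — transcripts without a valid (non-overlong) template
   site are removed; transcripts with ≥ 2 valid sites are flagged
   `multi_template` and excluded from ranking but reported, since
   multiple templates are not expected of a genuine TR.

Survivors are annotated with: Poly(A)-library expression class,
conserved-structure locus overlap (any-overlap), and H/ACA predictions —
when several H/ACA hits exist the one furthest towards the 3' end is
chosen, because the motif marks the 3' terminus of H/ACA-class RNAs and
the predictor has no positional bias.

**Ranking.** The rule-based score counts six criteria: single template;
template 1-based start ≤ 200 nt ("near the 5' end" has no published
number; 200 nt is this package's documented default); length in
[200, 500] nt (the typical animal TR range); Poly(A) class `absent`;
structure-locus overlap; H/ACA presence. Ties are broken by descending
total coverage, then id, making ranks order-independent.

**Poly(A) classes.** The labels absent/half/similar/abundant are
standard; their numeric boundaries are not published. The package bins
the ratio r = (library-size-rescaled Poly(A) coverage)/(total coverage)
as: r < 0.1 absent; r < 0.7 half; r ≤ 1.5 similar; else abundant. The
bins are configurable and deliberately excluded from acceptance checks.
The rescaling factor between libraries is supplied by the caller.

**Recall.** An annotated gene counts as recalled when at least a minimum
fraction (90 % for transcript sets, 50 % for alignment-based loci, both
caller-chosen) of its length is covered by the *union* of overlapping
predictions; abutting predictions therefore combine, overlapping ones do
not double-count.

## MAF post-processing

`ungap_filter` removes blocks whose overall gap-character fraction over
the whole block matrix exceeds 0.9. The published threshold ("0.9 of all
sequences in the block") admits a per-line reading; that variant is
implemented as a separate mode (`drop_gappy_lines`), and the block-matrix
reading is the default.

`merge_pass` greedily merges consecutive reference-sorted blocks when
(i) Jaccard species overlap ≥ 0.75 — the published "75 % species
consensus" does not define a denominator, and the union is the stricter,
symmetric choice — and (ii) every shared species continues on the same
source and strand with a coordinate gap in [0, 5] nt. Merging keeps only
shared species; per-species gap residues are inserted as extra columns
(gaps in all other species), fetched from genome FASTA when available
and `N` otherwise, so coordinate arithmetic always stays exact. Merged
scores are the sum of the parts and flagged synthetic, since re-scoring
is not defined for concatenated blocks. Per-species residue conservation
under merging is property-tested against the source genomes.

## Intron-anchored homolog annotation

Fast-evolving TRs defeat sequence-homology search; a conserved host-gene
intron is used as a syntenic anchor instead. Intron ordinals follow
transcription order of the supplied gene model (0-based; ordinal 1 =
"intron 2"); because exon/intron structure drifts between species, a
helper selects the intron whose flanking exon lengths best match a
reference. Scanning is strand-aware (the transcribed strand of the
intron), and one best site is kept per intron — longest, ties towards
the 5' end — since one template per intron is expected. Offsets obey
`offset5 + |motif| + offset3 = intron length` by construction.

Candidate windows span 70 nt upstream and 350 nt downstream of the
template and are clipped at intron boundaries by default (an
intron-hosted TR cannot extend into exons), with truncation flags; an
opt-out extends into the pre-mRNA. For oversized introns the window
makes no claim about gene boundaries beyond its flags.

**Consensus motifs.** Each per-species motif is a member of the template
language and hence has a unique phase on the repeated reverse
complement; alignment is gap-free phase matching. Among the six
rotations of the repeat, the one maximizing column agreement (summed
squared support) anchors the stack; the consensus keeps the contiguous
columns supported by a strict majority of species, and the core keeps
columns supported by all species minus an allowed number of exceptions
(default 2, reflecting the rare core drop-outs seen across real
*Caenorhabditis* homologs).

## The synthetic scenario generator

The generator emulates the statistical structure the screen assumes, not
real sequencing data: i.i.d. uniform-GC background (configurable), a
four-exon host gene whose 430 nt intron 2 carries the planted TR
(template at offset 85 from the intron 5' end — within the typical
80–90 nt — leaving ~335 nt downstream, inside the typical 300–350 nt),
a transcript placing the template at position 29, and literal H/ACA-like
boxes near the intron 3' end. Of 33 species, 21 (including the
reference) carry the template — mirroring the reported fraction of
template-bearing orthologous introns — with flanks diverged at a
configurable per-site substitution rate (default 0.1) around a protected
core, varied motifs from a curated set of real template variants, and
offsets drawn from 80–90 nt. Decoy transcripts (22 by default) are each
engineered to fall at one specific cascade stage, including near-miss
motifs one edit outside the language and a 42 nt telomeric repeat array
that must be flagged overlong. Coverage tracks are noiseless step
functions by default (Poisson noise optional). The MAF output is a
three-block mergeable chain, one ~95 %-gap block and one isolated block,
with block texts cut from the actual synthetic genomes so conservation
is checkable.

Planted motifs are written with *boundary-breaking* residues (the
adjacent base is forced off the cyclic continuation) so the planted
maximal run is exactly the planted span, and both strands of every
genome are scrubbed for chance template runs outside planted regions
(re-rolled with fresh random bases; planted positions are never
rewritten). This keeps the ground-truth manifest exact: every transcript
is removed at its intended stage, the planted TR ranks first, and its
intron offset is recovered exactly.

What passing on synthetic data does **not** show: robustness to indels
(the divergence model is substitution-only), to assembly or mapping
artifacts, to fragmented transcript models, or to realistic coverage
biases; real external-tool scores are noisier than the generated tables.
The generator fixes the *geometry* the method relies on, so tests
demonstrate correctness of the machinery, not field performance.

## Numerical and degenerate-input conventions

* All randomness flows through a single `numpy` Generator seeded by the
  caller; identical (config, seed) pairs produce byte-identical outputs.
* Empty inputs return empty outputs (never errors) for filters and the
  scanner; contract violations (overlong decomposition, out-of-range
  intron ordinal, non-member motifs in consensus, unsorted merge input)
  raise with specific messages.
* Filter boundaries are inclusive on the surviving side throughout:
  mean coverage ≥ 10 survives, coding score ≤ 0.5 survives, length
  ≤ 1000 survives, gap fraction ≤ 0.9 survives, merge distance ≤ 5
  merges.
* Problem sizes used by the test suite and acceptance checks — a 70 kb
  reference chromosome, 33 species of ~1.7 kb homolog regions, 1,000
  scanner-oracle sequences of 500 nt, 100 random merge chains, 50
  divergence replicates — were chosen as the smallest sizes at which
  every planted structure and boundary case is still exercised.

## Known limitations

* One telomere unit per scan; degenerate/variant repeats are out of
  scope.
* The merge operation never re-aligns columns; it is bookkeeping over an
  existing alignment.
* Coding potential, structure conservation and H/ACA motifs are consumed
  as external scores, never computed.
* The consensus-motif phase alignment assumes every input motif is an
  exact language member; mutated templates must be re-validated first.
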