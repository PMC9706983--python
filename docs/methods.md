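# Methods

## Problem setting

A transgene construct — a plasmid backbone carrying a 90 bp minimal *unc-54*
enhancer with single-insert cloning points (HindIII upstream, NheI
downstream) — is propagated in vivo as a repetitive extrachromosomal array of
roughly 70–300 tandem copies. Mononucleosome core DNA is recovered by MNase
digestion and probe hybridization and sequenced paired-end against the
transgene reference. The analysis asks two questions about each inserted DNA
element: does it change how many nucleosomes occupy the enhancer region
(occupancy), and does it hold nucleosomes in a fixed register (positioning)?

## Fragment processing

Alignments are reduced to fragments: one 0-based half-open interval per
properly paired, mapped pair on a single reference, spanning leftmost mate
start to rightmost mate end (taken from the template length). Secondary and
supplementary records are ignored; mates on different references are counted
and dropped, not fatal. Two length gates apply, both inclusive and both
configurable:

* **ingest cap, 200 bp** — mirrors the aligner insert-size limit used for
  repetitive construct references; applied when reading SAM/BAM or fragment
  BED;
* **retention window, 136–158 bp** — the mononucleosome band actually
  analysed (147 ± 11 bp). "Between 136 and 158" is read inclusively; the
  symmetric ±11 window around 147 supports that reading, and the bounds are
  parameters, not constants.

Each retained fragment contributes one **dyad** at
`start + (length − 1) // 2`. Even-length fragments have no central base; we
floor to the left-of-center base. Any consistent tie-break shifts even-length
dyads by at most 1 bp; this one is chosen for determinism and recorded here.
Strand is ignored: a nucleosome footprint is strand-symmetric and the
interval alone fixes the midpoint. Duplicate fragments are retained — arrays
are highly repetitive and duplicates are expected signal, not PCR artifacts
to remove. Samples (lines, MNase concentrations) are kept separate by
default; `pool_by_construct` merges them by count-wise summation when set
explicitly.

## Profile statistics

With `c(d)` the dyad count track on a reference of length `N`:

* **Occupancy**: `occ(p) = Σ_{|p−d| ≤ h} c(d)` with half-footprint
  `h = 73 bp` (147 bp canonical nucleosome). Footprints are clipped at the
  reference ends — no wraparound, no phantom dyads.
* **Positioning**: `score(p) = W_10(p) / W_150(p)` where `W_k(p)` sums dyads
  in the inclusive window `[p−k, p+k]`, truncated at the ends. Inner window
  21 positions, outer 301. A position whose outer window is empty scores 0
  (with no nucleosome within 150 bp, none is positioned there); occurrences
  are logged. Scores are bounded in [0, 1] because the inner window is a
  subset of the outer.

Both statistics are computed with integer cumulative sums, so they equal a
literal per-position recount exactly (the test suite checks this against
naive double-loop oracles, exact equality, no tolerance).

Occupancy profiles are **normalized** before summarising. The default divides
by the profile maximum over the analysis window (whole reference unless
configured), giving the 0–1 scale used for plotting and region totals; a
"mean" method is available. The choice of method is genuinely open — raw
totals over a 90 bp region at high coverage would be arbitrary-scale — and
max-normalization is the package default because summed sub-unity values over
a 90 bp enhancer produce totals on the observed tens-scale. The method and
window are recorded in the profile metadata and in every output header.
**Total occupancy** over a region is the sum of normalized values across it;
**ratio to control** divides a construct's total by the control construct's
(control versus itself is exactly 1; a zero control is an error).

## Coordinate conventions

Internally everything is 0-based, half-open. Reporting uses signed offsets
from the enhancer center: `offset = position − center`, negative upstream.
The center of an interval of length `L` starting at `s` is `s + L//2` — for
odd `L` the central base, for even `L` the upper-median base, chosen so the
90 bp enhancer spans exactly [−45, +45) on the report axis. Even-length
elements have "no true center", so element-level positioning reports return
the scores at both center-flanking positions `s + L//2 − 1` and `s + L//2`.
Note this interval-center convention is deliberately distinct from the
fragment-dyad tie-break (left-of-center): the former fixes a reporting
origin, the latter a per-fragment statistic; each is stated where it applies.

**Flank alignment** makes constructs with different insert lengths
comparable: the minimal contiguous interval covering the enhancer plus all
inserted elements (overridable in config) is excised; upstream flank
positions take offsets …, −2, −1 ending at its left edge and downstream
positions +1, +2, … from its right edge. Values are untouched — only labels
change — and profiles are not re-normalized after excision, so curves remain
on their per-construct scale. Non-contiguous removal requests are rejected.

## Array coverage estimate

Per-copy sequencing coverage for a `k`-copy array is
`mapped_pairs × effective_bases_per_pair / (probe_length × k)`, evaluated at
both ends of the 70–300 copy range (more copies → shallower per-copy
coverage, so the high copy number yields the low bound).
`effective_bases_per_pair` defaults to the mean reconstructed fragment
length — an explicit assumption, since with short (25 bp) reads the fragment
span, not the read bases, is what localises a pair. The formula string and
constants are carried in the result object rather than hidden, because
reasonable variants (read bases vs fragment span) differ by a constant
factor and downstream users should see which was used.

## Synthetic data generator

The generator is an explicit invention for testing the statistics — not a
sequence-dependent nucleosome-energetics model. Dyads are i.i.d. from a
mixture:

* **positioned sites** — probability ∝ `weight`; position = site dyad plus
  rounded `N(0, jitter_sd)`, resampled if off-reference. `jitter_sd` (bp)
  controls register sharpness: 0 gives a delta, ~3 a strong element, ≥10 a
  weak one.
* **background** — probability ∝ `background_weight`; uniform over the
  reference with per-position density multiplied by the factor of any
  covering **depletion zone** (factor ∈ [0,1]; 0 = hard exclusion),
  implemented by rejection sampling.

Fragment lengths are drawn from a discrete law on [130, 210] bp — default a
rounded normal, mean 147 bp, sd 6 bp, truncated — chosen to span beyond the
136–158 bp retention window so the filter is always exercised (the law's
mass on the window, ≈0.946, is a closed-form prediction the tests check
against observed retention). Fragments are laid out as
`[d − (L−1)//2, d − (L−1)//2 + L)`, which inverts the dyad tie-break exactly
for every length; fragments overhanging the reference are discarded and
counted, so `n_fragments = written + edge-discarded`.

The in vivo array's 70–300 tandem copies are modelled as a single-copy
reference with `n_fragments` scaled accordingly: hybridization collapses all
copies onto one probe sequence, so per-copy simulation would add nothing the
statistics can see. Sequence features the generator does **not** emulate —
MNase sequence bias, GC bias, dinucleotide periodicity, PCR duplication —
mean that passing tests demonstrate correctness of the statistics and
recoverability of planted signal, not robustness to real-data biases.

All randomness derives from one user seed via per-operation stream splits
(`SeedSequence([seed, op])`), so dyad simulation and length assignment are
independently reproducible and identical parameters give byte-identical
output files. Jitter draws flow through the normal sampler even at sd 0
(scale is applied after the underlying variates), so runs differing only in
`jitter_sd` share all other randomness for a given seed — which is what makes
paired jitter-level comparisons in the tests exact rather than noisy.

Presets (`control`, `positioning_601_like`, `repelling_PRS_like`,
`deboer_like`) give fully specified experiments over the placeholder
construct. Preset site weights (0.25 per site over 0.5 background) and zone
factors (0.01 repelling, 0.5 one-sided de Boer-like) are round numbers chosen
to make planted signal unambiguous at the default 50,000 fragments. The
"601"/"PRS-322" sequences in presets are seeded random stand-ins of the
correct lengths (147/70 bp) — real element sequences are config inputs
(FASTA), since only length and placement affect the dyad statistics;
homopolymer elements are built literally.

## Constructs and the placeholder backbone

Element lengths that are fixed by definition are enforced on use (PRS-322
70 bp, Trifonov 166 bp, polyA20/polyT5/A5cA5 literal). Reverse-oriented
inserts are reverse-complemented before insertion; assembly is
length-conservative and every recorded interval slices out of the assembled
sequence verbatim. The full parent plasmid sequence is not published in
machine-readable form, so the package ships a deterministic synthetic ~2.5 kb
placeholder backbone with marked HindIII/NheI points; the distances between
insertion points and enhancer edges default to 3 bp and are configurable,
because the true spacings are not published and element-center report
positions shift bp-for-bp with them. (The upstream cloning site is sometimes
written "HindII" in secondary sources; it is HindIII.)

## Pipeline determinism and problem sizes

The pipeline is a pure function of (config, input files): re-runs are
byte-identical, outputs carry provenance headers (parameters, package
version, input checksums) with no timestamps, and exit codes separate config
errors (2) from data errors (3). Default simulation sizes in tests and
examples (20,000–50,000 fragments on a ~2.6 kb reference, 10 replicate seeds
for recovery checks) are the sizes at which the planted effects dominate
Monte-Carlo noise by a comfortable margin — e.g. a ±0.1 tolerance on
depletion-factor recovery sits ~5× above the sampling noise at 50,000
dyads — while keeping any single check to seconds.

## Known limitations

* No statistical testing of profile differences between constructs; the
  summaries are descriptive, matching how such experiments are reported.
* The occupancy normalization is per-construct; cross-construct occupancy
  comparisons therefore assume comparable dynamic range, which the flank
  alignment view partially mitigates but does not remove.
* Ingest trusts proper-pair flags and template length; it does not re-pair
  mates by name, so aligner-specific pairing quirks pass through.
* The coverage estimate's constants are exposed rather than fitted; absolute
  coverage numbers depend on the `effective_bases_per_pair` assumption.
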