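# Methods

## The experimental design being modeled

A sequence-specific nuclease (SpCas9 with a single guide) cuts a genomic
target; erroneous end-joining leaves a footprint. The assay amplifies the
target region by PCR and digests the product with a restriction enzyme
whose recognition site lies near — but does not overlap — the predicted
cut. Wild-type molecules are cut; molecules whose footprint destroyed the
site resist digestion and can be enriched (by pre-digesting the genomic
DNA before PCR), cloned and Sanger-sequenced. Each sequenced clone is one
molecule from a pool of seedlings of one independent transformant line;
identical sequences within a line are counted as one mutagenesis event
because they may be PCR siblings.

## Coordinates and the cut

All coordinates are 0-based half-open on the amplicon; the cut position is
a between-base junction coordinate. The cut is placed 3 nt 5′ of the PAM
(blunt SpCas9 geometry) on the protospacer strand; this is a convention,
configurable per locus. Restriction-site matching is exact-sequence on
both strands (no degenerate IUPAC codes; both supported enzymes, PstI
`CTGCAG` and FauI `CCCGC`, are exact), and cleavage-offset geometry is not
modeled — the digest model only needs presence or absence of the site.

## Footprint calling

One contiguous event per clone: with longest common prefix `p` and suffix
`s` against the reference (capped so `p + s` never exceeds either
sequence), the deletion is `ref[p : len(ref)-s)` and the insertion
`read[p : len(read)-s)`. The call is canonicalized to the leftmost
equivalent placement by unit shifts (a shift left is possible when the
last inserted/deleted base equals the base left of the junction's right
flank); the full shift range `[p_min, p_max]` is recorded and its width is
the microhomology length for pure deletions. Reassembling
`ref[:start] + ins + ref[end:]` must reproduce the read byte-exactly; this
round trip is asserted on every call.

Policy choices the assay text leaves open:

- Equal-length replacements are classed `substitution` regardless of
  length and excluded from deletion- and insertion-length statistics
  (they are plausibly PCR artifacts and were described separately).
- A deletion length of a deletion+insertion (`delins`) event counts only
  the deleted reference bases; the insertion is tallied separately.
- Reads sharing neither primer anchor with the reference are excluded as
  unalignable, and called events reaching farther than 250 bp (default)
  from the cut are excluded as complex — scattered sequencing mismatches
  would otherwise inflate a footprint. Both exclusions are counted in the
  run manifest, not silently dropped.
- Intact reads get the degenerate placement (0, 0).

## Junction annotation

Microhomology is annotated for pure deletions only; junction ambiguity of
insertion-bearing events is attributed to the insertion placement.

Template search for insertions uses the window ±100 bp around the cut
(clipped at amplicon ends) and its reverse complement. A full-length match
is `perfect` (direct) or `reverse`; otherwise the insertion is greedily
decomposed into maximal matched stretches of ≥ `min_seed` (default 4)
bases, longest first, insertion-leftmost on ties, direct preferred, giving
`partial` when anything matches. Insertions shorter than `min_search_len`
(default 3) are not searched. When a word occurs at several window
positions, the occurrence whose midpoint is nearest the cut is chosen —
repair templates are typically copied from immediately around the break,
and the nearest copy is the most parsimonious source. Primer identity is
the longest exact match between the 3′ end of the retained left flank and
the bases immediately 5′ of the first matched segment, read in template
orientation; `primed` requires ≥ 2 bp (1 bp matches by chance in 25% of
junctions). All thresholds are configurable and echoed into output
headers.

## Mann–Whitney U

Two-tailed throughout. For n₁+n₂ ≤ 12 without ties the exact permutation
null is used; ties or larger samples use the normal approximation with
tie-corrected variance and 0.5 continuity correction (scipy's
implementations back both branches; the branch taken is recorded in the
output). Deletion lengths are heavily tied, so real contrasts virtually
always use the tie-corrected approximation. Raw p-values are reported and
flagged at α = 0.05 without multiple-testing correction, matching how such
contrasts are conventionally presented; Holm-adjusted columns can be added
via the API. Note that near p = 0.05 the exact/approximate conventions can
disagree; the empirical null rejection rate of the approximate branch at
n = 20 + 20 is ≈ 0.048.

## Synthetic data generator

The generator emulates the sequenced clone pools: each clone carries one
event flanked by exact reference sequence. Event classes and their default
weights (wild-type presets): intact 0.05, small 1–2 bp indel 0.10,
microhomology-flanked deletion 0.65, templated insertion 0.20. KU-deficient
presets shift weight toward templated insertions (0.28), reflecting the
reported excess of insertion events in those backgrounds.

**Deletion lengths** follow a two-component mixture: a short geometric
(minimal end-processing by classical end joining, parameter `p_short`) and
a discretized lognormal long tail (resection-scale deletions, `mu_long`,
`sigma_long`), mixed with weight `lambda_long`, truncated at 150 bp and
renormalized. A pure two-geometric mixture cannot reproduce several of the
reported bin vectors (its pmf is monotone and cannot place a mode in the
10–19 bp bin), hence the lognormal tail. Parameters are fitted offline by
multistart Nelder–Mead (`scripts/fit_presets.py`) so the analytic bin
probabilities match the reported per-genotype fractions to within 0.01,
and are stored in `src/dsbfoot/data/presets.json`. Where only the ≥ 20 bp
tail was reported (the KU-deficient backgrounds, and the first two bins of
*parp1 parp2* at the first target), the unreported split was chosen once:
proportionally similar to wild type but shifted toward longer deletions
(values are the `bin_targets` entries in the preset file).

**Deletions straddle or abut the cut**, with the left/right split uniform
over valid positions. Microhomology-class deletions draw a target
homology length m (default distribution over 0–6 bp: 0.40/0.25/0.15/
0.10/0.05/0.03/0.02) and search endpoints whose flanks share exactly that
m-mer, preferring the drawn length and widening by at most ±2 bp;
when no placement exists the event falls back to m = 0 and is counted and
flagged in the truth record. Re-detected microhomology can exceed the
planted value when flanking sequence happens to extend the repeat — never
undershoot it.

**Templated insertions** copy a window substring (reverse complement with
probability 0.3, after the reported mix of orientations), have geometric
lengths (p = 0.12, truncated at the reported maximum of 60 bp, median
< 10 bp), are accompanied by a deletion with probability 0.6 whose length
is scaled 3× (insertions were reported at junctions with larger
deletions), and plant a ≥ 2 bp primer identity with probability 0.5
(identity was reported "in about 50% of the inserted sequences"). 20% of
insertion events are instead random words, rejection-sampled (when ≥ 8 bp,
where absence is achievable) to be absent from the window in both
orientations. The generator records template position, orientation,
uniqueness in the window, and the achieved primer-identity length.

Two placement rules keep truth and call consistent: a planted insertion
boundary never equals the adjacent reference base (otherwise the minimal
footprint would be a strictly smaller event, or the junction could shift
and rotate the inserted word), and the planted placement is therefore the
canonical one.

**Synthetic loci.** Real amplicon sequences for the two published targets
live in supplementary material that is not redistributed here, so the
default loci are synthetic stand-ins (flagged `synthetic=True`): a random
360 bp amplicon with a 20-nt protospacer, AGG PAM, the enzyme site inside
the protospacer ending 2 bp 5′ of the cut (near, not overlapping —
matching the described geometry), a unique recognition site on either
strand, and 20 bp primers at the termini. Users analyzing real data supply
their own locus config (TOML/JSON, inline amplicon or FASTA reference).

**Determinism.** All randomness flows from one `numpy` generator seeded
from the config; identical (config, seed) gives byte-identical FASTA/TSV
outputs. PCR duplicates are simulated at rate 0.05 within lines (8 lines
per dataset by default).

## What the generator does and does not emulate

It reproduces the statistical structure the analysis consumes — event
mixtures, calibrated deletion-length spectra, microhomology, templated
insertions with primer identity, within-line duplicates, digest
detectability. It does not model PCR amplification bias, pooled-seedling
mosaicism, chromatogram noise (an optional uniform substitution-noise
rate exists to exercise the complex-clone policy, default off), partial
digestion, or multi-event clones. Passing tests on synthetic data
therefore demonstrate the correctness of the calling/annotation/statistics
machinery under the declared model, not robustness to those real-data
effects.

Two known consequences of the synthetic geometry are worth flagging.
First, the digest filter at the synthetic locus removes more short
deletions than at the real loci (the site sits on one side of the cut, so
a short deletion extending the other way keeps the site); post-filter bin
fractions are conditioned on detectability, mirroring — more strongly —
the real assay's acknowledged blind spot for 1–2 bp events. Second, the
observed primed fraction among all insertions is lower than the planted
50% among templated ones: 1–2 bp insertions are below the search
threshold, untemplated insertions dilute the pool, and very short template
words are ambiguous in the window. These are properties of the inference
problem, not bugs; the planted primer length is recovered exactly whenever
the template word is unique in the window.

## Numerical and design notes

- Deletion-length bins are exactly [1,9], [10,19], [20,49], [50,∞) bp;
  intact events must never reach statistics (length 0 raises).
- Canonical placement is leftmost; dedup keys are
  (line, class, interval, insertion) of the canonical form.
- The mutation-frequency estimate is resistant-band intensity divided by
  total lane intensity, taking quantified intensities as given input.
- Problem sizes in tests and in `scripts/acceptance.py` (hundreds of
  clones per preset, 2,000-clone recovery runs, 500-replicate power and
  2,000–10,000-replicate null simulations) were chosen as the smallest
  sizes at which the binomial/Monte-Carlo error is well below the effect
  sizes being checked.
- Sample sheets (TSV: clone_id, line_id, genotype, nuclease) are the
  canonical metadata channel; `cloneID|line|genotype|nuclease` FASTA
  headers are a fallback. All outputs are TSV with JSON mirrors plus a
  manifest recording versions, thresholds, seeds and per-stage counts;
  count conservation (clones = events + duplicates + unalignable) is
  asserted at run time.
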