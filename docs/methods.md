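# Methods

This note documents the models, conventions and numerical choices behind
`mitocomp`, and what the synthetic-data tests do and do not demonstrate.

## Annotation model

Coordinates are 1-based inclusive throughout, matching GenBank flat files and
published annotation tables; the only half-open arithmetic lives inside the
Biopython interop layer.  A feature may wrap the circle's origin (stored with
`end < start`); at most one such feature is allowed per annotation, and the
linearisation used for intergenic spacers starts at position 1.  The spacer
between circularly adjacent genes is `downstream.start − upstream.end − 1`
(negative values are overlaps), and for a gap/overlap-complete annotation the
feature lengths and spacers sum to the molecule length — a checked invariant.

Gene names are mapped into one canonical vocabulary (`cox1…cox3`, `atp6/8`,
`nad1–6`, `nad4L`, `cytb`, `rrnL/rrnS`, `CR`, and 22 tRNAs with the
leucine/serine isoacceptors disambiguated as `trnL1/trnL2/trnS1/trnS2` by
their CUN/UUR and AGN/UCN codon classes).  Cross-genome comparison requires a
single namespace, so aliases cover the common GenBank spellings (COI, ND4L,
12S, `tRNA-Leu (UUR)`), single-letter order shorthand, and the recurrent
`tranV` typo for `trnV`.  Direction `F` maps to the heavy strand, `R` to the
light strand.

**Lenient versus strict parsing.**  Published tables are not always
internally consistent: the bundled crab annotation states a trnY span of
15,517–15,680 (164 nt) against a printed size of 64, a control region of
13,547–14,762 against a stated 616 nt, and a trnI that begins inside that
stated span.  Which value is authoritative cannot be decided from the table
itself, so the default mode keeps such rows, records the printed value in
`stated_size`, computes geometry from the coordinates, and emits structured
warnings; strict mode raises instead.  Nothing is silently corrected.

## Composition and skews

`AT skew = (A − T)/(A + T)`, `GC skew = (G − C)/(G + C)`; both are
scale-invariant, so counts and percentages give identical values.  Symbols
outside A/C/G/T are excluded from every denominator and tallied separately
(fractional IUPAC weighting was rejected: it cannot be validated against
published integer-free percentage tables).  A zero denominator raises a
dedicated error rather than returning 0 — an AT-only sequence has an
*undefined* GC skew, not a symmetric one.

Rounding for table output is half-away-from-zero at the displayed precision;
full precision is always retained internally.  The bundled 41-taxon
composition table illustrates why this matters: skews recomputed from the
1-decimal percentages reproduce every 2-decimal printed skew exactly, but 48
of the 71 skews printed at 3 decimals differ in the last digit (maximum
absolute deviation 0.0035 — the published values were evidently computed from
unrounded counts).  The sweep therefore *flags* such rows as rounding residue
rather than treating them as errors.  Two further data notes are preserved
without correction: the crab's prose composition (C 19.2%, G 11.8%) conflicts
with its table row (C 20.5%, G 12.1%), and only the table row is consistent
with the printed GC skew of −0.26; the stated "AT-rich region constituted
67.4% of the total nucleotides" describes the overall A+T content.

## Codon usage and RSCU

CDS extraction is strand-aware (light-strand genes are reverse-complemented
before codon splitting) and wrap-aware.  The genetic code is NCBI translation
table 5 (invertebrate mitochondrial): AUA = Met, UGA = Trp, AGA/AGG = Ser —
giving one 8-codon serine family — with stops UAA/UAG forming their own
2-codon family.  Codon keys use the RNA alphabet to match published tables.

Two bookkeeping rules make the totals exact:

* A CDS whose length is not a multiple of three ends in a truncated stop
  ("T"/"TA"); the trailing 1–2 nt are not a codon and are excluded from
  counts.  The 13 published PCG lengths (three genes truncated) then yield
  `Σ floor(length/3) = 3728` complete codons.
* Full stop codons *are* counted and carry RSCU like any family: the
  published stop counts (8, 2) give RSCU (1.6, 0.4) = (2·8/10, 2·2/10).

`RSCU_c = |F|·n_c / Σ_{c′∈F} n_{c′}`; a family observed zero times gets RSCU
0 for all members, flagged.  Every family's RSCU sums to its size before
rounding (asserted to 1e−9).  Start codons ATN, GTG and CTG are all accepted:
the literature records both GTG and CTG for *atp8* in the same genome, so a
mismatch warns rather than fails.

## Gene order and rearrangement analysis

An order is a signed circular permutation (sign = strand) over up to 38
elements; the control region is orderable (it relocates in some crustacean
rearrangements) but can be excluded by flag.  The Pancrustacean ground
pattern constant carries the conserved arthropod strand assignment.  The
published listing of that pattern omits *nad1*; the constant restores it
between *trnS2* and *trnL1*, where both the canonical pancrustacean
arrangement and the crab's own annotation place it — without it the gene
sets would not even be comparable.

`normalize` rotates cox1 to the front and, if cox1 is sign-negative,
reflects and sign-flips the whole order first, so the two possible reading
frames of a circle normalise identically.  Breakpoint distance counts signed
circular adjacencies of one order absent from the other, with each adjacency
canonicalised over its two strand readings; it is symmetric, zero exactly on
normalised equality, and a single-gene translocation always costs 3.

`detect_moved_genes` searches subsets of increasing cardinality (exhaustive
up to `max_set`, default 3 — published brachyuran cases involve one or two
moved tRNAs, and subset search is exponential) for the smallest set whose
excision leaves identical circular gene sequences; remaining sign
disagreements are reported as inversions.  Ties are broken toward tRNA-only
sets, then lexicographically, and **all** tied minimal sets are returned:
moving gene X in front of its neighbour Y produces the *identical*
permutation as moving Y behind X, so single-event recovery is only defined
up to this equivalence.  The simulator round-trip tests count an event
recovered when the true gene's singleton appears among the tied minimal
candidates; in sampled sweeps the tie-break picks it directly in ≈98–99% of
events.  Beyond the cap the result is flagged `complex` and carries only the
breakpoint distance.

The neighbor-joining tree over the breakpoint-distance matrix (scikit-bio's
NJ, taxa pre-sorted for deterministic ties) is a similarity summary of
arrangements only — deliberately not a reimplementation of sequence-based
Bayesian/ML phylogenetics, which is out of scope along with alignment,
alignment masking and model selection.

## Synthetic genome generator

`GenomeSpec` defaults are the published crab conditions: 15,580 bp, A+T
0.674, AT skew −0.01, GC skew −0.26, the ground-pattern gene order, the 13
published PCG lengths and start codons, truncated stops on cox1/cox2/cytb,
tRNAs of 60–75 nt, rRNAs of 1,328/827 nt.  Base probabilities come from the
first-order model `pA = at·(1+skew_AT)/2` (and analogously for the other
three) — the only composition structure the summary statistics constrain.

Three design choices matter for interpreting tests:

* **Quota sampling.**  Base and codon draws use largest-remainder
  apportionment of exact expected counts followed by a seeded shuffle, not
  i.i.d. draws.  The generator's contract is *controlled* composition, and
  multinomial noise alone would give the GC skew a standard deviation of
  ≈0.013 at this molecule length — larger than the ±0.01 recovery tolerance
  the generator is meant to guarantee.  Consequently generated genomes hit
  their composition targets to ≈0.001–0.002 and the residual randomness
  lives in the arrangement of bases, not their counts.
* **Strand- and stop-aware codon model.**  PCG bodies are drawn in coding
  orientation; light-strand genes use complemented base weights so that
  after reverse-complementation every gene contributes the target
  composition on the heavy strand.  Excluding the AT-rich stop codons from
  CDS bodies would bias composition by ≈1.5 percentage points of A+T, so the
  base weights are moment-matched (a short fixed-point iteration) to keep
  the stop-free codon distribution's marginal on target.
* **Layout closure.**  Features tile the circle in gene-order sequence with
  configurable spacers; the control region absorbs the remaining length, so
  the molecule length is met exactly and the geometry invariant (lengths +
  spacers = molecule length) holds by construction.  A layout with under
  50 nt left for the control region is rejected as infeasible.

What the generator does *not* emulate: substitution processes along a tree,
indels, codon autocorrelation, tRNA/rRNA secondary structure, and the
control region's tandem-repeat structure.  Passing tests therefore show that
the statistics and detectors are computed correctly and are mutually
consistent — not that they are robust to the sequence-level noise of real
records.

The TDRL simulator duplicates a contiguous block in tandem and deletes one
copy of each duplicated gene per a 1/2 loss mask (random from the seed if
unsupplied), never touching strand signs — the classic same-strand mechanism
for tRNA relocations.  Duplicating (trnF, nad5, trnH) and keeping trnH from
the first copy but trnF and nad5 from the second reproduces exactly the
observed crab arrangement (…trnE, trnH, trnF, nad5, nad4…), and the detector
recovers {trnH}.  Translocation and inversion simulators are single-event
primitives with no-op inputs rejected; multi-event histories beyond
single-event recovery are out of scope.

## Problem sizes and determinism

All headline computations run from printed-table inputs (41 composition
rows, 64 codon counts, 38 features) or from single 15.6 kb seeded genomes;
the simulator sweeps use 100 events per run.  Every random process flows
from one explicit `numpy` Generator seed — same seed, byte-identical output —
and the CLI exposes that seed directly.
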