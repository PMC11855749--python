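# Methods

`redexome` models the screening of an exome-sequenced patient cohort for
pathogenic short tandem repeat (STR) expansions, end to end: a locus
catalogue with expanded/normal cutoffs, read-level evidence at each
locus, a simplified diploid repeat genotyper, a deterministic triage of
predicted expansions, and cohort-level genotyping-rate and coverage
analytics stratified by exome capture kit and read length. Because
patient-level sequencing data cannot be redistributed, the package
includes a seeded synthetic cohort generator that reproduces the
statistical structure such screens exhibit; all stochastic components of
the pipeline are exercised against it.

## The locus catalogue

A repeat-expansion disease (RED) locus is described by its gene, repeat
motif (1–12 bp over A/C/G/T/N; `N` covers printed degenerate motifs such
as the GCN poly-alanine repeats), a pathogenic cutoff in repeat units and
in base pairs, a genomic region class (coding, intron, 5′UTR, 3′UTR),
optional interruption motifs, and a zygosity requirement. The shipped
catalogue lists 26 neurological RED loci: 12 coding, 7 intronic and 7 in
UTRs.

Invariants and conventions:

* For ordinary loci the two cutoffs are redundant and the loader enforces
  `cutoff_bp = cutoff_units × |motif|`; 22 of the 23 thresholded shipped
  rows satisfy it exactly.
* The boundary is **inclusive**: an allele of exactly `cutoff_units` is
  expanded. The printed cutoff is treated as the minimal abnormal size,
  the convention used by short-read STR variant catalogues. A per-locus
  `cutoff_inclusive` switch exists for loci where a strict reading is
  preferred; an optional premutation band could be layered on the same
  mechanism but is not modelled — a single expanded/normal boundary is
  used throughout.
* Three loci (PHOX2B, NIPA1, PABN1) have no established single cutoff and
  carry `NA`. They are loaded and reported but excluded from expansion
  calling and triage; any cutoff arithmetic on them raises a dedicated
  no-threshold error rather than producing a number.
* RFC1 is a *motif change* locus: the pathogenic AAGGG motif replaces the
  reference motif, so "expansion" means *any* pathogenic-motif allele
  (unit cutoff 0) and its printed bp value is exempt from the product
  rule. The `motif_change` flag is the loader's whitelist for such rows.
* Coordinates are 0-based half-open internally; the VCF writer converts
  to 1-based POS. The shipped intervals are synthetic placeholders sized
  like a typical reference repeat tract (they are what the depth
  arithmetic needs); real genome-build coordinates are a user-supplied
  column, and no liftover is attempted.
* Interruption motifs default to CAT for the ATXN1 CAG run and empty
  elsewhere; GLS carries a biallelic zygosity requirement (a single
  expanded GLS allele is flagged, not counted as diagnostic).

Detectability is pure geometry: spanning reads can size an expansion
exactly iff `cutoff_bp + 2·min_flank ≤ read_length`, where `min_flank`
is the anchoring sequence required on each side of the tract (default
10 bp). Otherwise only lower bounds are observable at the locus.

## Synthetic cohort generator

The generator emulates the features of a multi-kit exome cohort that
drive repeat-genotyping performance, and nothing else:

* **Kits.** Each capture kit has a read length, a per-locus target map
  and two mean depths: 60× on target, 3× off target (0× for the
  focused-design preset). The four-kit default preset (SureSelect
  V6-like at 150 bp, V4-like at 125 bp, TruSeq-like at 100 bp,
  Nextera-like at 75 bp with zero off-target depth) targets coding loci
  broadly — with ATXN2 untargeted everywhere and HTT/CACNA1A dropping
  out of the smaller designs — keeps most intronic loci off target, and
  captures UTR loci on the two larger designs. The preset is
  illustrative, not a reproduction of any vendor's design.
* **Genotypes.** Normal alleles are drawn per locus from a rounded
  normal distribution centred on the reference tract length (sd 3
  units, clipped below the cutoff); each allele is independently
  expanded with a small probability (5×10⁻⁴ per allele baseline, raised
  to a few per thousand at the loci that dominate referral-cohort calls:
  ATXN1, DMPK, GLS, HTT). Expanded sizes are uniform between the cutoff
  and 10× the cutoff (50–400 units for the motif-change locus). With
  probability 0.5 an expanded allele at an interruption-prone locus
  receives one interrupting unit at a uniform interior position —
  reflecting that a large fraction of apparent ATXN1 expansions in
  screening data are CAT-interrupted and non-pathogenic.
* **Reads.** Per sample × locus the read count is Poisson with the
  kit/locus mean depth. Each read picks an allele uniformly, lands at a
  uniform offset with ≥1 bp tract overlap, and is classified
  geometrically: *spanning* (covers tract plus `min_flank` on both
  sides; yields the exact unit count), *in-repeat* (entirely inside the
  tract; in-tract sequence of full read length), or *flanking*
  (everything else; carries its observed in-tract sequence). A read is
  high quality with probability 0.95 — a single aggregate Bernoulli
  stand-in for per-base quality, which the review rules treat as the
  unit of "a high-quality read". There is no GC/capture bias, no
  alignment simulation, no substitution-error model and no FASTQ/BAM
  output; conclusions about real data are therefore limited to the
  geometric and depth-driven effects the generator does model.

One integer seed drives everything; equal seeds give byte-identical
output files.

## Repeat genotyper

The caller is a deliberately simple evidence-counting genotyper in the
style of short-read STR callers:

* Spanning-read unit counts are clustered; a neighbouring count within
  ±1 unit is absorbed only when its support is ≤25% of the peak's
  (stutter is a minority species — unconditional merging would collapse
  genuine adjacent heterozygotes). The two best-supported clusters are
  the alleles; one cluster with no longer-allele signal is a homozygote.
* In-repeat reads bound the long allele below by
  `⌊read_length/|motif|⌋` units. A flanking read showing `k` complete
  in-tract units bounds an allele at `≥ k` units — not `k+1`, and only
  when `k` exceeds the largest spanning-explained allele, because a
  flanking-classed read may in fact have covered the whole tract
  without sufficient anchoring flank; the more aggressive reading
  systematically fabricates expansions at small-cutoff loci (CSTB at 4
  units, RFC1 at 0). When the best bound exceeds the largest spanning
  allele the long allele is reported as a lower bound and rendered
  `>N` (e.g. `12/>50`).
* Locus coverage (LC) is total locus-attributable bases over the
  reference interval length: a spanning read contributes at least the
  full interval (a contracted allele aligns as a deletion, not as
  missing coverage), flanking/in-repeat reads contribute their in-tract
  bases (expanded-allele reads thereby stack depth on the interval, as
  repeat-trapped reads do in a real pileup).
* Filter: `NoCall` with zero reads, `LowDepth` when caller LC < 10
  (a conventional minimum for a confident diploid genotype,
  configurable), `PASS` otherwise. Genotyping-rate metrics count `PASS`
  only.
* The pipeline feeds the caller only quality-passing reads while pileup
  LC is computed over all reads, so caller-reported coverage is
  systematically at or below pileup coverage — the same asymmetry seen
  between caller VCF coverage fields and BAM-derived depth.
* No confidence intervals, no graph realignment, no paired-end rescue:
  at loci whose cutoff exceeds the read length the caller can only
  produce bounds up to `⌊read_length/|motif|⌋` units, so very large
  expansions are undetectable at short read lengths. This is a declared
  simplification; real callers recover some such events from paired-end
  in-repeat read counts.

## Triage of predicted expansions

Every call predicting an expanded allele (exact or bound ≥ cutoff) is
reviewed by a stateless rule engine over four inputs: `n_hq_support`
(high-quality spanning/flanking reads consistent with the expanded
allele — spanning within ±1 unit of it, flanking/in-repeat implying more
units than the short allele explains), `n_max_reads` (high-quality
full-read-length in-repeat reads of pure motif, i.e. reads at the
maximum measurable expansion), `L = read_length > cutoff_bp` (strict;
equality falls to the short-read branch), and interruption status:

* **discard** if a catalogued interruption motif is observed, in motif
  frame, on a read supporting the expanded allele (interruptions on
  normal-allele reads are reported but not discarding — the rule is
  about the pathogenicity of the expanded tract);
* else **pass** if `L` and (`n_hq_support ≥ 2` or `n_max_reads > 10`,
  both read strictly);
* else **borderline** if (`L` and `n_hq_support == 1`) or (not `L` and
  `n_hq_support ≥ 2`);
* else **fail**.

The two support counts are disjoint (in-repeat reads tally only as
maximum-expansion reads); otherwise the `>10` clause could never fire
independently. The engine is verified cell-by-cell against an
independently written brute-force truth table over 160 enumerated
states, and is monotone: more support never demotes a call.

Interruption scanning decomposes each read's in-tract sequence into
motif-frame units, trying every frame offset and keeping the one with
the most motif matches (reads start mid-unit); partial edge units are
ignored.

## Cohort metrics

* **Expansion summary**: per-locus triage category counts (region-class
  order) with a totals row. The fail percentage is
  `100 × fail / (pass + borderline + fail)` to one decimal —
  interruption discards are bookkept separately from the reviewed-call
  denominator.
* **Validation bookkeeping**: only pass/borderline calls may be
  dispatched for PCR; the summary reports tested/confirmed counts by
  category and a diagnostic yield of `100 × diagnostic / confirmed`
  rounded to the nearest integer (`NA` when nothing is confirmed).
* **Genotyping rate**: per locus × kit × read length,
  `100 × n_PASS / n_samples` to one decimal, with loci at 0% included;
  mean pileup and caller LC accompany each stratum. "Rate" is defined on
  the caller's filter, not on triage outcome.
* **Read-length trend**: mean rate per region class (coding / intron /
  UTR, the two UTR classes collapsed) across read-length strata with a
  non-strict monotonicity verdict; at saturating depth the series may be
  flat, which counts as non-decreasing.
* **Coverage comparison**: per locus × kit mean pileup vs caller LC and
  their ratio, flagged if the ratio ever exceeds 1.

## Numerical and testing choices

* Percentages are rounded to one decimal (integer for diagnostic
  yield); LC values to two decimals. Ties in allele clustering break
  toward the smaller allele.
* Tests and the acceptance script run cohorts of 4 kits × 100–250
  samples × 26 loci and a three-read-length trend cohort of 100 samples
  per stratum — sizes at which the law-of-large-numbers checks
  (Poisson depth means, recovery fractions) are stable at fixed seeds.
* The exact-recovery check conditions on an a-priori geometric
  criterion: each true allele must have ≥5 *expected* spanning reads
  (computable from depth, read length and allele size under the uniform
  placement model). An allele that produced no spanning read cannot be
  sized exactly by any caller, so an unconditional exact-recovery claim
  near the resolvability boundary would measure read-placement luck,
  not caller quality. Under the condition, recovery is ≥99%; expansion
  *detection* (triage pass/borderline) is checked separately under the
  weaker spanning-resolvability condition.
* Degenerate inputs: empty evidence → NoCall; empty catalogue or kit
  list → config error; zero samples → empty outputs without error;
  division guards render undefined percentages as `NA`/NaN rather than
  raising.

## Known limitations

* The synthetic kit presets and per-locus expansion probabilities are
  plausible, not calibrated to any real kit or cohort; absolute
  genotyping rates from the simulation are not comparable to rates
  measured on real exomes (which reflect capture chemistry, GC bias and
  alignment artefacts the generator omits).
* The caller's lower-bound rule cannot represent bounds beyond one read
  length, so genotypes like `12/>150` at 100 bp read length (reachable
  with paired-end information) are out of scope.
* Triage reproduces a visual-inspection protocol as deterministic
  rules; the original protocol's judgment calls (e.g. what counts as a
  high-quality read) are encoded as the explicit thresholds above, and
  any ambiguity is resolved in the strict direction.
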