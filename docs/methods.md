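# Methods

This note records the models, parameter choices and numerical decisions
behind `estsurvey`, and what the synthetic-data validation does and does not
establish about real surveys.

## Redundancy statistics

A library of `n` high-quality reads clustering into `d` distinct sequences
has empirical coverage `ĉ = 1 − d/n` and discovery rate `n/d`; the identity
`discovery = 1/(1 − coverage)` is exact and is enforced to floating-point
precision. The Good–Turing form `ĉ = 1 − n₁/n` (Susko–Roger), driven by the
singleton count `n₁`, instead estimates the probability that the *next* read
resamples an already-seen gene. The two answer slightly different questions
and disagree on finite samples; both are implemented, with the empirical
form as the default because it is the one that per-library clustering
summaries print. The Good–Turing estimator's bias against the true
resampling probability is checked by simulation (lognormal abundance
profiles, multinomial sampling at n = 5,000): mean absolute bias is below
0.01, which is the property that justifies using it for library triage.

Display rounding is 4 decimals for coverage and 3 for discovery
(round-half-even); full precision is kept internally and in the returned
DataFrames.

## Quality trimming

Trimming operates on error probabilities `e = 10^(−Q/10)`.

* **Bracket rule** (default max error 0.001 = Q30): strip bases from both
  ends until the terminal bases meet the bound. Interior bases above the
  bound are not touched by this rule.
* **Window rule** (default one window: length 10, max mean error 0.063):
  an interval is valid when every in-window mean meets the bound; intervals
  shorter than a window length must meet the bound on their whole extent.
  The kept interval is the longest valid interval, leftmost on ties.

The composed `trim_read` searches for the longest interval *inside the
bracket interval* that satisfies every window rule **and** whose terminal
bases meet the bracket bound. Requiring clean terminal bases of the final
interval (rather than literally composing bracket-then-window) is a
deliberate design choice: it makes trimming idempotent — re-trimming a
trimmed read is a no-op — and makes the result exactly equal to an
exhaustive search over all constrained intervals, which is how the test
suite checks it (random reads up to 200 bp against a brute-force oracle).
Raising any quality score never shortens the kept interval.

The pass gate — some contiguous run of ≥ 100 kept bases with mean Phred
≥ 20 — reads "average high-quality score over at least 100 bases" as a mean
over a contiguous run, the simplest reading that yields a per-read boolean.
It is evaluated in O(n) with a prefix-sum/min-scan.

Vector and adapter trimming are out of scope; the simulator emits
vector-free reads, and real inputs are assumed pre-screened.

## Clustering stand-in

Real surveys assemble with a dedicated assembler and this package consumes
its outputs (ACE contig membership, or plain membership TSVs). For synthetic
data a single-linkage clusterer links reads sharing ≥ 3 distinct canonical
(strand-collapsed) 16-mers and takes the transitive closure — deterministic
and input-order independent, with dense cluster ids assigned by each
cluster's smallest read id. K-mers that are ambiguous or repeat-like (all
but two of the period-q base comparisons matching, for any period q ≤ 4)
are excluded from the index; microsatellite-derived k-mers are otherwise
shared between unrelated genes carrying the same motif, and this exclusion
plays the role repeat masking plays ahead of a real assembly. On simulated
surveys (inter-gene identity that of random sequence) the clusterer recovers
the true number of sampled genes within 2%, which is sufficient because the
downstream statistics consume only cluster counts. It is *not* an assembler:
no consensus, no overlap alignment, and it will merge genes that share long
exact tracts.

## DSN normalization kinetics

The paper-level description of normalization — denature, reassociate under
second-order kinetics, degrade the double-stranded fraction — is modeled
minimally: for composite exposure θ = k·C₀·t, the surviving single-stranded
fraction of a transcript with share `pᵢ` is `1/(1 + θ·pᵢ)` (ideal
second-order Cot kinetics, no cross-hybridization between distinct genes),
followed by renormalization:

    qᵢ ∝ pᵢ / (1 + θ·pᵢ)

This map preserves abundance ranks, never increases the max/min spread,
never decreases Shannon entropy, and flattens to uniform as θ → ∞ — so a
gene's share can be reduced at most `n_genes · pᵢ`-fold. θ is not
measurable from the published protocol (enzyme dilution was tuned per
tissue), so it is *calibrated*: `calibrate_theta` root-finds θ on [0, 1e12]
(Brent's method, xtol 1e-12) so that a chosen transcript's share falls by a
requested fold, and reports unreachable targets (beyond the flattening
limit) as errors. Calibration followed by normalization round-trips the
requested fold to well within 0.1% across folds 1–100.

## Synthetic survey generator

The generator emulates the study conditions of a multi-tissue Sanger EST
survey with DSN-normalized libraries:

* **Abundances**: lognormal with σ = 2.0 over 2,000 genes by default,
  normalized to sum to 1. This puts the dominant transcript at a few to
  ~12% of the pool — the regime where a non-normalized library shows a
  dominant transcript near 4% and where a 40-fold reduction of it is
  reachable (flattening limit `n·p_top` ≳ 55 across seeds). σ = 0 gives a
  uniform profile for calibration tests.
* **Transcripts**: random uniform-base sequences, mean 900 nt (sd 250,
  min 300), two haplotypes per gene differing only at planted SNP offsets;
  a CDS occupies roughly the middle 60% (≈15% 5'UTR, ≈25% 3'UTR).
* **Planted SSRs**: exact tandem repeats of primitive 2–4 nt units (e.g.
  AC, AAT, AGAT), ≥ 24 nt, planted in the 5'UTR/ORF/3'UTR with weights
  0.30/0.24/0.46 (the regional distribution such surveys report), with
  flank guards so the planted coordinates are the maximal tract.
* **Planted SNPs**: Poisson(1) per gene; allele B is a transition with
  probability 0.5 by default (configurable, e.g. 2:1 for transition-biased
  mixes); haplotype B is sampled per read at frequency 0.5 by default.
* **Reads**: 5'-anchored with a small geometric start offset (p = 0.5),
  normal lengths 600 ± 100 nt clipped to [100, 800]; qualities
  `Q(pos) = 45 − 0.04·pos + N(0, 2)` clipped to [2, 60]; substitution
  errors injected per base with probability exactly `10^(−Q/10)`. One
  integer seed drives a single generator threaded through all sampling, so
  a given seed and configuration reproduce the FASTQ byte for byte.

Because simulated reads carry no indels, a cluster's multiple alignment is
obtained positionally (each read padded with gaps to transcript
coordinates); real-data realignment is out of scope. The truth table also
records, per read, the kept interval the default trim policy produces, the
transcript start offset and the haplotype, enabling end-to-end checks.

What the generator does **not** model: vector/adapter contamination,
chimeras, chromatogram-level artifacts, PCR amplification bias, indel
sequencing errors, homologous gene families (inter-gene identity is that of
random sequence). Consequently the synthetic pass rate of the default read
model is near 100% — the published ~85% pass rate of real surveys includes
failure modes (short inserts, vector-only clones) outside this model — and
clusterer adequacy results say nothing about assembling paralogs. Passing
tests demonstrate the *analytics* are correct, not that real libraries are
this clean.

## Completeness classification

"Complete within 10 amino acids" is read as a distance: 5'-complete iff
`subject_start − 1 ≤ 10`, 3'-complete iff
`subject_length − subject_end ≤ 10` — the only reading under which a hit
starting at residue 1 has distance 0. Protein length bins are
[1, 250], [251, 500], [501, 750], [751, 1000], [1001, ∞). Multi-hit queries
collapse to the best hit (lowest e-value, then highest subject coverage,
then lexicographic subject id) so each query is counted once; classifying
all hits is available by flag. Reverse-frame hits (subject start > end in
the tabular file) are excluded with a warning — frame handling belongs to
the upstream search. Subject lengths come from a companion table because
the standard 12-column hit format does not carry them.

## Microsatellite mining

Perfect tandem repeats only, by default: unit sizes 2–4, minimum tract
24 nt, tracts broken by N, each tract reported at its smallest generating
unit (a dinucleotide run is never reported as its tetranucleotide double),
homopolymer-equivalent units excluded, overlaps resolved
longest-then-leftmost-then-smallest-unit. Detection is linear-time per unit
size via run-length scans of the lag-q equality mask; the suite checks exact
equality with a brute-force enumerator on random sequences and exact
recovery of every planted tract. Canonical motif naming takes the
lexicographic minimum over all rotations of the unit and of its reverse
complement (so GT → AC, TTA → AAT). Region calls use the tract midpoint
against the CDS interval. Imperfect (mismatch-tolerant) repeat scoring is
deliberately not the default: the mining parameters a published survey
states (unit sizes, minimum length) fully specify only the perfect-repeat
variant, and only that variant is oracle-testable.

## SNP candidates

Any column of a cluster alignment with ≥ 2 distinct A/C/G/T bases is a
candidate; gaps and N never count as alleles, and indel polymorphism is out
of scope. The reliability filter keeps columns where at least two bases
each appear ≥ 2 times (the standard two-observations-per-allele rule).
Columns with ≥ 3 passing alleles are kept but reported as *multiallelic*
and excluded from the transition/transversion summary — published filtered
counts decompose exactly into transitions + transversions, implying a
biallelic treatment, but the handling of rarer multiallelic columns is never
stated, so they are surfaced rather than silently dropped or misclassified.
No minimum column depth is imposed beyond the allele-count rule itself.

## Numerical and interface conventions

All internal coordinates are 0-based half-open; 1-based coordinates appear
only at the tabular-hit ingestion boundary (subject coordinates kept
1-based inclusive, as in the format) and in the VCF-like export (documented
in its header). Quality scores are integers in [0, 60]; FASTQ is Phred+33,
written by a dedicated emitter so outputs are byte-stable. Every output TSV
begins with a comment line declaring its coordinate convention; every
pipeline run writes a JSON manifest echoing all resolved parameters.

## Validation scales

The test suite runs the oracle-equivalence suites on 1,100 random instances
(400 trimming, 400 SSR, 300 variant-calling), the Good–Turing bias check on
100 simulated libraries of 5,000 reads, and planted-feature recovery plus
the binomial filter-pass prediction (clusters of depth 10, minor-haplotype
frequency 0.3, 200 clusters) on a bundled 2,000-gene / 3,000-read synthetic
survey. These sizes were chosen as the smallest that make the statistical
assertions sharp (3σ bands on proportions need a few hundred trials); the
whole suite completes in well under a minute on one CPU.

## Known limitations

* The clusterer is a counting stand-in, not an assembler; gene families and
  long shared repeats will merge.
* The DSN model ignores cross-hybridization and assumes a single composite
  exposure; θ is a calibrated effective parameter, not a rate measurement.
* Completeness assumes forward-frame protein hits and 5'-sequenced queries.
* The SSR miner's default perfect-repeat mode undercounts relative to
  mismatch-tolerant miners on real (imperfect) repeats.
* Trimming assumes per-base qualities are trustworthy; it does not model
  systematic miscalls.
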