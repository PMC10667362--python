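# Methods

## Scope and model

`nerdcall` operationalizes a biomarker pipeline for NER deficiency in
renal tumors.  Its core quantitative object is the per-sample exposure
to the COSMIC indel signature ID8, obtained by non-negative
least-squares (NNLS) refitting of an 83-channel indel catalog against a
fixed signature matrix.  The decision layer is two thresholds: ID8
exposure strictly greater than 5 calls NER deficiency, and a PTGR1
expression gate (inclusive, at the expression level of the A498 cell
line) narrows NERD samples to plausible irofulven responders.  The
package does not extract signatures de novo, does not call variants,
and consumes MSI status and pathogenicity annotations as inputs from
their dedicated external tools.

## Variant filtering

Eight predicates are applied per record, all inclusive exactly as
written: `FILTER == {PASS}`, `TLOD ≥ 6`, `NLOD ≥ 3`,
`NORMAL.DEPTH ≥ 15`, `TUMOR.DEPTH ≥ 20`, `TUMOR.ALT ≥ 5`,
`NORMAL.ALT ≤ 0`, `TUMOR.AF ≥ 0.05`.  Records with a missing tested
field are rejected with an `unevaluable:<field>` reason rather than
silently failed, so audits can distinguish "bad" from "unknown".
Multi-allelic sites are split per ALT allele before filtering, with AD
and per-allele AF apportioned from the caller's arrays; TLOD, declared
per-ALT by MuTect2, is taken per split allele.  The tumor allele
fraction is the caller's `FORMAT/AF` when present, otherwise
`ALT/depth`.

Sample-level selection proceeds in a fixed order: WGA, FFPE and MSI
flags first; then one sample per patient (lowest `preference_rank`,
ties broken by lexicographic sample id — the tie-break is this
package's own convention, since only the WGA-removal motivation for
the rule is externally specified); finally samples with fewer than 50
passing variants are dropped, because signature refitting is
unreliable below that count.  Every excluded sample carries a reason
code.

A deleterious mutation is an exonic SNV labeled Pathogenic or Likely
Pathogenic, any nonsense SNV regardless of label, or an indel labeled
Pathogenic/Likely Pathogenic.  ERCC-family status per sample is the
single deleteriously mutated gene among {ERCC2, ERCC3, ERCC6}, `multi`
for two or more, else `none`.

## ID-83 classification conventions

The 83 channels follow the published COSMIC layout: 1 bp
deletions/insertions by pyrimidine-strand base (A→T, G→C) and
homopolymer length (deletions 1..6+, insertions 0..5+ pre-existing
bases); ≥2 bp indels of size 2, 3, 4, 5+ by tandem-repeat copies
(deletions count the deleted copy, 1..6+; insertions count
pre-existing copies, 0..5+); and ≥2 bp single-copy deletions by
microhomology length (capped at size − 1 and at the 5+ bin).  Channel
identity is stored with these display semantics; the zero-based labels
used in signature files (`1:Del:C:0` … `5:Del:M:5`) are the serialized
form, and the reader reorders arbitrary row orders to this canonical
order.

Counting is made representation-independent by canonicalizing first:
shared prefix (anchor) and suffix bases are stripped, the record is
checked against the reference (a mismatch is a data error, an absent
contig likewise — silent skips would corrupt catalogs), and the indel
is left-aligned by repeated unit rotation.  All context scans then run
rightward from the left-aligned start:

* homopolymer length — run of the indel base in the reference,
  including the deleted base for deletions, excluding the inserted
  base for insertions;
* repeat copies — contiguous exact copies of the indel sequence;
* microhomology — the longer of the deleted sequence's prefix match
  against the right flank and suffix match against the left flank,
  strictly shorter than the deletion (a full copy is a repeat).

Left-alignment plus rightward scanning is one of several equivalent
conventions; it is deterministic, and the property tests check that
every shifted VCF encoding of the same physical indel classifies
identically and that classification is invariant under
reverse-complementing reference and variant.  Complex substitutions
(both alleles nonempty after anchor stripping) fit no channel; they
are excluded and counted, never force-classified.  SNVs are ignored by
the catalog.

## Refitting

Exposures solve min‖c − S·e‖₂ subject to e ≥ 0 via an active-set NNLS
solver; the problem is convex, so the optimum is global.  Exposures
stay in mutation-count units — no renormalization to the catalog total
is imposed, and the ID8 component is thresholded unrounded (a rounding
switch exists but is off by default).  Signature columns must be
nonnegative and sum to 1 within 1e-6.  Collinear columns trigger a
degeneracy warning and the solver's optimum is reported as-is.  The
refit accepts an optional signature subset; by default the full
supplied matrix is used.

## Decision layer

`nerd = id8 > 5` (strict) and `responder = nerd and ptgr1 ≥ cutoff`
(inclusive), both overridable.  Expression values are
log2(raw + pseudocount) with pseudocount 1; cohort and cell-line
tables must declare a shared normalization or the calibration refuses
to compare them, since FPKM and TPM values are not interchangeable.
The ERCC-enrichment test is a two-sided Fisher exact test on the 2×2
of (any deleterious ERCC mutation) × (NERD); sidedness is configurable
because only "Fisher exact test" is externally specified and two-sided
is the conventional default.  Degenerate tables (a zero margin) return
p = 1 with an undefined odds ratio; otherwise the conditional-MLE odds
ratio is reported.  Summary fractions are printed at 0.1% precision
(43/289 → 14.9%, 36/389 → 9.3%); when a pre-QC denominator is
supplied, the responder fraction is reported over both denominators
rather than guessing which one a given figure used.

## Synthetic cohorts

The simulator is the package's test bed and defines its study
conditions.  Reference contigs (default three, ≥30 kb) are built from
engineered, self-guarded motifs: homopolymer runs up to length 8,
tandem repeats of unit sizes 2–7, and microhomology-flanked unique
segments, at least 20–40 registered loci per channel, each bounded by
guard bases so that left-alignment and context scans cannot leak into
the surrounding spacer sequence.  `realize_variant` is the inverse of
the classifier by construction and round-trips 100% of channels.

Per sample, the indel count is Poisson (default mean 150, a free
parameter documented as such — exome indel burdens vary widely);
each indel draws a signature from the sample's mixture weights and a
channel from that signature's column, using the same 3-signature toy
matrix the refit consumes (ID1: 1 bp T insertions; ID2: 1 bp T
deletions; ID8: long deletions with 0–2 bp microhomology — disjoint
supports, hence linearly independent columns).  Default mixtures:
NERD samples {ID1 0.35, ID2 0.25, ID8 0.40}, background {ID1 0.54,
ID2 0.44, ID8 0.02}; the small background ID8 share reflects that
occasional long deletions occur without NER deficiency and makes the
classification task non-trivial near the threshold.  A planned
fraction of records (default 0.1, exact counts, cycling through the
eight predicates) violates exactly one filter predicate each, so
filter tests are deterministic.  PTGR1 is simulated directly in
log2(FPKM+1) units (avoiding a transcript-length model): two group
means (6.0 responder-like, 3.0 low; SD 0.8), a 0.6 probability of the
high group, and a calibration panel whose A498 entry is planted at
4.5.  Deleterious ERCC annotations ride on simulated SNVs at
per-group rates (0.25 NERD, 0.02 background).  Random streams are
split per purpose (reference, assignment, burden, channels, caller
statistics, expression), and everything — FASTA, VCFs, tables — is
byte-reproducible from the seed.

What the simulator does *not* emulate: read-level noise (caller
statistics are drawn directly, not from alignments), real exome
channel backgrounds (the toy matrix has disjoint supports; real COSMIC
signatures overlap and make refitting harder), expression–copy-number
linkage, and cross-platform expression harmonization.  Passing tests
therefore demonstrate correctness of the pipeline's logic and
estimator, not clinical performance on real cohorts.

## Verification sizes and frozen bounds

The validation suite runs at the following problem sizes, chosen as
the package's own test conditions: classifier round-trip 83 channels ×
50 realizations; left-alignment concordance over 500 shifted
representations; NNLS versus an independent projected-gradient solver
on 100 random catalogs (‖Δe‖∞ < 1e-6); ID8 recovery over 200 samples
at Poisson burden 200 and share 0.4 (≥95% of estimates within 3·√80 of
80 — a calibration run measured 99.5%, mean 79.9); Fisher exact versus
full hypergeometric enumeration for every 2×2 table with N ≤ 60 (the
probability-tie convention uses a 1e-7 relative tolerance; maximum
observed deviation 7e-15); end-to-end recovery of planted NERD labels
over 20 seeds of 40-sample cohorts, mean balanced accuracy ≥ 0.90 (a
calibration run measured 0.96 mean, 0.89 minimum — the shortfall cases
are background samples whose 2% ID8 share drifts above five
deletions, an intended ambiguity of the generative model).

## Numerical and degenerate-input choices

Zero catalogs refit to zero exposures with zero residual (not an
error).  Empty cohorts cannot be summarized.  Missing PTGR1 entries,
absent reference cell lines, absent ID8 columns and unknown signature
subsets are configuration errors.  Exposure scale equivariance holds
to 1e-9 relative; perturbing any exposure by ±1e-3 (clipped at zero)
never reduces the residual.  Percentages are rounded half-to-even at
0.1%.

## Known limitations

Real use requires the FASTA matching the alignments the VCFs were
called on; classification against a mismatched build fails loudly on
REF checks.  The microhomology definition evaluates both flanks and
takes the maximum; after left-alignment the left flank cannot match,
so this matters only for records fed in without normalization.  The
PTGR1 gate assumes the cohort and calibration tables share a
normalization and refuses mixed units, but it cannot detect
harmonization errors hidden behind identical unit tags.  The
Fisher-test p-value convention for probability ties follows the
standard implementations (1e-7 relative tolerance); alternative tie
conventions can differ in the last decimals on highly discrete
tables.
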