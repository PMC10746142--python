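# Methods

## The inference problem

Given short-read resequencing of individuals from a focal lineage and a
closely related reference lineage, all mapped to a common annotated
genome, the package infers changes in the focal lineage's gene
repertoire from the depth signal alone (loss, duplication, copy number),
from cross-species alignments (unitary pseudogenes, protein indels), and
from per-tissue differential-expression tables (cross-organ consistent
regulation). Read mapping, alignment construction and DE fitting are
upstream of the package: it consumes depth tables, GFF3, FASTA/MAF and
DE TSVs.

All in-memory coordinates are 0-based half-open; GFF3's 1-based
inclusive convention is converted at the I/O boundary and nowhere else.
Strand never affects depth aggregation; it matters only when extracting
CDS sequence.

## Depth classification and the loss caller

Per individual, each coding site is classed

- HIGH if depth > ½ × that individual's mean coding depth,
- LOW if depth < 3 reads,
- MID otherwise.

The "average coverage" denominator is the mean over all annotated coding
sites of that individual (the quantity being classified); whether it
should instead be genome-wide is not derivable from the method
description, so the mean is a per-call argument. When the mean is below
6 a site can satisfy both rules; LOW wins, because read absence is the
conservative signal for a loss screen. HIGH uses strict >, LOW strict <.
Sites missing from a depth file but inside annotated CDS are depth 0,
not skipped; individuals with zero mean coding depth are excluded with a
warning.

A site is a species-specific lost site (SLS) when it is HIGH in all
reference individuals and LOW in all focal individuals. The
all-individuals quantifier is the default; both quantifiers are
relaxable to fractions for noisy cohorts. A gene is a candidate loss
when SLS cover ≥ 40% of its coding length (inclusive boundary).

## Duplication calling and copy number

Per-site depths are divided by the individual's mean coding depth before
comparison, which cancels library-size differences; comparing raw
averages (the behaviour on depth-matched cohorts) is available with
`normalize=False`. A site is a high-copy site (HCS) when the mean
normalized focal depth strictly exceeds 1.5× the mean normalized
reference depth. Sites with reference mean 0 cannot enter the ratio and
are excluded and counted separately. Candidate duplications have HCS
over ≥ 50% of the CDS.

Copy number is `round(reference_copies × gene_depth_ratio)` with
half-away-from-zero rounding and a floor of 1, where the gene ratio is
the ratio of summed normalized focal to reference depth over the gene.
The model assumes multi-mapping collapse: reads from tandem copies pile
onto the single annotated locus. Note a mechanical bias: an expansion
inflates the focal individuals' own mean coverage, shrinking the
normalized ratio by a factor ≈ 1 + (f−1)·L_gene/L_coding; at desk scale
(200 genes) this is ~2% and the integer estimate is unaffected.

## Unitary pseudogenes

Stage 1 (locus presence): from MAF blocks or per-gene aligned FASTA, the
coverage of a gene for species X is the fraction of its CDS positions at
which X's row is non-gap. Candidates need coverage ≥ 0.70 for at least
one reference species and ≤ 0.30 for the focal species. The 0.30
"absent" bound quantifies a qualitative criterion and is configurable.

Stage 2 (ORF disruption): the focal CDS row is walked through its
pairwise alignment against an intact ortholog (validated: length
divisible by 3, no internal stop, standard genetic code TAA/TAG/TGA
only). Maximal indel runs whose length is not a multiple of 3 are
frameshift events; in-frame indels are not events. Premature stops are
found by translating the ungapped focal sequence directly in its own
frame, so a frameshift's downstream consequences are detected exactly
and a pair of compensating indels that restores the frame creates no
spurious stops. Start loss and stop loss are separate events. The intact
fraction is the first event's 1-based codon position over the ortholog's
codon count (a stop substituted at codon 10 of 100 gives 0.10); an
event-free gene is intact with fraction 1.0.

## De novo gene screen

Four independent predicates: depth absence (> 50% of coding sites with
depth < 10 in every reference individual — both thresholds are
arguments, since the depth-10 rule presumes ~30× coverage), outgroup
homology < 0.4, expression (max tissue TPM ≥ 1), ORF completeness. The
candidate set is order-independent; the canonical order
depth → homology → expression → ORF only selects the primary rejection
reason (cheapest evidence first).

The homology fraction is the union of CDS positions covered by
local-alignment hits over the CDS length, maximized over outgroups. The
built-in matcher marks exact k-mer hits on either strand; k defaults to
15 because at k = 11 chance collisions against a few hundred kb of
unrelated sequence already cover most of a random CDS, a behaviour no
extension-and-evalue-filtered local aligner shows, whereas at k = 15 the
per-k-mer collision probability is ~3×10⁻⁴ and identical copies still
score ~1. Real-data hit tables (query, target, qstart, qend, identity)
can be imported instead.

## Lineage-specific protein indels

A column is specific when all non-focal rows carry the same character
and the focal row differs (residue mismatch or one-sided gap). Maximal
runs of ≥ 3 specific columns are reported (inclusive ≥ 3 by default; a
strict > 3 switch exists because the method has been stated both ways),
classified as deletion (focal gapped), insertion (non-focal gapped) or
substitution run. A region is kept only if the 5 columns on each side
have mean pairwise identity ≥ 0.90 across all rows (including the focal
row by default; excludable); windows truncated by the alignment edge
fail. Reported regions are therefore maximal, disjoint, and
flank-validated. Consistency across focal individuals is an optional
flag given per-individual aligned rows, not an automatic filter.

## Cross-tissue expression consistency

DE indicators are +1 when log₂FC ≥ 1 and adjusted p < 0.05, −1 for the
mirrored down case, 0 otherwise; missing values become 0 with a warning.
The consistent set is the intersection across ≥ 2 tissues and shrinks
monotonically as tissues are added.

The independence test makes the "DE in one organ says nothing about DE
in another" assumption explicit: the statistic is the observed count of
all-tissue-consistent genes, the null permutes each tissue's indicator
column independently (preserving per-tissue DE rates, destroying
cross-organ association), and the p-value is one-sided with add-one
correction, `(1 + #{null ≥ obs})/(n_perm + 1)`, with ties counted
conservatively (≥). The p-value is in (0, 1] and reproducible under a
fixed seed; an all-zero matrix returns p = 1 with a warning.

## The simulator: what it emulates and what it does not

The generator's defaults are the study design they stand in for: 200
genes, 8 focal + 5 reference individuals, 30× mean depth, 6 tissues.
Per-site coding depth is Poisson around each individual's mean — the
simplest count model that reproduces the HIGH/MID/LOW behaviour.
Planted losses collapse focal depth to Poisson(0.3) capped at 2 (always
LOW); losses are depth collapse rather than sequence removal because the
callers consume depth only. Duplications scale focal depth by the
extra-copy factor (fractional factors model expansions of multi-copy
families). De novo genes are the mirror image: depth collapse in the
reference individuals, a guaranteed expressed tissue, and
compositionally skewed (AT-rich) sequence so they share no seeds with
GC-balanced outgroups. Pseudogene recipes (substitution count, deletion
lengths) are applied to a pairwise CDS alignment against the intact
ortholog; if a recipe contains no frameshifting deletion, three
substitutions are spent writing TAA into an undeleted middle codon so
the planted gene is disrupted by construction. Protein alignments carry
the planted indel in the focal row with background substitutions sparing
the planted region and its 5-column flanks ("embedded in conserved
context" is part of the planted signal, and is what the flank gate
requires). DE tables give planted consistent genes log₂FC ∈ [1, 4] and
p < 0.05 in every tissue over an independent per-tissue background rate
(default 0.2).

Not modelled: GC bias, mappability, paralog cross-mapping, real intron
splice signals, overdispersion beyond Poisson, correlated expression
structure. A green truth-recovery test therefore establishes that the
decision rules are implemented correctly and separate the planted
signal from Poisson sampling noise at ~30× — not that the thresholds are
robust to mapping artefacts on real data.

All outputs are byte-identical under a fixed `rng_seed`; each simulation
operation draws from its own seed stream so generating one fixture type
does not perturb another. The package is single-threaded NumPy, so
results are trivially independent of thread count.

## Numerical and design choices

- Boundaries follow the stated rules exactly: SLS ≥ 0.40, HCS fraction
  ≥ 0.50 and ratio strictly > 1.5, coverage ≥ 0.70, deletion depth
  strictly < 10 and fraction strictly > 0.50, homology strictly < 0.4,
  TPM ≥ 1, DE |log₂FC| ≥ 1 and p strictly < 0.05.
- Copy-number rounding is half-away-from-zero (4.5 → 5), not banker's.
- Multi-transcript genes collapse to the longest summed CDS; overlapping
  CDS within one transcript is a validation error.
- Call tables are deterministically ordered (descending evidence, then
  gene id) and carry a provenance comment (version, seed, config hash).
- Degenerate inputs fail loudly and early: empty CDS, ragged alignments,
  zero reference individuals, non-finite depth ratios, ortholog rows
  with internal stops.

## Known limitations

The loss caller cannot distinguish true deletion from divergence-driven
mapping failure; the upstream mappability check that guards against this
is outside the package, and candidates are exported for external
confirmation (synteny, re-alignment). Duplication calls do not resolve
breakpoints or distinguish tandem from dispersed copies. The pseudogene
module does not detect processed retrocopies and uses only the standard
genetic code. The permutation test conditions on per-tissue DE rates;
it does not model gene-level expression correlation across species.
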