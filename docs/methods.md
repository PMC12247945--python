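# Methods

## The problem

A gene proven essential in one species is routinely assumed to do the same
job in its relatives.  Presence/absence of the ortholog is the cheapest
falsifier of that assumption: if the gene is not in the genome, the network
must work differently.  But absence calls from homology search alone are
dominated by artifacts — diverged sequence below detection thresholds,
genes split across assembly contigs, loci at contig ends.  The package
therefore layers three detection strategies of increasing stringency and
validates every stage against simulated clades with planted ground truth.

## Tiered presence/absence inference

**Alignment model.**  All protein comparisons are optimal Smith–Waterman
local alignments (Biopython's pairwise aligner) under BLOSUM62 with affine
gaps: a gap of length *g* costs `open + g·extend`, defaults open 11,
extend 1 (the standard protein-search defaults; the underlying searches in
this kind of study rarely publish their parameters, so these are explicit,
configurable assumptions).  `X` scores 0 against everything.  Two percent
identities are carried per hit, both anchored to *full* sequence lengths
(the convention used by ortholog databases): identical residues divided by
query length, and by target length.  Hits imported from 12-column tabular
files carry alignment-length identity and are converted on import.
Equal-scoring hits are ordered by higher target identity, then target id,
making every ranking deterministic and input-order independent.

**Tier 1 (identity threshold).**  A gene is present iff its best forward
hit reaches 25% identity on either the query or the target length
(inclusive).  "Either" is deliberate: the threshold rule this emulates
does not specify which of the two conventions it applies to, and the
permissive reading matches confidence-inclusive ortholog listings; a
`require_both` switch gives the strict reading.

**Tier 2 (RBBH).**  Pure reciprocity, no identity threshold: the two
rules are kept in separate tiers on purpose, as independent detection
strategies.  Ranking is by alignment score (a bitscore analog).  Orthology
is treated as one-to-one; paralog expansions are out of scope.

**Tier 3 (synteny).**  For each tier-2 absence, the three nearest
reference genes per side anchor the locus.  Anchors are mapped into the
target via the RBBH map; the contig carrying most mapped anchors is
examined.  Geometry drives the verdict:

- both sides anchored on one contig → a candidate span between the
  innermost anchors.  Anchor order is checked against the reference order
  *orientation-agnostically* (whole-block inversions count as conserved
  synteny — the question is neighborhood retention, not orientation);
- a side whose reference anchors are truncated by the reference contig
  end is bracketed by the target contig boundary instead (otherwise genes
  at reference contig edges could never have their absence confirmed);
- one-sided mappings, anchors scattered across contigs, or a contig end
  within `end_margin` (default 1,000 bp, configurable) on the focal side
  of the innermost anchor are flagged; flagged geometries can never
  confirm an absence.

Every candidate region — the span, or on broken neighborhoods the
focal-ward terminal segments of anchor-bearing contigs — is scanned by
translating all six frames and locally aligning each to the focal protein.
A hit scoring ≥ `min_fraction` (default 0.3) of the protein's
self-alignment score rescues the gene (`present_rescued`); a clean,
order-consistent, unflagged span with no hit is `absent_confirmed`;
anything else is `unresolved`.  The flags are raised only when they bear
on the focal locus: a contig end lying *beyond* the outer anchors of a
fully bracketed span says nothing about the focal gene and does not block
confirmation.  Tier 3 therefore only ever rescues or demotes tier-2
absences, never creates new ones — asserted at run time in the pipeline.

**Reporting collapse.**  `present_rescued` → present; only
`absent_confirmed` → absent; `unresolved` → present by default
(conservative: reported absences are exactly the verified class), with a
strict mode keeping unresolved visible as a third state.  Percent
denominators default to the focal gene-list size, independent of extra
tracked genes.  Percentages round half-away-from-zero at the per-table
precision.

## The clade simulator

`simulate_clade` emulates the data this pipeline is designed for, not
general genome evolution.  A reference species carries `n_genes` genes
(default 50) of `gene_len_codons` codons (default 100) on one chromosome
in fixed order with fixed `intergenic_len` spacing (default 1,000 bp),
random strands.  Each other species independently:

- loses each gene with `loss_prob` (default 0.1) — a clean deletion;
- substitutes amino acids at `subst_rate` per site (default 0.1), each
  substituted residue re-encoded by a random codon of the new residue.
  Substitutions are uniform over non-identical residues — no rate matrix —
  because downstream stages consume percent identity, not phylogeny;
- is fragmented by a Poisson breakpoint process (`frag_break_rate` per
  100 kb, default 0.5; scaled for the ~65 kb toy chromosome so that runs
  actually exercise the machinery), each breakpoint landing inside a
  surviving gene with `gene_split_prob` (default 0.5).  A split gene keeps
  truncated annotation rows on both contigs but is dropped from the
  proteome, emulating gene models broken across contig ends — an
  annotated partial protein would still form a reciprocal best pair and
  the contig-end artifact the tier-3 stage exists to catch would never
  arise.

Not simulated (out of scope): rearrangements (the synteny test assumes
conserved local order), indels, codon-usage bias, recombination,
demography.  Passing tests on this generator demonstrate the pipeline's
logic on clean planted truth; they do not measure sensitivity on real,
repeat-rich, rearranged genomes.

**What the planted truth can and cannot promise.**  Confirmed absences
are *sound* by construction: across 50 seeded default clades the test
suite requires zero confirmed absences that are not planted losses and
that no split gene is ever confirmed absent.  Completeness is conditional:
a planted loss whose own neighborhood is damaged — a breakpoint inside an
innermost flanking anchor, or all three flanking genes on one side
themselves lost — is correctly demoted to `unresolved`, because the gene
could genuinely sit in the assembly gap.  The suite therefore asserts
exact recovery for every loss whose neighborhood is intact (a predicate
computed from the planted truth, not from pipeline output), and
soundness unconditionally.  Raising the fragmentation rate raises the
unresolved count, never the confirmed-absent count.

## McDonald–Kreitman test

Sites are classified from an aligned allele sample plus one ancestral
coding sequence.  A position with two segregating states is polymorphic;
its effect is judged by substituting the minor state into the
sample-majority codon (codons with several segregating positions are
decomposed per position against that majority context, matching common MKT
tool behavior).  A monomorphic position differing from the ancestor is a
fixation, judged in the ancestral codon context.  A position both
segregating and ancestrally mismatched counts as polymorphic only — a
segregating site is not a fixation.  Positions with three or more states
are skipped with a warning; they are rare at the sample sizes involved and
no principled pathway decomposition is attempted.  Tie-breaks (50/50
sites) resolve major/minor lexicographically, consistently between the
frequency and the codon-context computations.

The frequency filter removes polymorphisms with minor-allele frequency
strictly below the cutoff (default 0.12): "less than 12%" excluded, 12%
itself kept.  Filtering is monotone in the cutoff and never touches
divergence counts.

Statistics: Pearson χ² *without* Yates correction — on the worked-example
table (Ps=42, Ds=0, Pn=27, Dn=3) the uncorrected statistic is 4.383 where
4.390 has been printed for the same table by a webtool whose exact
variant is not recoverable; the corrected value (2.24) is far from both,
so the uncorrected form is clearly the right reading and the 0.16%
discrepancy is documented rather than chased.  χ² is computed from the
closed form and cross-checked in tests against an independent generic
contingency routine; the Fisher exact p is two-sided.  α and NI are
reported as undefined (not errors) when their denominators vanish.  A
majority-rule parsimony ancestor (ties to the outgroup) is provided for
when no likelihood reconstruction is available; likelihood ancestral
reconstruction itself is out of scope and the ancestor is otherwise an
input.

## Fertility effect sizes

`bootstrap_mean_diff` resamples each group with replacement (default
5,000 resamples, the common default of estimation-statistics tools; the
underlying figures this mirrors do not state theirs) and reports the BCa
95% interval of the mean difference, via scipy's bootstrap with an
explicit degenerate-data guard (constant groups → point interval).
Significance is the interval excluding zero.  `permutation_test` shuffles
group labels (default 10,000 permutations) and reports the two-sided
plus-one-corrected p, so the smallest attainable p is 1/(n_perm+1) —
reporting p < 10⁻⁴ requires at least 10,000 permutations.  The test suite
checks empirical coverage of the BCa interval on 1,000 equal-mean
negative-binomial pairs (95% ± 2%; measured ≈ 94%) and super-uniformity
of the permutation p under label exchangeability.

## Problem sizes

Clade-scale checks run on 50-gene, 4-species clades (100-codon genes,
1 kb spacers) across 50 seeds; MKT recovery uses 10 alleles × 442 codons
(a bam-sized coding sequence) across 20 seeds; alignment correctness is
checked against an exhaustive enumeration oracle on sequences up to
length 8, where enumeration is exact and cheap.  These sizes exercise
every code path at full statistical strictness while keeping the whole
suite under a minute of alignment work.

## Numerical and degenerate-input choices

- Alignment score ≤ 0 → "no hit" (`None`), including all-`X` inputs.
- Empty sequences, non-alphabet characters, ragged alignments, lengths
  not divisible by 3, all-zero contingency tables, empty count groups:
  immediate `ValueError`/`KeyError` with a specific message; malformed
  tabular rows report their line number.
- Overlapping innermost anchors produce a degenerate (possibly empty)
  span rather than an error; a span shorter than a codon scans to "no
  hit".
- All simulators draw from a single seeded generator; identical
  parameters give byte-identical emitted files.
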