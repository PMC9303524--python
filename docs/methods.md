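# Methods

This note documents the models and procedures implemented in `paralogon`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmarks do and do not establish.

## Synteny neighborhoods

Coordinates are ordinal gene ranks per chromosome (0-based); nothing in the
analysis uses physical distance or strand, only co-chromosome membership
and flanking order.  A linkage-group family joins the neighborhood of
paralog *P* when, in **at least one** reference genome, any of its loci
shares a chromosome with *P*'s anchor locus.  The permissive any-locus rule
is the default (a strict single-copy mode exists via
`define_neighborhoods(..., single_copy_only=True)`); the one-genome rule is
deliberately generous because each descendant genome loses and rearranges
independently.  Query families in exactly one neighborhood take its label;
in two or more, `SHARED`; in none, `OTHER`.  Families absent from the query
genome are excluded from the denominator, so category counts partition the
query-present families exactly.  A family found on several query
chromosomes counts as "on" each of them when contingencies are built.

`SHARED` and `OTHER` families are *not* dropped from contingency tables:
they populate the no-label row.  This makes the on-chromosome marginal
(a + c) a property of the chromosome alone, identical across the four
focal labels — an internal consistency check that the bundled published
tables satisfy (52, 43 and 12 for the three TCF-bearing lamprey
chromosomes).

Duplicate query paralogs are disambiguated by flanking-gene sharing: each
is assigned to the reference paralog maximising the number of shared
flanking families, with ties reported rather than broken.  The flanking
window is supplied by the caller; ten genes a side is a sensible default
for chromosome-scale assemblies.

## Unconditional exact test

Enrichment is tested unconditionally: group sizes are fixed, the common
success probability π is a nuisance.  Two conventions are load-bearing and
were chosen so that the package reproduces the published worked examples:

* **Orientation.** The two binomial groups are the on-chromosome and
  off-chromosome family totals (column margins a + c and b + d), success =
  carrying the focal label.  This is the convention of the R package used
  in the original analysis (and of scipy's implementation).  The row
  orientation is available (`fixed_margin="rows"`), and the core
  `unconditional_exact_test(x1, n1, x2, n2)` is orientation-free.
* **Sidedness.** The headline value is the one-sided (greater) tail; the
  published table values reproduce under it to < 1%.  The two-sided
  (|T| ≥ |T_obs|) value is always computed alongside.

The statistic is the pooled Wald score; outcomes with zero pooled variance
(all successes or all failures) are assigned T = 0, which places them in
every two-sided rejection region of a degenerate observed table and in no
strict one-sided region — the convention that keeps p ≡ 1 for null tables.
The nuisance maximisation uses 1001 evenly spaced grid points by default
plus bounded local refinement (Brent) around the grid argmax; refinement
can only raise the p-value, keeping the test conservative.  Binomial pmf
tables are cached per (group size, grid), so repeated tests at fixed
margins (the simulation studies) cost only a masked tensor contraction.

Validity: under 2000 simulated null tables at the published group sizes
the two-sided rejection rate at α = 0.05 is ≈ 0.045–0.05 — at or below
the nominal level, as an unconditional exact test must be.  Correctness:
the implementation matches an independent exhaustive-enumeration oracle to
10⁻⁹ on every table with group sizes ≤ 6, and scipy's implementation on
the published tables.

The genome-wide placement test is an exact binomial tail, computed as an
explicit pmf sum (verified against the regularized-incomplete-beta
identity) with minimum-likelihood two-sided variant.  Null probabilities
per chromosome are supplied by the caller — gene-content proportions are
the natural choice, a uniform option exists — and the convention used is
recorded in the result.  No multiple-testing correction is applied by
default (raw p-values are reported); a Bonferroni flag exists.

## Diagnostic residues

A residue set R (|R| ≤ `max_set`, default 2 — two-residue diagnostics
occur in practice) is diagnostic for a subfamily at a column when it
covers at least `min(ceil(min_support·n), n − allowed_exceptions)` of the
n members and the fraction of non-members carrying any residue of R is at
most `max_leakage` (default 0).  Defaults tolerate one divergent member
(`allowed_exceptions = 1`), since single divergent sequences are expected
in real alignments.  Gaps never count as evidence and gap-majority columns
are skipped.  Columns are 1-based within the supplied block; the scanner
does not locate domains — block boundaries are the caller's choice.  Note
that with only two subfamilies the complement of a diagnostic column is
itself diagnostic; interpretation needs three or more groups.

## Gene-structure characters and ancestral reconstruction

Gene models are declarative: ordered exons with motif annotations, isoform
splice paths, alternative transcription starts.  Fused exons of particular
lineages are written as compound labels (`X-XI`).  `extract_features` maps
a model to 15 binary characters deterministically; the non-obvious codings:

* `ISOFORM_B` — some splice path reaches exon XIV without passing exon
  XII/XII′: a C-clamp-less terminus.  This structural reading (rather than
  the literal isoform letter) gives the single-isoform TCF7L1 gene a
  B-like terminus, which its architecture in fact has.
* `ISOFORM_E` / `C_CLAMP` — some path joins the CRARF-bearing exon XII to
  exon XIV, i.e. a complete C-clamp; single-isoform invertebrate genes
  qualify.
* `ISOFORM_N` — a path truncating before the first HMG exon.  In the
  bundled matrix this is split into two lineage characters (LEF1-type and
  TCF7L2-type N) because their homology is unresolved; each then costs one
  independent gain and neither reaches the root.
* `DELTA_N_ISOFORM` — an isoform starting at a non-first exon.
* `EXON_III_MET` is a per-gene flag (`met33`), not derivable from exon
  topology.
* Characters the underlying data cannot call (partial cyclostome models)
  are forced to `unknown` via an explicit per-gene list.

Reconstruction is exact unordered binary parsimony, implemented as 0/1
Sankoff dynamic programming with a downward and an upward pass, which
handles polytomies and unknown leaves (wildcards) exactly and yields, per
node, the full set of states attainable in *some* most-parsimonious
reconstruction; non-singleton sets are reported `ambiguous`, never
resolved arbitrarily.  Scores equal exhaustive enumeration on all trees
with ≤ 6 leaves (1000 random cases in the suite).  The event narrative
comes from one canonical optimal labeling chosen by a secondary cost that
prefers the fewest gains, then the parental state; its change count equals
the parsimony score character by character.

**Dollo alternative.** Convergent gain of a complex motif is biologically
implausible, but plain parsimony will happily infer two gains when losses
are plentiful.  `dollo_states` places a single gain on the edge above the
most recent common ancestor of the present leaves, with free losses below.
It is off by default; only the merged pre-WGD report consults it, and only
for characters whose optimal labelings all require ≥ 2 gains.

**Uncertain lineage placement.** The cyclostome genes attach as a polytomy
at three alternative points — the vertebrate root (pre-1R), the TCF7L1–L2
stem, or the TCF7–LEF1 stem (post-1R options) — reflecting their
unresolved phylogenetic position.  The merged pre-WGD model reports a firm
state only when every placement (and the Dollo alternative, where
triggered) agrees; otherwise `placement_dependent` or `ambiguous`.  On the
bundled matrix this yields: CRARF exon, complete C-clamp, B- and E-like
termini and the exon III methionine firmly present; LVPQ and the two
N-isoform characters firmly absent; exon IV, SxxSS, CtBP, exon XII′ and
exon XIII question-marked — the question marks land exactly on the
components whose ancestry genuinely depends on where the cyclostomes
branch.

## Synthetic genomes

`simulate_wgd_genomes` models: an ancestral linkage group of `n_families`
(default scenarios use 156, the size of the real lamprey ortholog set),
duplicated `n_rounds` ∈ {1, 2} times; each paralogon maps to its own
chromosome per reference genome (optionally two paralogons fused onto one
chromosome in the first genome); rediploidization retains each
family × paralogon copy once, ancestrally, with `retention_prob` (default
0.3); each descendant genome then loses surviving copies independently
with `genome_loss_prob` (default 0; the pipeline's default scenario uses
0.1); retained copies translocate to a uniformly chosen non-home
chromosome with `translocation_rate`.  One designated anchor family always
survives everywhere, untranslocated — its copies are the anchors.  Gene
order within chromosomes is a seeded shuffle.  Randomness uses spawned
`SeedSequence` streams in a documented order (retention, translocation,
placement) with fixed-shape draws, so any stage can be re-derived
independently; identical config + seed gives byte-identical output.

The query lineage either inherits the reference paralogon structure
(`shared_2R`: a copy exists where some reference genome retained it, minus
query-lineage loss at `loss_prob`) or re-duplicates independently
(`independent_dup`: retention ignores the reference sorting).  A
translocation knob with an `intact_paralogons` exemption builds the
power-study scenario: one paralogon left intact among fully scattered
ones.

What the generator does **not** emulate: loss anti-correlation between
ohnolog copies (real rediploidization keeps *exactly one* copy for most
families, so the real SHARED fraction, ~7%, is lower than any independent-
Bernoulli model produces at matched retention — defaults give a
majority-single-neighborhood split but a heavier SHARED tail);
chromosome-scale rearrangement structure (translocations are uniform,
memoryless); any sequence evolution (alignment blocks are consensus +
planted columns + iid noise, no substitution model, no indels).
Consequently, passing benchmarks show the inference chain is *correct
under its own assumptions* (exact recovery in the no-noise limit for
every seed; the true neighborhood–chromosome pair attains the minimum
p-value in ≥ 95% of enriched simulations) — not that real fractionated
genomes are this easy.

## Bundled data

The published contingency cells, category counts and a per-family
assignment consistent with every cell are bundled as fixtures
(`paralogon.datasets`); all p-values are recomputed at run time, never
stored.  The alignment blocks are **synthetic reconstructions**: the
original supplementary alignment is not redistributed, so the blocks carry
only the documented column structure (diagnostic residues at columns
2/20/22/43/64 of the HMG box, the position-33 methionine of exon III, the
described cyclostome residue mixtures) on an arbitrary seeded background.
Column-level results reproduce; sequence-level ones cannot and are not
claimed.  The gene-model YAML encodes composite per-subfamily
architectures as described in the comparative literature, with unknowns
marked where cyclostome data are partial.

## Numerical and degenerate-input conventions

* Nuisance grid endpoints π ∈ {0, 1} are included; their degenerate pmfs
  contribute only to regions containing the all-0/all-n outcomes.
* p-values are clipped to [0, 1]; two-sided minimum-likelihood sums use a
  1 + 10⁻⁷ relative tolerance when comparing pmf values.
* Empty neighborhoods, empty assignments, degenerate margins (an empty
  group), out-of-range columns, and unknown labels raise `ValidationError`
  rather than returning defaults; readers raise `ParseError` naming the
  offending line.
* Parsimony tie-breaks: canonical labelings prefer fewer gains (secondary
  cost 10⁻⁶ per gain), then the parental state; reported states ignore the
  canonical choice and come from the exact MPR sets.

## Problem sizes used by the shipped studies

Test-suite and acceptance-script studies run at the sizes of the real
worked example (156 families, 4 reference genomes, 4 paralogons): 50 seeds
for exact no-noise recovery, 200 seeds for enrichment power, 2000
replicates for the null-validity study, 1000 random ≤ 6-leaf cases for the
parsimony oracle, and the full ≤ 6 × 6 outcome space for the exact-test
oracle.  The complete suite runs in well under a minute on one CPU.
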