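# Methods

`plastgap` implements the bespoke computational layer of a plastome
phylogenomics workflow: construction of the analysis matrix from a
whole-plastome alignment, scoring of indels as single evolutionary events
with slipped-strand-mispairing (SSM) attribution, parsimony-based
classification of each indel as a putative synapomorphy or homoplasy
against a reference tree, and a randomized outgroup-selection experiment
that asks whether the ingroup topology depends on outgroup choice. A
synthetic-data generator provides every input with known ground truth, so
the whole pipeline is testable at desk scale with no downloads.

## Coordinates and alphabet

All column coordinates are 0-based, half-open intervals. Sequences are
over `{A, C, G, T, N, -}`; IUPAC ambiguity codes are accepted and treated
as missing data, as is `N`. `?` on input is normalized to `N`; the NEXUS
match character `.` is rejected. Only `-` counts as a gap: ambiguity
codes never trigger gap-column removal, because the matrix-construction
rule removes positions *containing gaps introduced by alignment*, not
positions with sequencing uncertainty.

## Matrix construction (`plastgap.alignment`)

Plastomes are assumed arranged LSC + IRb + SSC with one inverted-repeat
copy (IRa) already omitted, or omitted via `excise_columns`, which deletes
the union of user-supplied column intervals (the same operation removes
regions containing inversions; inversion detection itself is out of scope
and intervals are user-supplied). `strip_gap_columns` removes every column
in which at least one row has `-`. Both operations return a `ColumnMap`
(surviving output column -> source column), so any derived matrix is
traceable to source coordinates, and stripping returns a `StripReport`
with the fraction of columns removed. These operations satisfy, and the
tests verify, a small algebra: stripping is idempotent; reading source
columns through the `ColumnMap` reconstructs the output exactly;
`n_after + (columns with >= 1 gap) == n_before`; and excision commutes
with stripping up to column multiset.

`pairwise_percent_difference` compares two aligned rows over the columns
where both characters are unambiguous bases, returning percent difference
or identity together with the compared-column count. This is the utility
used to check reported insertion divergences at full scale.

## Indel scoring (`plastgap.indels`)

Candidate events are maximal per-row gap runs, grouped by identical
footprint (same start and end). Runs touching a row's first or last column
are terminal and treated as missing data (unscorable assembly ends), never
as indels. Acceptance applies four criteria; when several fail, the first
in this fixed order is reported, making reports deterministic:

1. `too_short` — length below `min_length` (default 2 bp);
2. `mononucleotide` — the ungapped segment (read from the first fully
   ungapped row) is a single repeated base and at least one immediately
   adjacent base matches it (homopolymer-length variation is excluded
   regardless of length);
3. `ambiguous_overlap` — the footprint partially overlaps (including
   nests) a different footprint: such column ranges cannot be interpreted
   as single events, and both parties are rejected;
4. `autapomorphic` — fewer than `min_shared` rows (default 2) share the
   footprint. "Individuals" are alignment rows, so conspecific duplicate
   accessions count separately.

SSM attribution compares the per-column majority consensus of the
ungapped rows at the event interval with the equal-length windows
immediately upstream and downstream: `perfect` if either window matches
exactly, `near_perfect` if the best identity reaches
`ssm_identity_threshold`, else `none`. The 0.80 default operationalizes
"near-perfect", which the underlying protocol leaves qualitative; it is
configurable. Only immediately adjacent equal-length windows are
examined; longer-period repeats are out of scope. Windows truncated by
the alignment edge are skipped (both skipped gives `none`).

Region classification assigns each accepted event the class of the
feature with maximal column overlap, ties broken coding > intron > igs.
GFF3 `CDS` and `intron` features are read directly; intergenic spacers
are the complement. Accepted events become binary characters (1 = gap
present, i.e. segment absent; `?` for rows that are entirely N/ambiguous
across the interval). Polarity (insertion vs deletion) is *not* asserted
at cataloguing time; it is resolved downstream against the outgroup.

## Tree mapping (`plastgap.treemap`)

Characters are mapped a posteriori onto a reference tree; they are never
used in tree inference. The minimum number of state changes is computed
by a unit-cost dynamic program (Sankoff-style recursion), which for
binary characters is exact on arbitrary topologies including polytomies
— the classic set-intersection recurrence is only guaranteed on binary
trees. Missing leaves carry both states at zero cost and so impose no
constraint; the count is rooting-invariant (verified by exhaustive
enumeration on random trees in the tests).

Classification fixes polarity first: the derived state is the opposite of
the outgroup state when the outgroup rows agree and are scored, otherwise
the ingroup minority state (ties resolved to gap-as-derived). The
reported step count then constrains the root to the ancestral state, which
makes "one step" exactly equivalent to "the derived leaves form a rooted
clade (ignoring missing leaves)". A character is `synapomorphic` with one
polarized step and >= 2 derived leaves; `homoplastic` with >= 2 steps;
`autapomorphic` (reported, flagged, and counted separately) when the
derived state is confined to one leaf; `invariant_excluded` otherwise.
Characters shared by an ingroup clade *and* the outgroup fall out of this
rule as homoplastic-by-polarity rather than being silently repolarized.

Tabulation counts synapomorphies per named clade by exact leaf-set
equality of the supported clade (the MRCA leaf set of the derived
leaves), lists unmatched synapomorphies under their literal leaf sets,
and totals homoplastic characters separately.

## Outgroup jackknife (`plastgap.jackknife`)

Each iteration draws one representative per named outgroup pool
(uniform, independent across iterations by default; drawing without
replacement is available and requires pool size >= iteration count),
infers a tree for ingroup + drawn outgroups, prunes the outgroups, and
compares the ingroup topologies across iterations by unrooted
Robinson–Foulds distance; the congruence report carries the pairwise RF
matrix, an all-identical flag and the strict consensus. Per-bipartition
bootstrap supports are summarized as mean ± sample (n−1) standard
deviation across the iterations containing the bipartition.

The built-in backend is deliberately distance-based so the experiment
runs at desk scale: Jukes–Cantor distances over shared unambiguous
columns (p-distances >= 0.75 are capped), neighbor joining, and
nonparametric bootstrap supports from seeded multinomial column
reweighting (mismatch counts are precomputed per pair, so each replicate
is a matrix–vector product). A maximum-likelihood program can be wrapped
as an external backend (its command line recorded verbatim); ML inference
is never reimplemented. Per-iteration randomness derives from the master
seed plus a CRC of the drawn outgroup set, so a single iteration is
reproducible in isolation and identical draws yield byte-identical
analyses — with singleton pools every node has zero support variance by
construction.

## Synthetic data (`plastgap.simulate`)

The generator emulates the statistical structure the analysis assumes.

*Tree*: pure-birth (Yule) with waiting time Exp(k·λ) at k lineages and a
final wait with all n present, so the expected root height is
(rate/λ)·Σ_{k=2..n} 1/k in branch-length units; branch lengths are in
expected substitutions per site.

*Substitutions*: K80 (equal base frequencies, transition/transversion
ratio κ, default 2) with optional gamma rate heterogeneity, simulated
per branch with the closed-form transition probabilities. At κ=1 and long
branches pairwise difference saturates at 75 %, which the tests check.

*Indels*: a Poisson number of events per eligible branch, partitioned
into SSM, plain and mononucleotide types, lengths 2 + Geometric(p) − 1
(default p = 0.35, mean ≈ 3.9 bp). Events are placed by rejection
sampling with reserved windows covering the event and both flank windows,
so footprints never overlap or abut. SSM insertions copy each bearer's
own upstream flank (a tandem duplication); SSM deletions first write each
row's segment over its upstream flank, so the surviving rows retain a
perfect adjacent duplicate; plain events are resampled until flank
identity is below the SSM threshold and they are not
homopolymer-adjacent; mononucleotide events overwrite the interval and
one adjacent base with a single repeated base. Events are restricted to
branches whose descendant set excludes the designated outgroup leaf
(the first leaf of the smaller root-side clade) and has 2..n−2 members,
so every injected event is shared, polarizable and synapomorphic for its
branch — which is what makes exact-recovery oracles meaningful. Optional
terminal-gap masking emulates incomplete assemblies; an optional stress
mode substitutes bases in SSM flanks to push repeat identity below
threshold for negative tests.

Defaults are desk-scale study conditions: 20 taxa × 20 kb, rate 0.01
substitutions/site per unit time (few-percent tip divergence), SSM
fraction 0.47 (the scored-indel SSM share at full scale), mononucleotide
fraction 0.10, ≈ 60 events in total. Full plastome scale (135 kb) is a
parameter change, not a different code path.

What passing the simulation oracles does *not* show: the generator makes
the identical-footprint assumption true by construction, inserts no
alignment error, no inversion, no IR structure and no rate variation
across regions, and inherited insertions do not accrue later
substitutions. Exact recovery on synthetic data therefore validates the
scoring logic, not the behaviour of the criteria on ambiguously aligned
real plastomes — on real data the `ambiguous_overlap` rule and manual
adjudication dominate the discrepancy budget.

## Numerical and degenerate-input choices

* Rejection reasons are evaluated in a fixed documented order; taxon
  order inside events follows alignment row order.
* SSM consensus ties are broken by the earliest ungapped row.
* JC distances are capped at 5.0 substitutions/site at saturation.
* NJ negative branch lengths are tolerated (topology only is consumed).
* Sample (n−1) standard deviation is used for all ± summaries; a single
  observation reports sd 0.
* An all-gap alignment strips to zero columns without error; an event
  interval with no fully ungapped row cannot be SSM-assessed and raises a
  consistency error.
* Yule simulation labels leaves in tree traversal order (`t01`, `t02`,
  ...), so identical seeds give identical Newick strings.

## Problem sizes

The test suite and the acceptance script run the Fitch-oracle sweep at
200 trees × 20 characters (trees up to 10 leaves, exhaustive enumeration
up to 2^13 assignments), indel recovery at 20 taxa × 20 kb, and the
jackknife at 14 taxa × 20 kb × 16 iterations × 100 bootstrap replicates
— sizes chosen so the full pipeline exercises every code path in a few
seconds while the statistical checks (Yule height, saturation, recovery)
retain enough replication to be discriminating.

## Known limitations

* Indel polarity relies on the outgroup row; with no scored outgroup the
  minority-state heuristic can mispolarize characters whose derived set
  is large.
* The built-in backend is NJ on JC distances: adequate for congruence
  experiments on clocklike synthetic data, not a substitute for ML on
  real plastomes (wrap an external program for that).
* SSM detection examines only immediately adjacent equal-length windows;
  longer-period or interrupted repeats are not attributed.
* GFF3 handling maps only `CDS` and `intron` feature types; everything
  between features is an intergenic spacer.
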