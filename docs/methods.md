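# Methods

## Benchmark classification

Every curated reference orthologous group (RefOG) is compared against one
predicted group: the one maximizing coverage |prediction ∩ members|.  Ties
are broken toward the smaller predicted group (favouring precision) and
then the lexicographically smaller group id, so matching is deterministic.
A RefOG that intersects no prediction is matched to nothing and all its
members count as missing.  Two RefOGs may map to the same predicted group;
each classification is computed independently, so the summed TA+MA basis
can exceed the number of distinct reference genes — reports carry both
numbers (`totals` and `n_reference_genes`) explicitly.

The partition identities TA ∪ MA = members, TA ∪ FA = matched group, with
all three categories pairwise disjoint, are asserted on every
classification at run time.

Recall is 100·|TA|/(|TA|+|MA|), rounded to the nearest integer percent by
default (pass `ndigits=None` for the raw value).  Per-species error tables
count each FA/MA gene once under the species token parsed from its
identifier (the substring before the first `"."`, configurable).  Datasets
are compared with a two-sample, two-sided Kolmogorov–Smirnov test on the
per-species error vectors; the asymptotic p-value is the default (suitable
for ~100-species samples) with an exact small-sample option.

## Function-based conservation scores

All three tests share one scheme: define family-specific conserved feature
tokens over a RefOG's members at a 75% threshold, then score each gene by
how many conserved tokens it carries.  The comparator at the threshold
differs by test and this is deliberate: domain content and EC terms use a
strict comparator (*more than* 75% of members), neighbour families an
inclusive one (*at least* 75%).  Both are overridable.  Members without
annotation stay in the denominator, lowering every fraction; genes without
annotation or genomic placement score 0 rather than being excluded, so
category summaries remain comparable across TA/FA/MA (empty categories are
reported as absent, never as a fabricated zero mean).

* **Domain content** is a set of unique domain tokens, not an architecture
  vector; repeats deduplicate.
* **Gene order** inspects ±5 genes around each member (an operon-scale
  window; windows truncate at linear replicon ends and wrap on circular
  replicons).  Neighbour genes are clustered into families by single
  linkage over pairwise homology hits that pass E ≤ 1e-5 *and* an aligned
  length of at least 90% of the shorter gene; components are named by their
  lexicographically smallest member so tokens are deterministic.  A gene's
  score counts conserved families represented in its window, each family
  once regardless of how many window genes belong to it.  The e-value
  cutoff is read as 1·10⁻⁵ (the conventional intent of "10e-5") and is
  configurable.
* **Enzymatic activity** expands each EC number hierarchically —
  `EC:1.2.3.4 → {EC:1.2.3.4, EC:1.2.3.-, EC:1.2.-.-}` — down to two
  retained digits (no single-digit term), then applies the same
  conserved-token scheme to the expanded sets.  Expansion is a closure:
  expanding an expansion adds nothing.

A predicted group is called **"accurately inferred"** by a test when the
test could not flag any false assignment: every FA gene scores at least as
high as the worst-scoring TA gene (vacuously true with no FA; false by
convention when there are FA genes but no TA genes to compare against).
No decision rule is canonical here; this minimum-over-TA rule is the
conservative choice — any separable false assignment breaks the call.

## Tree operations

Gene trees are rooted on the largest clade consisting purely of
distant-outgroup leaves (ties: lexicographically smallest leaf set), with
the root placed at that edge's midpoint so leaf-to-leaf path lengths are
preserved; trees without distant outgroups fall back to midpoint rooting
(implemented directly on the longest leaf-to-leaf path).  Candidate
orthologous groups relative to the ingroup LCA are the maximal
pure-ingroup clades of at least `min_og_size` (default 2) leaves; smaller
clades go to a xenolog-candidate pool.  Within an ingroup clade,
duplications (in-paralogs) do not split groups; only intervening outgroup
leaves do.  Polytomies are allowed throughout; "sister" means all other
children of the parent.  Support values are carried but not filtered on by
default (`collapse_low_support` is available as a pre-pass).

Xenolog flagging operationalizes "nested within the close and distant
outgroups": a maximal pure-ingroup clade is flagged when its sister is
pure outgroup with a **majority of distant-outgroup** leaves, and the
nearest `min_flank` (default 3) leaves **beyond that sister**, walking
toward the root, are majority outgroup.  Two asymmetries are intentional.
First, a clade sister to the close outgroup is never flagged: that is the
normal species ladder, and close-outgroup-boundary signals are ambiguous
(phylogenetic signal versus noise), so they are deliberately left to human
review.  Second, the flank looks past the sister because a transfer *out*
of the ingroup plants a stray outgroup clade next to a perfectly vertical
ingroup clade — from topology alone the transfer direction is
unidentifiable, and the surrounding territory is the best local evidence.
A clade whose parent is the root is exempt (that is just the rooting).
The rule is conservative by construction: on simulated histories without
transfers it flags nothing, and with transfers it recovers roughly a third
of true xenologs at ~75% precision under moderate rates — missed cases are
dominated by transfers from the close outgroup, which the rule declines to
call by design.  All outputs are candidates; final curation remains human.

Bit-score recruitment offers the literal reading of "within the range" —
min ≤ score ≤ max over known members, boundaries inclusive — as the
default, plus a `floor` mode (score ≥ min) since scores above the member
maximum are biologically stronger matches.

## Simulator

The paper-facing analyses need ground truth; the simulator provides it
with the most transparent models that produce the relevant phenomena, and
no more:

* **Gene families** evolve along an ultrametric species tree by a
  Gillespie birth-death-transfer process: per-lineage exponential waiting
  times for duplication (λ), loss (μ) and transfer (η), rates per unit
  branch length.  Transfers copy the lineage onto a uniformly random
  contemporaneous branch, which is why an ultrametric tree is required
  whenever η > 0 (enforced).  At speciations lineages enter both
  daughters.  Defaults: λ = μ = 0.3, η = 0.15 on trees of depth 1.0 —
  modest event counts per family, desk-runnable in milliseconds.
* **Ground truth**: a gene copy present at the reference node (the ingroup
  LCA, node label `ING` on generated trees) founds one true OG; extant
  ingroup genes descending from it through speciations and duplications
  only belong to that OG.  A gene whose ancestry entered the ingroup via a
  transfer from outside is a xenolog and belongs to no OG; transfers
  within the ingroup keep the donor's OG.  The event log records every
  lineage segment, so this derivation is replayable from the log alone.
* **Species trees**: generated with an ingroup (LCA at age 0.6), a close
  outgroup (split 0.75) and a distant outgroup (split at the root, depth
  1.0), with random ultrametric topology within each clade — a cartoon of
  the ingroup/close/distant sampling structure the curation protocol
  assumes.  Defaults of 20 ingroup and 6+6 outgroup species keep runs in
  seconds.
* **Genomes**: one circular replicon per species; an ancestral order over
  families is drawn once, in-paralogs sit adjacent at their family's slot,
  and each gene independently keeps its ancestral position with
  probability `p_syn` (default 0.95), else it is relocated uniformly.
  This per-gene relocation model was chosen over an adjacency-breaking
  model for bookkeeping transparency; at `p_syn = 1` all non-xenolog
  genomes share the ancestral order exactly.  Xenologs are *always*
  relocated — the empirical signature that makes gene order a xenolog
  detector.
* **Annotations**: each family carries 1–4 domain tokens and, with
  probability 0.6, one four-digit EC number; members inherit each domain
  with probability `q_dom` (default 0.95) and the EC with probability 0.9.
  Xenologs inherit their family's architecture, which is precisely why the
  domain test cannot see them (`q_dom = 1` reproduces that masking
  scenario by construction).
* **Hits**: all within-family pairs receive e-values at or below 1e-30
  with 95% coverage of the shorter gene, plus a few cross-family decoys
  between 1e-4 and 1, so single-linkage clustering recovers the family
  partition exactly (a round-trip that is itself tested).  There is no
  sequence-level simulation anywhere — scores and e-values are fabricated
  at the hit level.
* **Error injection**: each true group receives at most one structural
  perturbation — split off a strict minority (expected MA), merge with an
  intact partner (mutual expected FA), contaminate with fabricated foreign
  genes (expected FA), or drop members (expected MA) — drawn from
  configurable probabilities (defaults 0.15/0.10/0.15/0.15).  Restricting
  to one action per group and minority splits keeps the best-coverage
  match unambiguous, so the recorded expected TA/FA/MA counts are exact
  arithmetic, not estimates; the benchmark must recover them to the gene.
  Optionally each family's xenologs are added to its largest group's
  prediction, emulating homology-based predictions that cannot see HGT.

Identical configuration and seed give a bit-identical world; all
sub-generators derive from one seed sequence.

## What the simulations do and do not show

The simulator reproduces the *mechanisms* the analyses target — vertical
descent versus transfer, operon-like synteny, inherited annotations,
split/merge/contamination error modes — with clean separations (e.g.
within-family hits are unambiguous, annotations have no false positives,
genomes have no rearrangement hotspots).  Passing tests therefore
demonstrate that the classification algebra, the scoring rules and the
tree logic are correct and that the qualitative orderings (gene order
flags masked xenologs where domains cannot; denser species sampling helps
distance-based clustering) follow from the modelled mechanisms.  They do
not calibrate absolute error rates of any real database, and real
annotation noise, alignment artefacts and tree-estimation error are out of
scope by design (alignment, tree inference and HMM search are upstream
tools, not re-implemented here).

## Numerical and degenerate-input choices

* Thresholds are compared exactly as stated (strict vs inclusive); the
  75%-of-4-members boundary case is part of the test suite.
* Empty reference members, empty member score maps, empty KS samples and
  malformed EC strings or gene identifiers raise immediately, naming the
  offending token; empty predicted intersections are a valid "no match".
* Readers reject structurally invalid input with file and line number
  rather than repairing it; duplicate membership rows collapse with a
  warning, duplicate genes across groups are an input error.
* All writers sort keys and rows, so outputs are diff-stable.
* Test problem sizes (10–14 ingroup species, 6–10 families, 20–100 seeds)
  were chosen so the full suite and the acceptance script each run in a
  few seconds on one core while keeping every Monte-Carlo check
  well-resolved.

## Known limitations

* Xenolog flagging sees only one tree at a time; transfer direction is
  unidentifiable from topology alone, and close-outgroup transfers are
  deliberately not called.  Recall is correspondingly conservative.
* The best-coverage match is per-RefOG; no global one-to-one assignment
  between reference and predicted groups is attempted.
* OrthoXML support is read-only and single-level (nested groups are
  flattened with a warning), matching the benchmark's single-phylogenetic-
  level scope.
* The simulator's uniform-recipient transfer model has no donor-recipient
  distance bias, and its genomes have no gene-length or strand structure;
  both are irrelevant to the quantities measured but would matter for,
  e.g., realistic operon evolution studies.
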