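# Methods

## Problem and model

A per-run protein summary lists entries `<N, TopID, Acc, Prot, Gene, Rest>`:
a within-run group identifier, the group's representative (top/master)
protein, the accession, protein name, gene symbol(s), and arbitrary further
columns. The package links the groups of many such summaries by a purely
set-theoretic rule: two groups are related iff they share an accession, and
global groups are the transitive closure of that relation over all processed
runs. No assumption is made about which member of a group was truly present,
about scores, or about sequence similarity — the linkage reflects exactly the
ambiguity the upstream software reported.

The merge is implemented as a union-find over accessions rather than the
literal repeat-until-fixpoint loop; the contract is the connected-component
postcondition, which the test suite verifies against an independent naive
fixpoint merge on hundreds of random instances. `is_connected` exposes the
connectivity definition (direct overlap or a chain of connector sets) as a
graph-connectivity check, used to validate that every global group is the
union of the connected local groups it contains.

### Code assignment

The algorithm only requires codes to be distinct. For incremental workflows
codes should also be *stable*, so: an unchanged or extended group keeps its
PGC; when groups merge, the smallest (oldest) participating PGC survives; new
groups draw from a monotone counter, and codes of merged-away groups are
never reused. Consequently group *composition* is invariant to processing
order and to splitting the build into increments, while code *values* are
not — analyses that compare dictionaries should compare compositions.

## Grouping modes

* `all` (default): the full reported group. One local group per source
  group; the union of local groups equals the accessions of the file.
* `top_gene`: the top entry plus members sharing ≥1 gene symbol with it
  (case-insensitive; multi-symbol cells are split on `;`, `,`, `|`). When
  the dialect provides a rank column, members must additionally match the
  top's rank (exact for integral values, 1e-9 tolerance otherwise); when no
  rank exists all members count as equal rank. A top without gene
  annotation degrades the group to the singleton top. The "any shared
  gene" reading (rather than first-gene-only) is deliberate, to cover
  multi-gene annotations.
* `top_identifier`: the singleton top. Linking degenerates to exact
  top-accession matching; included for comparison.

Refined groups are always subsets of the `all` groups and the per-run group
count is identical in all modes.

Accessions are exact, case-sensitive strings; version suffixes are
significant (`IPI00215894.1` ≠ `IPI00797833.3`). An optional
`normalize_accession` hook exists on the reader but is off by default.

## Input dialects

Column naming varies by software, so parsing goes through a `Dialect`
mapping. Preset `proteinpilot` expects group column `N` and takes the first
row of each group as the top; preset `discoverer` uses a master-protein flag
column. Arbitrary mappings can be given as a dict or a YAML file; only a
group-id column and an accession column are mandatory. Groups are the
maximal consecutive row blocks sharing a group id, duplicate
(group, accession) rows are dropped with a warning, and unmapped columns are
carried verbatim (never parsed or reordered) so coded output preserves them
byte-identically.

## Coding and cross-run analyses

Coding is a pure per-accession lookup; an accession absent from the
dictionary is an error by default (the dictionary should cover the coded
runs) or the sentinel code 0 under `allow_missing`. For the stepwise
analyses under refined modes, runs are first restricted to the entries the
refinement retains — a code counts as identified in a run only if that run's
*refined* group maps to it. Without this restriction a pruned-but-listed
member would mark a group as present and the refined common-code curves
could exceed the `all` curve, which is meaningless for comparing the modes.

Per update step the change log records: `new_accessions` (never seen
before), `new_groups` (freshly coded), and `mergers`, counted as consumed
pre-existing groups — a merge of g groups contributes g−1 — so that
Σ new_groups − Σ mergers equals the final group count exactly. Stepwise
analyses default to processing runs in decreasing order of group count (ties
by run id). The "consistently detected" filter keeps codes present in all
runs (threshold 1.0, default) or in strictly more than a given fraction of
runs (e.g. 0.75).

Group-size histograms use the bins 1, 2, 3–5, >5. Dice tables are
run × global-group: `dice_vs_dictionary` compares the run's local members of
a code against the full global group (1 = identical, 0 = absent);
`dice_top_proteins` compares the run's top against the union of tops
representing the group across runs (1 everywhere iff a unique top represents
the group in every run).

## Synthetic studies

The generator emulates the three cross-run effects on a fixed universe of
true groups: per run, a group drops out entirely with `dropout_prob`, each
non-top member independently with `member_dropout_prob`, and the top rotates
onto another surviving member with `top_swap_prob`; surviving groups are
renumbered sequentially. Defaults — 12 runs, 220 true groups, ~60%
singleton size weights with a decaying tail, dropout 0.15, member dropout
0.10, top swap 0.20, 90% single-gene groups — describe a moderate
plasma-proteomics study in which most groups are singletons and multi-gene
groups are a small minority. Accessions are `PROT%05d.%d` (with version
suffixes, to exercise version handling) and genes `GENE%04d`. Per-accession
peptide counts are drawn once per universe, so a zero-variation
configuration yields byte-identical runs.

Because the canonical top survives in every realization, all observed
fragments of a true group overlap through it: the `all`-mode build must
recover exactly the true groups restricted to observed accessions, which the
tests assert over 100 seeded replicates. Two things the generator does *not*
emulate: (i) cross-run mergers never arise (fragments always share the top,
so groups only extend — merger counting is tested on constructed cases
instead), and (ii) per-group detectability is homogeneous, so the
simultaneous "many groups in only one run, many in all runs" pattern of real
studies (which needs heterogeneous detectability) is not reproduced.
Passing tests therefore demonstrate the correctness of the linking machinery
under the stated drift model, not the marginal detection statistics of any
real dataset.

Two deterministic fixtures encode textbook situations: a kininogen-1
isoform group whose runs produce a split, a merger, and an extension
(2 → 1 → 1 global groups, final size 4), and a pyruvate-kinase group whose
gene annotation and rotating tops make the three modes disagree (1 / 2 / 3
global groups).

## Numerical and degenerate-input choices

* Dice on two empty sets is undefined and raises; empty collections are
  "not connected" by convention.
* The rank tolerance (1e-9) only matters for float-valued rank columns.
* An empty dictionary is a valid merge target; updating with an already
  contained local group set changes nothing (idempotence).
* Serialized dictionaries are two-column TSV (`PGC`, `Accession`), sorted
  for diff-ability, with a `# next_pgc=` comment preserving the code counter
  across round trips even when it is ahead of max(PGC)+1.
* Problem sizes in the test suite and the acceptance script (500 random
  merge instances of ≤200 accessions / ≤60 sets, 50 permutations and splits
  of a 10-run study, 100 recovery replicates of 6 runs × 60 groups, one
  12-run × 220-group summary study) were chosen to exercise the asymptotic
  behaviour at desk scale; the whole suite runs in seconds.

## Known limitations

* Linkage is binary overlap; it cannot down-weight spurious single-accession
  bridges, so one promiscuous accession can chain otherwise unrelated
  groups into one code (the merge warning in the log flags such events).
* The change-log and curve analyses assume every run was coded with the same
  dictionary; mixing dictionaries is not detectable from codes alone.
* Gene-based refinement trusts the summary's gene annotation; no identifier
  mapping or aliasing is attempted.
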