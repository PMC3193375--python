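# Methods

## Scoring model

`refogbench` scores a method's orthologous-group (OG) partition against a
set of curated reference orthologous groups (RefOGs). Scoring assumes the
predictions form a **disjoint partition** of the method's gene universe
(each gene in at most one OG); a duplicate assignment is treated as a
corrupt input file, not a scoreable prediction. Gene identity is the bare
identifier after stripping an optional `species|` prefix, compared by exact
string match: orthology-database dumps differ in prefix conventions, not in
the identifiers themselves. Before scoring, both the RefOGs and the
predictions are restricted to a common reference-species set (default: 12
bilaterian species tags), so methods built on different species panels are
compared on common ground. The RefOG universe need not equal a method's
universe: a curated gene absent from the method entirely is simply a
missing gene.

Per RefOG *R*:

1. **Best match.** *O\** = argmax over predicted OGs of |*O* ∩ *R*|. Ties
   are broken by fewer non-member genes (a precision tie-break), then by
   the lexicographically smallest OG id — fully deterministic. If no OG
   contains any member of *R*, there is no match: all members are missing,
   no erroneous genes, and no group-level events (no grouping happened).
2. **Gene level.** missing = *R* \ *O\**, erroneous = *O\** \ *R*.
   Erroneous genes are counted against the best match only; the
   conservation identity |overlap| + |missing| = |*R*| always holds.
3. **Group level.** *B* = OGs with ≥ 1 member of *R*. Fissions =
   max(0, |*B*| − 1), so an unsplit family scores zero (counting raw OGs
   would penalize perfect predictions); the raw member-bearing list is
   retained. Fusions = OGs in *B* whose non-member count exceeds the alien
   tolerance. The tolerance defaults to 3 ("more than three erroneously
   assigned genes"); fusion detection therefore looks at **every**
   member-bearing OG, not only the best match.
4. **Accuracy flags.** `gene_strict` ⇔ missing = erroneous = ∅.
   `group_accurate` ⇔ fissions = fusions = 0; sub-threshold aliens are
   tolerated. A `strict_group_mode` flag additionally requires zero aliens
   in any member-bearing OG. `gene_strict` implies `group_accurate` under a
   disjoint partition, so strict accuracy never exceeds group accuracy.

Aggregation yields six schemes per method: strict gene-level accuracy %,
total missing/erroneous, % of RefOGs affected by each, group accuracy %,
total fissions/fusions, % of RefOGs affected by each. Percentages use the
number of RefOGs evaluated as denominator and are *reported* to one decimal
place with round-half-up; internal values stay exact floats. Ranking is
ascending by total errors (missing + erroneous + fissions + fusions), ties
to higher strict accuracy, then method name. A RefOG affected by both
fission and fusion counts once in each per-type percentage; no combined
"affected by any event" percentage is reported, since per-type flags are
the unambiguous primitive.

## Complexity factors

* **MeanID** — mean over all unordered row pairs of (identical positions) /
  (co-ungapped positions); pairs with no co-ungapped position contribute 0;
  gaps never count as match or mismatch. This is the standard
  mean-pairwise-identity rate proxy (high identity = slow evolution).
* **Alignment quality** — per column, each co-ungapped residue pair scores
  S(a,b)/√(S(a,a)·S(b,b)) (BLOSUM62 by default) clipped to [0, 1]; pairs
  with a gap score 0; the column score is the mean over all row pairs and
  the overall score the mean over columns with ≥ 1 residue. Residues whose
  self-score is non-positive (e.g. `X` in BLOSUM62) cannot be
  self-normalized and score 0. This is a norMD-style normalized-similarity
  objective, **not** a bit-exact norMD implementation, and is labelled as a
  stand-in in all outputs.
* **Average domains** — Σ domain counts over members / family size, as an
  exact quotient; members absent from the domain table count 0.

Class boundaries (configurable via `ClassThresholds`): size < 14 small,
14–40 medium, > 40 large; MeanID ≥ 0.7 slow, [0.5, 0.7) medium, < 0.5 fast;
alignment quality > 0.6 high else low; domains < 2, [2, 4], > 4. Exact
boundary values (14, 40 members; 0.5, 0.7 identity) go to the middle size
class and the slower rate class; this convention is stated in the output
headers.

**Association testing.** For each factor × error-type cell we compute a
Spearman rank correlation on the continuous factor and, where a class rule
exists, a Kruskal–Wallis test across the factor's classes. Rank tests were
chosen for distribution-freeness (error counts are small, skewed
integers). All non-degenerate p-values in the grid are adjusted by
Benjamini–Hochberg (via `scipy.stats.false_discovery_control`);
significance is adjusted p < 0.05. Constant factors (or error columns) give
an undefined statistic, are flagged `degenerate`, and are excluded from the
adjustment.

## Annotation reconciliation

Identifier history rows are (gene_id, status ∈ {current, retracted,
pseudogene, superseded}, first_version, last_version, replacement_id).
Versions are opaque ordinals, so any annotation lineage works. Category
assignment for an error gene: absent or ambiguous in the table → *unknown*;
first_version greater than the method's annotation version →
*introduced_later* (the method could never have seen it, whatever its
current status); otherwise by status, with *superseded + replacement*
counted as *mapped_current* because the identifier still maps into the
current annotation through its replacement. A gene_id with several rows is
resolved by last_version precedence; exact ties are reported *unknown*
rather than guessed. The five categories always partition the error set.

Per-species coverage = 100 · (orthologs − missing) / orthologs, with
missing genes attributed to their species from the matched-OG comparison by
default; an any-OG mode instead counts a member as recovered when it
appears in any member-bearing OG of its family. Species with zero RefOG
orthologs are omitted with a warning (their coverage is undefined), which
also means an erroneous gene from such a species does not appear in the
breakdown.

## Synthetic benchmark and its ledger oracle

Defaults emulate a curated metazoan benchmark: 12 species, 70 families,
sizes drawn from a lognormal (log-mean 3.0, log-sd 0.6) clipped to
[2, 100] — mean ≈ 23 members, so ≈ 1.6 k genes per benchmark, spanning
single-copy-like families up to ~100-member expansions. Species are
assigned round-robin from a random start with 25 % jitter, with the first
two members forced onto distinct species so every family spans ≥ 2 species.

Perturbation plants the four error types in stage order drops → splits →
aliens → merges, each stage consuming an independent child stream of the
run seed so partial configurations stay reproducible. Splits partition
survivors uniformly at random into k non-empty parts (shuffle + cut
points). Aliens and merge blocks come from a decoy pool disjoint from all
families, so erroneous-gene attribution is unambiguous; the default merge
block of 5 decoys crosses the more-than-three fusion threshold by
construction, while default alien counts (1–2) stay below it.

The `TruthLedger` records, per family, the dropped genes and each derived
OG's surviving-member and alien counts. `expected_summary` re-derives all
six schemes from those counts alone — applying the same published
definitions (best part by members, then fewer aliens, then id; fissions =
parts − 1; fusions = parts at/above the alien threshold) but never reading
the prediction files. Decoys belong to no family and families are disjoint,
so a family's member-bearing OGs are exactly its own parts, making the
ledger arithmetic provably equivalent to the engine's definitions; the
equality is asserted exactly (integer counts and identical percentage
arithmetic) over hundreds of seeds.

**What the generator does not emulate:** shared homology between families
(aliens are unrelated decoys, whereas real erroneous genes are usually
homologs), inter-method correlation, annotation-version drift inside one
run, and realistic sequence evolution (the MSA simulator is uniform
substitution without indels, giving the closed-form expected pairwise
identity (1−p)² + p²/19). Passing the oracle tests therefore certifies the
*metric logic*, not performance claims about real databases.

**Monotonicity caveat:** raising `p_drop` under common random numbers never
decreases total missing in drop-only configurations (the planted drop set
grows monotonically). With random re-splitting active, a changed survivor
set re-draws the partition, so the realized best-part size can shift; the
guarantee is documented and tested for the drop-only regime.

## Numerical and interface choices

* Percentages are exact floats internally; one-decimal round-half-up
  formatting (via `decimal`) only at report boundaries.
* All reports are byte-stable: fixed column orders, lexicographic sorting,
  no timestamps in data files.
* Seeds are mandatory for every stochastic operation; identical seed +
  config ⇒ byte-identical outputs.
* The MSA simulator's `disjoint_rows` mode gives each row its own alphabet
  slice so that at substitution probability 1 rows share no residues
  (pairwise identity exactly 0) — a degenerate-limit check.
* Problem sizes in the test suite and acceptance script (70-family
  benchmarks, 200-seed oracle sweeps, 100 random universes ≤ 50 genes,
  length-10⁴ alignments, 200/500 association replicates) were chosen as the
  smallest sizes at which the checked properties are sharp: exact-equality
  checks need no replication beyond seed coverage, and the statistical
  checks (3-SE identity band, power ≥ 0.9, false-positive rate within
  3–7 %) are stable at these replicate counts.

## Known limitations

* The alignment-quality score is a stand-in with norMD-like normalization,
  not the published norMD; its 0.6 class boundary is kept configurable for
  that reason.
* Fusion counting is threshold-based on alien counts and does not ask
  whether the aliens are themselves a coherent homologous block.
* The association tests report correlation, not causation; factors
  (size, rate, alignment quality) are themselves correlated in real
  benchmarks, and no attempt is made to deconfound them.
* `compare_runs` requires the two runs to score the same number of RefOGs
  and does not align RefOG identities beyond that count check.
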