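# Methods

## Model and assumptions

The unit of comparison is the domain architecture (DA): the unordered
set of unique-putative Pfam family names on a protein. Orthology is
taken entirely from KEGG Orthology — a KO group is treated as one
family of orthologous proteins across organisms, with no further
phylogenetic structure. Events are therefore *unpolarized*: "gained"
and "missing" are defined relative to the other DAs of the same KO, not
against an ancestral reconstruction, and translocations are symmetric
statements about reciprocal presence/absence, not dated transfers.

Treating a DA as an unordered set is a deliberate choice. Every
downstream rule tests only membership (`d ∈ p`), and the
unique-putative reduction already collapses copies, so N- to C-terminal
order would never be consulted; keeping sets makes DA identity
well-defined under copy-number changes. The cost is that pure
rearrangements of the same domain content are invisible.

## Pipeline

1. **Ingest.** Proteins enter the analysis only with exactly one
   distinct *significant* KofamKOALA assignment (asterisk-marked rows,
   i.e. score above the family's adaptive threshold); zero or multiple
   distinct KOs drop the protein (tallied in the build report).
   Per gene, only the longest isoform is analysed, ties broken by the
   lexicographically smallest RefSeq accession so selection is
   deterministic. KO-less proteins are stored but excluded from event
   calling.
2. **Domain resolution.** Hits are reduced greedily: visit hits by
   descending bit score (ties: lower E-value, then smaller envelope
   start, then family name), keep a hit iff its closed envelope
   interval `[env_from, env_to]` shares no residue with any kept hit.
   Nested hits count as overlapping. Greedy-by-score is used rather
   than exact weighted interval scheduling because the rule is a
   per-conflict "highest score wins", which greedy realizes
   deterministically whether conflicts come in pairs or in larger
   connected groups. Bit score (not −log E-value) is the ranking
   statistic, as in HMMER itself. The fixed tie-break chain makes
   outputs bit-stable across runs and platforms.
3. **Store.** Six relations in a single SQLite file (or `:memory:`).
   Referential integrity is enforced at build time with explicit
   errors naming the table and key; the Unknown clan sentinel
   (`9999.0`) is always present so clan joins never dangle.
4. **Architectures.** Items are indexed per KO by descending member
   count, ties by the lexicographically smallest sorted domain list.
   For item *i*: `missing_i = (∪_j p_j) \ p_i` and
   `gained_i = {d ∈ p_i : ∃ j ≠ i, d ∉ p_j}`. With one item both
   patterns are empty; two items is the minimum for signal.
5. **Events.** Thresholds as in the README. All of them sit in
   `RunConfig` (defaults: `min_group_size = 4`,
   `duplication_percentile = 0.99`) because the 4-organism cutoffs are
   modelling choices, not derived constants.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_group_size` | 4 organisms | floor for \|A\| (mobility) and \|A*\|, \|B*\| (translocation) |
| `duplication_percentile` | 0.99 | significance cutoff on the \|diff\| distribution |
| `duplication_rule` | `empirical` | see below |
| `ambiguity_policy` | `exclude` | where both-pattern organisms go |

**Paralog ambiguity.** The containing/lacking split is not well defined
for an organism that has, within one KO, both a protein with the domain
and a protein without it. Under the default policy such organisms join
neither A nor B and do not count toward T, which preserves the
disjointness A ∩ B = ∅ without biasing either side; `to_A`/`to_B`
reassign them instead for sensitivity analysis.

**Duplication rule.** The global verdict compares
`diff = n_duplicated − n_nonduplicated` (over the KOs containing the
domain) with a percentile of the |diff| distribution across all
domains. The phrase "99% of the cumulative sum of the differences"
admits a second reading — a rank cutoff where the descending cumulative
sum of |diff| reaches 99% of its total — which is implemented as
`duplication_rule="cumsum-rank"`. The empirical two-sided percentile is
the default because it is symmetric in the duplicated/nonduplicated
directions, as the prose requires. Per-KO constancy is evaluated only
over proteins that *contain* the domain; counting zero-copy proteins
would make every mobile domain trivially "duplicated".

**Event granularity.** One translocation event per (domain, KO pair)
triple — a domain mobile in many KOs generates many pairwise events
while remaining a single translocation *domain*; indel events are one
per (domain, KO). Orientation is canonicalized by numeric KO order
(ko1 < ko2), with A* computed from ko1's containing side; class labels
are composites `superdomain(A*)-superdomain(B*)` (indels:
containing-side first).

## Synthetic cohorts

`FixtureSpec`/`generate_cohort` emulate the whole input surface with no
downloads: registry, protein table (with alternative isoforms),
pfam_scan hits (with overlapping and nested decoy hits so the putative
filters do real work), KofamKOALA rows (with sub-threshold and
multi-KO decoys so the ingest filters do real work), and a manifest of
expected calls computed by applying the printed inequalities directly
to the constructed presence patterns — a code path independent of the
detectors, so generator and detector validate each other.

Default cohort shape: 12 eukaryotes, 2 bacteria, 1 virus
(eukaryote-dominated, like the corpora this model targets), 4 KO
groups, paralog rate 0.1, isoform rate 0.2, decoy rate 0.3, ambiguity
rate 0. Background DA variation per KO (dropping one core family from
at most three organisms) is deliberately kept *below* the mobility
threshold, so at noiseless settings the only events in a cohort are
the planted ones — that is what makes sensitivity/false-positive
statements in the tests exact. Plantings with reciprocal groups under
the threshold are padded with organisms containing the domain in both
KOs, keeping the domain mobile so the planting degrades to indels
rather than silently vanishing.

What the generator does *not* emulate: real sequences and HMM scoring
(scores are drawn, not computed), clan competition among hits,
correlated domain content between KOs, gene order/synteny, and
realistic organism sampling. Passing tests therefore demonstrate that
the event logic implements the stated rules exactly on inputs of the
stated shape — not that the calls are robust to annotation noise in
real proteomes.

The eleven-organism FERM_C fixture reproduces the worked
reciprocal-translocation case (FRMD6/K16822 vs MYLIP/K10637, groups of
five and six organisms, all eukaryotes). Group membership uses the
published organism codes; per-organism protein counts are synthetic,
so total protein counts are not asserted.

## Numerical and degenerate-input choices

* Closed 1-based envelope intervals; overlap means ≥ 1 shared residue.
* Empty KO queries return empty member lists (not errors); an empty
  organism set for superdomain classification is a contract error.
* `np.percentile` with linear interpolation on |diff|; an empty diff
  distribution yields an infinite cutoff (nothing called).
* Organism codes are 3–5 characters, letter-initial, case-sensitive
  (lowercase = KEGG-style codes); registries reject duplicates.
* Seeds: a single integer drives `numpy.random.default_rng`; cohort
  writing iterates sorted containers, so equal seeds give byte-equal
  output trees.

## Scale of the shipped checks

Tests run the pipeline at desk scale: cohorts of ≤ 20 organisms and
≤ 10 KO groups, 500 randomized oracle-equivalence fixtures and 100
planted-recovery seeds — sizes chosen so the whole suite completes in
well under a minute while exercising every rule boundary (|A| = 4,
|T| − 4, |A*| = 4) explicitly.

## Known limitations

* No phylogeny: events are neither dated nor polarized, and convergent
  loss is indistinguishable from a single exchange.
* KO groups are trusted as orthology; mis-grouped paralogs distort the
  A/B splits (partially mitigated by the exclusion policy).
* Domain order is ignored (see above); tandem-repeat expansion is only
  visible to the duplication caller, not to DA identity.
* The duplication percentile is computed over whatever domain universe
  the database holds; on very small corpora the cutoff is coarse and
  most verdicts are "undetermined" by design.
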