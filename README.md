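# domevol

Protein evolution through the lens of domain architectures.

`domevol` models each protein as the set of Pfam domains it carries and
each gene family as a KEGG-Orthology (KO) group of orthologous proteins
across organisms. By comparing domain-architecture variation *within*
and *between* KO groups it calls four kinds of evolutionary events —
**mobile domains**, reciprocal **translocations** between KO pairs,
**indels**, and **duplications** — and classifies each by superdomain
taxonomy (Eukaryota / Bacteria / Viruses, or Mixed). It is aimed at
comparative genomicists studying domain shuffling: the "mix and merge"
view of protein evolution, in which chromosomal rearrangements move
functional units between gene families, rather than nucleotide-level
models.

## The model

Inputs are per-organism annotated proteomes: a protein metadata table,
Pfam hits (pfam_scan dialect), KO assignments (KofamKOALA detail-TSV
dialect) and an organism registry with superdomain taxonomy. Two
filters make a clean catalogue: only proteins with exactly one
confident KO assignment are kept, and only the longest isoform per gene
(so alternative splicing cannot masquerade as domain gain/loss).

Overlapping or nested Pfam hits on one protein are resolved to
**putative** domains (greedy maximal bit score, pairwise
non-overlapping envelopes) and then to **unique putative** domains (one
highest-scoring representative per family). A protein's *domain
architecture* (DA) is its unique-putative set; each KO partitions into
*items* — groups of proteins sharing a DA, with matched organism /
protein lists in which a repeated organism encodes paralogs.

For a domain *d* in KO *k*, let *A* be the organisms whose proteins all
contain *d*, *B* those whose proteins all lack it, and *T = A ∪ B*
(organisms with both kinds of paralogs are set aside). Then

* *d* is **mobile** in *k* iff `4 ≤ |A| < |T| − 4`;
* *d* mobile in KOs *k₁ < k₂* **translocates** between them iff the
  reciprocal groups `A* = A₁ ∩ B₂` and `B* = A₂ ∩ B₁` satisfy
  `|A*| ≥ 4` and `|B*| ≥ 4`; one event per (domain, KO pair);
* otherwise each mobile (domain, KO) record is an **indel** event —
  the two outcomes are mutually exclusive per domain;
* for **duplication**, putative copies are kept: *d* is nonduplicated
  in a KO iff its copy number is constant across the containing member
  proteins, and globally duplicated (or nonduplicated) when the signed
  count of duplicated-minus-nonduplicated KOs reaches the 99th
  percentile of the |diff| distribution over all domains.

Everything is backed by a six-relation embedded SQLite store
(taxonomy, ko_annotation, clan_domain, pfam_domain,
org_protein_annotation, pfam_data) with TSV export/import.

## Worked example

The package ships a generator for the classic worked case: the FERM_C
domain (a PH-like clan member) swapping reciprocally between the FRMD6
ortholog group (K16822) and the MYLIP E3-ligase group (K10637) across
eleven vertebrate genomes — five organisms carry FERM_C in FRMD6 but
not MYLIP, six show the opposite pattern.

```sh
domevol simulate --out-dir demo --preset ferm-c
domevol build --registry demo/registry.tsv --proteins demo/proteins.tsv \
    --pfam demo/pfam_hits.txt --koala demo/koala.tsv \
    --clans demo/clans.tsv --db demo/evo.db
domevol detect --db demo/evo.db --out-dir demo/events
```

which logs

```
INFO domevol: proteins loaded: 25
INFO domevol: longest isoforms: 24
INFO domevol: mobile (domain, KO) records: 2
INFO domevol: translocation events: 1 (1 domains)
INFO domevol: indel events: 0
```

and writes `demo/events/translocations.tsv`:

```
domain_name  clan_id  ko1     ko2     A_star                   B_star                class
FERM_C       0266.9   K10637  K16822  CHA,MIO,PEM,cge,ola,rno  CAA,CHL,ECTE,ccar,lav Eukaryota-Eukaryota
```

Reading: FERM_C is mobile in both KO groups (the two mobile records);
the six organisms of `A_star` carry it in MYLIP and lack it in FRMD6,
the five of `B_star` the reverse — a reciprocal exchange, hence one
translocation and no indel for this domain. One alternative isoform
(dropped by the longest-isoform filter) and one overlapping decoy hit
(dropped by putative resolution) are in the inputs on purpose; 25
proteins load but 24 longest isoforms enter the analysis.

`domevol summarize` aggregates events into a per-(class, clan) count
table, and `domevol simulate` (random preset) generates seeded cohorts
with planted translocations/indels/duplications plus a manifest of the
expected calls — the basis of the end-to-end tests.

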