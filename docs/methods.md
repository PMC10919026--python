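# Methods

## The reference model

The catalog is the package's scientific core: a set of enzyme functions,
keyed by complete four-field EC numbers, that participate in microbial
halogen metabolism. Each entry carries

- **role** — `halogenase` or `dehalogenase` for enzymes that directly
  form or break a carbon–halogen bond (together the "direct" subset),
  `auxiliary` for enzymes of the surrounding pathway steps;
- **mechanism** — for dehalogenases only: `hydrolytic` if and only if
  the EC belongs to the carbon–halogen hydrolase family (prefix
  `3.8.1.`), otherwise `non_hydrolytic`; `not_applicable` elsewhere;
- **direction** — the pathway direction (`halogenation` or
  `dehalogenation`) the enzyme serves;
- **cluster memberships** — zero or more of 32 named clusters grouped by
  the degraded halogenated molecule (23 degradative clusters, D1–D23) or
  the produced halometabolite (9 biosynthetic clusters, B1–B9).

Only complete EC numbers are admitted; partially assigned ECs (e.g.
`3.8.1.-`) describe incompletely characterised enzymes and are rejected
at load, and screening consequently does exact string matching with no
prefix or wildcard semantics. An EC may belong to several clusters — the
(S)-2-haloacid dehalogenase (EC 3.8.1.2), for instance, appears in both
the chloroalkane/chloroalkene and the chloroacrylate degradation
contexts — and a cluster never mixes pathway directions: degradative
clusters contain only dehalogenation-direction ECs, biosynthetic
clusters only halogenation-direction ECs. These rules are enforced as
structural invariants at catalog construction; the published counts
(161 total, 42 direct = 16 + 26, 119 auxiliary, 23 + 9 clusters) are
*reported* by `validate_published_counts` rather than enforced, so
user-supplied catalogs of any size load fine.

**Packaged catalog provenance.** About 60% of the packaged entries are
real, well-known enzymes: the full hydrolytic dehalogenase family
(EC 3.8.1.1–3.8.1.11), halide lyases (EC 4.5.1.x), reductive
dehalogenases and deiodinases (EC 1.21.x.x), the flavin-dependent
tryptophan halogenases (EC 1.14.19.9/58/59), haloperoxidases
(EC 1.11.1.8/10/18), the fluorinase and chlorinase (EC 2.5.1.63/94), and
accessory pathway enzymes of the chlorocatechol, atrazine, chloroacrylate
and rebeccamycin pathways, among others. The remaining entries are
**synthetic placeholders** that keep the catalog's published structure
exactly: they occupy EC class 8 — unassigned in the real EC system, so a
placeholder can never shadow or collide with a real enzyme — and are
labelled "synthetic placeholder" in their names and in the catalog
version string. The cluster scheme's names and numbering follow the
degradative/biosynthetic categories the study describes; member rosters
combine the explicitly named member ECs with plausible pathway
companions. Analyses of real data should treat the packaged catalog as a
structurally faithful scaffold and substitute a fully curated roster
(the TSV export/import round-trip exists for exactly this purpose).

## Screening and counting semantics

A feature contributes one gene to every *distinct* catalog EC it
carries: a bifunctional annotation with two catalog ECs is visible under
both functions, while duplicate identical ECs on one feature count once
(EC sets are deduplicated at parse time). Feature type is not
restricted — EC presence alone gates counting, since non-coding features
carry no ECs in practice. Counts are raw feature tallies with no
cross-contig deduplication.

## Gene density

For sample *s* and function or cluster *f*:
`density = n_genes / size_mbp`, in genes per megabase pair. The
denominator is supplied out-of-band — the total assembled contig size
for a metagenome, the MAG's own assembly size for a MAG — rather than
summed from gene spans, because the statistic normalises by assembly
size, not by gene content. A cluster's count is the sum over its member
ECs; an EC in *k* clusters contributes its full count to each, so
cluster values are deliberately never totalled across clusters.
Densities are kept at full precision internally and in machine outputs
(serialised via `repr`, which round-trips IEEE doubles exactly; re-read
with pandas' `round_trip` float parser); a display column rounded to a
configurable number of decimals (default 2, the conventional print
precision for these values) travels alongside.

Presence, for all comparison operations, is binary: a function, cluster
or taxon is present when at least one gene (label) is observed. The
shared fraction of a sample set is |intersection| / |union|.

## MAG quality and novelty

Quality tiers apply the standard completeness/contamination gates with
the boundary semantics taken literally: **high** requires completeness
strictly greater than 90% *and* contamination strictly below 5%;
**medium** is any non-high MAG with completeness ≥ 50% and contamination
< 10%; everything else is discarded. The strictness matters exactly at
the boundaries (completeness 90.0 is medium, not high) and is pinned by
unit tests.

Novelty is a pure function of the GTDB-Tk classification string: a named
species ⇒ `known_species`; empty species under a named genus ⇒
`novel_species`; empty genus under a named family ⇒ `novel_genus`; empty
family under a named order ⇒ `novel_family`. When both order and family
are unassigned the call is `novel_higher` rather than a guessed rank,
which makes the residual explicit instead of over-claiming a family-level
novelty; the literal string `unclassified` (or an empty domain) maps to
`unclassified`. Taxon aggregation groups per-MAG density records at a
caller-chosen rank (phylum…genus), reporting MAG count, mean and max
density per key, with empty ranks grouped under an explicit sentinel.

## Tree annotation

The annotation bundle joins per-MAG density tracks (total catalog
density, the four role/mechanism splits, and every cluster) onto a
Newick tree's leaves in leaf order, never reordering the tree. Leaves
with a configurable reference prefix (default `Ref`) — external
reference genomes included during tree building — are passed through
with a reference flag; MAGs without a computed profile get value 0 plus
a missing flag, so absence of data is distinguishable from a measured
zero. Writers emit the iTOL simple-bar and color-strip text dialects
(these figures are conventionally rendered in iTOL) plus a plain
long-format TSV twin; colors for the taxonomic-order strip are assigned
from a fixed palette over the sorted order names, making outputs
byte-reproducible.

## The synthetic-data generator

The generator emulates the statistical structure of an annotated
macroalgal-microbiome study: per-sample feature tables with planted
per-EC gene densities, MAG metadata with a controlled quality mix and a
taxon pool, and a random bifurcating tree. Densities, not absolute
counts, are the planted quantities, because density is the statistic the
pipeline reports. Two count models:

- **exact** — each planted (sample, EC) receives exactly
  `round(density × size_mbp)` features, so recovery through the whole
  pipeline is exact and deterministic (the ground-truth file records the
  realised count and density);
- **poisson** — the count is drawn from a Poisson with that mean,
  emulating sampling noise; recovery error is then reported, not
  asserted, and is bounded by Poisson statistics (relative standard
  error (density × size_mbp)^(−1/2) per sample).

Decoy features — half with no EC, a third with a complete EC drawn from
a reserved non-catalog EC class (default class 9, checked against the
catalog), the rest with a partial EC such as `3.8.1.-` — exercise the
screening filter; tests verify they never perturb a catalog count. MAG
quality values are drawn inside the chosen tier's region (with explicit
boundary cases injectable, e.g. completeness exactly 90.0), and GTDB
strings come from a pool containing the bacterial orders reported as
enriched in halogen-metabolism functions in macroalgal microbiomes
(Rhodobacterales, Rhizobiales, Caulobacterales, Geminicoccales,
Sphingomonadales, Granulosicoccales, Microtrichales, Pseudomonadales,
Flavobacteriales, UBA10353, UBA9160) at several novelty levels. All
randomness flows through a single seeded generator; a fixed seed gives
byte-identical bundles.

What the generator does **not** emulate: sequence content, assembly
artifacts, annotation error (wrong or missed ECs), gene-length biases,
strain heterogeneity, or any correlation between taxonomy and gene
content. Passing recovery tests therefore demonstrates that the
pipeline's bookkeeping — parsing, matching, counting, normalising,
tiering, labelling — is exact, not that upstream annotation of real data
is accurate.

## Problem sizes used in the shipped analyses

The acceptance script simulates the three-host study at realistic
assembly sizes (784.2, 525.8 and 435.3 Mbp) with 81 planted functions of
which 63 are shared by all three metagenomes, 98 MAGs (49/31/18 per
host, ~20% high quality), 20 further randomised exact-model specs, and
1000 Poisson replicates at mean count 10 — sizes chosen so the full run
completes in seconds while every count is large enough to be
informative.

## Numerical and design notes

- Cluster-vs-member-sum additivity holds to ~1e-16 relative error (pure
  float summation); the tests allow 1e-12.
- `round()` display rounding uses Python's banker's rounding; full-precision
  values are authoritative everywhere.
- Readers reject inconsistent inputs loudly (missing columns, duplicate
  locus tags, non-positive lengths, malformed GTDB strings, completeness
  outside [0, 100]) naming the offending entry, row or line.
- European digit-grouped integers ("784.246.579") are normalised only by
  an explicitly invoked helper; plain readers accept bare integers.
- Profiles record a catalog checksum so cross-catalog mixing (comparing
  or splitting profiles screened against different catalogs) is an
  error, not a silent wrong answer.
- The CLI records every run's merged effective configuration in
  `manifest.json`; manifests contain no timestamps, keeping reruns
  byte-identical.

## Known limitations

- The packaged cluster rosters and the placeholder share of the catalog
  are a structural scaffold, not a finished curation (see provenance
  above).
- Screening trusts upstream EC assignments entirely; no sequence-based
  validation or EC prediction is attempted.
- No statistical testing of density differences between samples is
  offered: the intended study design has no replication, so the package
  reports descriptive quantities only.
- Tree handling is annotation-only; the package neither infers trees nor
  renders figures.
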