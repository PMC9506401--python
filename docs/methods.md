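# Methods

This note documents the models, rules and numerical choices behind
`rarebiome`, and what the synthetic validation does and does not show.

## Design and data model

The analysis targets a multi-host sealed-jar experiment: H host species
(default 17) grown on two substrates — sterile sand, which only the seed
can inoculate, and field soil — with three replicate jars per
host × substrate, each sampled as shoot, root and rhizosphere; seed and
spermosphere samples (two replicates) are taken per seed lot and carry no
substrate. Bacterial 16S and fungal ITS OTU tables are independent
datasets with disjoint OTU pools and are never merged.

The canonical interchange format is tab-separated UTF-8 text: counts as
samples × OTUs with integer cells, metadata as
`sample_id / host / tissue / substrate / replicate`, taxonomy as
`otu_id` plus the six ranks kingdom…genus. BIOM 2.x files can be ingested
onto the same in-memory table. Validation is strict at load time
(non-negative integral counts, unique identifiers, substrate/tissue
consistency) while cross-dataset consistency is *reported*, never raised,
so callers can decide severity.

## Preprocessing

1. **Non-target removal.** OTUs whose taxonomy matches, case-insensitively
   at any rank, one of the keywords
   `{mitochondri, chloroplast, plant, protist, viridiplantae, streptophyta}`
   are dropped. The original curation was manual; a keyword rule is the
   reproducible equivalent and the rule list is configurable.
2. **Singleton removal.** OTUs with a table-wide read total below 2 are
   dropped. The screen uses post-merge totals — the only information
   available downstream of clustering — which has the identical effect on
   any OTU the screen can see.
3. **Replicate collapsing** sums counts over the replicate jars of each
   host × tissue × substrate treatment (integer arithmetic; total reads are
   conserved exactly, and this is property-tested). Averaging is *not*
   used here; read-proportion summaries that need per-host means compute
   them downstream of percent normalisation.
4. **Percent normalisation** scales each collapsed group row to sum 100.
   All-zero rows (a treatment whose samples returned no reads) are kept at
   zero and flagged rather than dropped, keeping the group axis aligned
   with the design.
5. **Presence** is a strict comparison: a cell is detected iff its
   relative abundance exceeds the threshold (default 0 %, meaning ≥ 1 read
   after collapsing). Strictness makes presence monotone in the threshold
   and fixes the boundary behaviour of the relaxed 0.15 % bacterial mode:
   exactly 0.15 % is absent.

## Uncommon and abundant screens

Occupancy is the number of distinct host species in which an OTU is
detected, computed *within a compartment* (tissue × substrate) because the
downstream screens and reports are all per sample type; a dataset-wide
mode exists. An OTU is **uncommon** when occupancy ≤ `max_hosts`
(default 9; 9/17 ≈ 52.9 %, just under the 53 % phrasing of the screen).
Seed and spermosphere samples have no substrate axis and use a
sample-majority rule instead: uncommon ⇔ present in ≤ ⌊N/2⌋ of N samples.

**Abundant** uncommon OTUs exceed a peak relative abundance across the
compartment's host groups; the comparison is strict, and the default bar
is 5 % (10 % in seed/spermosphere reports). Top-k rankings sum relative
abundance across groups and break ties lexicographically on OTU id so all
orderings are deterministic.

## Sørensen transmission accounting

For each host and tissue, A is the set of uncommon OTUs detected in the
host's sand-grown group and B the soil-grown set; the Dice–Sørensen index

    QS = 2 |A ∩ B| / (|A| + |B|)

is reported per host with per-tissue arithmetic means over hosts (rounded
to two decimals for tabulation). The both-empty case is defined as 0: no
observed community on either substrate is no evidence of shared
membership, consistent with tabulating 0.00 entries. An OTU qualifies for
A/B if the screen flagged it uncommon in either of the tissue's two
substrate compartments; hosts missing one substrate's group are omitted
and reported. Presence uses the 0 % threshold here; the relaxed 0.15 %
mode is reserved for the sparse bacterial per-plant reports.

## Source classification

The seed/soil/unknown rules are a parameterised reconstruction of calls
that were originally made by expert judgment; all thresholds live in
`ClassifierParams` and are echoed into each call's evidence:

* **seed** — the OTU is detected in the host's sterile sand-grown plants.
  By default evidence is cross-tissue (`cross_tissue=True`): carriage is a
  property of the host's seed lot, so a sand-shoot detection counts for
  the same host's roots. A strict same-tissue mode exists.
* **soil** — no sand detection anywhere for the host, the focal soil group
  carries the OTU, and it is detected in ≥ `soil_support` (default 2)
  soil-grown rhizospheres dataset-wide, evidence the soil genuinely
  supplies it. A soil call is structurally impossible in the presence of
  sand evidence (enforced by the call type's invariant).
* **unknown** — everything else; typically a one-off soil-side detection
  whose propagule could have ridden in on either seed or soil.

Flags: **stochastic** marks OTUs occurring in ≤ `stochastic_max_groups`
(default 2) collapsed groups dataset-wide (one-off "island" colonists);
**biotic_filtered** marks OTUs with soil-rhizosphere host occupancy ≥
`filter_rhizo_min` (default 10) but soil-root occupancy ≤
`filter_root_max` (default 4) — abundant around roots yet excluded from
them. The defaults are anchored to the worked field examples the rules
reconstruct (a fungus in 12 rhizospheres but 4 roots; hyperabundant taxa
seen in a single sample).

Calls are emitted per (OTU, host, tissue) for every soil-grown detection
of an OTU that is uncommon in that tissue's soil compartment (a whitelist
admits near-common OTUs of special interest).

## Descriptive summaries

* **Phylum roll-ups**: uncommon OTU counts are unions across hosts per
  compartment (missing phyla bucket as "unclassified"); read percentages
  are means over hosts of the summed uncommon relative abundance per
  phylum.
* **Binary PCA**: eigendecomposition of the (n−1)-normalised covariance of
  the 0/1 presence matrix. Signs are fixed so each component's
  largest-magnitude loading is positive — the data do not constrain signs,
  and the convention makes outputs platform-stable.
* **Bray–Curtis** `Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`, defined 0 for two all-zero rows.
  Hierarchical clustering uses scipy with average linkage (UPGMA, the
  community-ecology default; complete and single are options). Input rows
  are pre-sorted by label before linkage so equal-distance merges break
  ties deterministically, and label permutations cannot change the leaf
  order.
* **Heatmap bins** are left-exclusive:
  {0}, (0, 0.1], (0.1, 0.25], (0.25, 0.5], (0.5, 1], (1, 5], (5, ∞) — the
  printed colour-scale boundaries overlap, so half-open intervals were
  adopted and are property-tested as a partition of [0, ∞).
* **Plant-grouping detection**: with exactly two leaves per host (one per
  substrate) in the dendrogram order, a host "groups by plant" iff its two
  leaves are adjacent — the vertical-transmission signature in ordered
  heatmaps.

## Synthetic community generator

The simulator emulates the jar design with seven OTU classes per marker
(defaults: 8 core-seed, 25 deterministic rare-seed, 25 stochastic
rare-seed, 17 host-specialists, 15 soil-common of which 5 root-filtered,
35 soil-rare, 5 contaminants — about 130 OTUs per marker, a deliberately
scaled-down community that keeps the full pipeline fast while exercising
every screen). Mechanisms:

* **Seed carriage**: core-seed OTUs ride in every lot; deterministic
  rare-seed OTUs in a fixed subset of 1–4 lots; stochastic rare-seed
  carriage is Bernoulli(p = 0.3) per lot, giving expected occupancy H·p;
  specialists in exactly one lot at 50× base abundance. Carried OTUs
  appear in the lot's seed/spermosphere samples and establish in each
  tissue × substrate with probability 0.9.
* **Soil propagules**: soil-common OTUs inoculate every soil jar;
  soil-rare propagule counts are Poisson(λ = 0.5) per jar, so per-jar
  presence probability is 1 − e^(−λ) ≈ 0.39 (the classic sparse-inoculum
  arithmetic: propagule densities below ~1 per gram make the partitioning
  of homogenised soil into jars itself a lottery). Soil OTUs always reach
  the rhizosphere of an inoculated jar, pass into roots with
  per-(OTU, host) probability 0.8 (0.15 for the filtered subset) and into
  shoots with probability 0.05.
* **Contaminants** are injected into one random sample each, with no
  biological source (truth label "unknown").
* **Reads**: per-OTU base abundances are log-normal (σ = 1.5) with a 5×
  boost for the core backbone; per-sample multiplicative jitter
  (log-normal, σ = 0.5); depths are log-normal (median 3000, σ_log = 1.3)
  clipped to [10, 80 000]; reads are multinomial at the sampled depth.

`deterministic_regime()` switches every stochastic channel off: carriage
certain, λ = 50 (every jar inoculated), establishment and passage
probabilities 1, no contaminants, and proportional read allocation that
guarantees ≥ 1 read per established OTU (read sampling is itself a
stochastic channel). In this regime the stochastic seed and soil-common
classes occupy all H hosts and correctly drop out of the uncommon screen;
the recovery gate is carried by the deterministically rare classes.

The generator is bit-reproducible given `rng_seed` (verified across
processes) and its closed forms (`expected_occupancy`) are checked against
Monte-Carlo occupancy at 2000 OTUs within three standard errors.

**What the simulation does not emulate:** sequence-level noise (chimeras,
clustering artifacts, taxonomy misassignment), compositional coupling
between markers, host–host abundance correlations, and the severe
sparsity/overdispersion of real amplicon data. Passing the recovery gates
therefore demonstrates the pipeline's internal consistency — the screens
and rules recover the generative truth under the stated mechanisms — not
field-data accuracy, where the original expert annotations remain the
reference.

## Reference similarity table

`data/sorensen_reference.tsv` ships the published per-host Sørensen
similarities for the 17-species jar experiment (fungal and bacterial ×
rhizosphere/roots/shoots). The package recomputes its column means
(0.08/0.22/0.21 fungal, 0.15/0.24/0.26 bacterial) through the same
averaging path used for freshly computed tables; it is typed reference
data, not a computed artifact.

## Known limitations

* The source classifier reconstructs expert judgment with fixed numeric
  thresholds; on real data the defaults should be treated as a starting
  point and the per-call evidence columns inspected.
* Occupancy screens assume each host contributes one collapsed group per
  compartment; unbalanced designs are handled but change the meaning of
  `max_hosts`.
* The seed/spermosphere majority screen is sample-level, so its outcome
  depends on the number of replicate lots sampled.
* Simulator class proportions are not estimates of any real community;
  they are stated defaults chosen to exercise the analysis.
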