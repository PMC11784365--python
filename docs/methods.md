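# Methods

`darkfix` quantifies the genetic potential for, and expression of,
light-independent ("dark") CO2 fixation in soil meta-omics data. It operates
strictly downstream of assembly, binning and gene prediction: its inputs are
the tabular outputs of that upstream machinery (MAG tables with CheckM-style
QC metrics, per-genome gene predictions, annotation hits, read-alignment or
count tables, and sample metadata). This note records the models, rules and
numerical choices the package implements, and what its synthetic data can
and cannot show.

## Gene catalog

**MAG quality control.** Genomes are kept when completeness >= 50% and
contamination < 10%; the completeness bound is inclusive and the
contamination bound strict. Records with missing metrics raise an error
naming the genome rather than being dropped silently.

**Clustering.** The non-redundant catalog uses greedy incremental clustering
at 95% nucleotide identity: genes sorted by length descending (ties broken
by gene id for reproducibility), each gene joining the first cluster whose
representative it matches at >= 95% identity over >= 90% of the shorter
sequence, else founding a new cluster whose representative it becomes.
Pairwise identity is computed over the best local alignment of the pair
(match +1, mismatch −1, gap −2; configurable via `AlignmentParams`), with
identity defined as matches / alignment columns and coverage as the aligned
span on the shorter sequence over its length. Where co-optimal local
alignments exist, the identity of the reported alignment may differ from
another optimum by a column or two; the clustering decision is stable as
long as pairs do not sit exactly on the 0.95 boundary. When gene sequences
are not supplied (table-only pipelines) every gene forms a singleton
cluster, which is exact whenever upstream dereplication already happened.
This is a deliberate reimplementation of the *decision rule*, not of any
specific clustering tool's heuristics or word indexing.

**Annotation filter.** KO annotation hits are kept when query AND subject
coverage are >= 70% and the bitscore reaches >= 50% of the reference's
self-alignment bitscore; one best KO per gene is retained (highest bitscore,
ties to the lexicographically smallest KO id). The filter is idempotent and
order-independent.

## Per-cell quantification

Read alignments are kept at >= 45 bp aligned length, >= 97% identity and
>= 80% read coverage (all inclusive); each distinct read id is credited to
at most one gene — its best alignment by identity, then aligned length, then
gene id (`multimap="best"`; `"all"` retains every passing alignment for
fractional schemes). Reads, not read pairs, are the counting unit.

The normalization chain is

1. gene copies = raw counts / gene length in kb (any length unit is valid by
   scale invariance; kb gives readable magnitudes),
2. KO copies = sum of gene copies over genes sharing a KEGG ortholog,
3. per-cell copies = KO copies / d(s), where d(s) is the per-sample median
   KO copy number of a configurable set of universal single-copy marker
   genes (markers absent from the matrix enter the median as zero; an even
   marker count uses the mean of the two central values).

Normalizing to single-copy markers rather than library size makes samples
comparable regardless of their eukaryotic or viral read fractions, and gives
the result its interpretation: a KO carried once per genome by every cell
reads 1.0; the starred key genes read as the abundance-weighted fraction of
cells encoding the pathway (metaG), or its mean expression per cell (metaT,
which can exceed 1). Samples whose marker median is zero are excluded and
flagged, never silently zeroed; if every sample's median is zero the run
aborts. Metatranscriptomes are normalized against their own (metaT) marker
copies.

*Numerical detail:* with an even marker count the median is the mean of two
central values, which is not exactly division-invariant in IEEE arithmetic;
`per_cell_normalize` applies up to five refinement passes so that the
documented invariant — normalized marker median exactly 1.0 per retained
sample — holds bit-exactly.

## Pathway registry and completeness calling

The registry (`registry.yaml`, shipped with the package and user-editable)
encodes seven autotrophic CO2-fixation pathways and their diagnostic
enzymes: the rTCA cycle (2-oxoglutarate synthase EC 1.2.7.3; ATP-citrate
lyase *aclA* EC 2.3.3.8), the Wood–Ljungdahl pathway (acetyl-CoA synthase
*acsC/cdhE* EC 2.3.1.169/2.1.1.245; CO dehydrogenase EC 1.2.7.4), the Calvin
cycle (RuBisCO *rbcL* EC 4.1.1.39; phosphoribulokinase EC 2.7.1.19), the
DC/4-HB cycle (4-hydroxybutyryl-CoA dehydratase EC 4.2.1.120; malate
dehydrogenase EC 1.1.1.37), the 3-HP bicycle (malonyl-CoA reductase EC
1.2.1.75; propionyl-CoA synthase EC 6.4.1.3; malyl-CoA lyase EC 4.1.3.24),
the 3-HP/4-HB cycle (acetyl-CoA/propionyl-CoA carboxylase EC 6.4.1.3;
methylmalonyl-CoA mutase EC 5.4.99.2; 4-hydroxybutyryl-CoA dehydratase) and
the reductive glycine pathway (glycine reductase *grdB* EC 1.21.4.2;
methenyl-THF cyclohydrolase EC 3.5.4.9). Four starred genes (*aclA*,
*acsC/cdhE*, *rbcL*, *grdB*) serve as the per-pathway abundance markers. KO
ids are the quantification currency; genes are matched KO-first with EC
fallback, and the dual-named acetyl-CoA synthase is one marker with two
accepted symbols and EC numbers. Genes listed in more than one pathway carry
a `shared_with` annotation and are never *exclusive* evidence; the
registry validator enforces that where two pathways list the same gene they
reference each other (a one-sided entry marks a gene that also participates
in another pathway's chemistry without being a key gene there).

**Calling rule** per genome and pathway: *absent* when no key gene is
present; *complete* when every key gene and every configured companion gene
is present AND at least one present key gene is exclusive to the pathway;
*key_gene_only* otherwise. Consequently the DC/4-HB and 3-HP/4-HB cycles —
whose listed key genes are all shared — can never be called complete from
key genes alone, which is intentional: distinguishing them from overlapping
metabolism requires evidence this rule refuses to fabricate. This is the
package's answer to percent-completeness scoring of the KEGG-module/MetaCyc
kind, which overestimates pathways whose genes overlap other metabolism.
Companion genes default to empty (the non-starred enzymes are already
required key genes); users can extend them per pathway in the registry.

**Conflict resolution.** A key-gene-only call is arbitrated against
completeness among close relatives: same-genus genomes (same species when
the genus rank is unpopulated). If at least one relative holds a complete
call for the pathway and none for any competitor sharing the evidence genes,
the call is annotated with `lineage_support = (rank, n_relatives,
n_complete)`; ties or absent relatives leave it unresolved with both
candidates noted. Lineage evidence never promotes a call to complete.
A curated override table (genome id or taxon → pathway → status) can be
applied last, logged, for literature knowledge the data cannot supply.

**Dataset-level absence.** A pathway is declared absent from the whole
dataset only when no genome shows any evidence for it AND all its registry
KOs have zero per-cell abundance in every sample of both assays — the
criterion under which three of the seven pathways (3-HP bicycle, 3-HP/4-HB,
DC/4-HB) drop out of the default synthetic dataset, leaving four detected.

**Chemoautotrophy check.** RuBisCO-positive genomes are labelled
`chemoautotrophic-S-oxidizer` when they carry thiosulfate dehydrogenase
(*tsd*) or the sulfur-oxidation protein *soxZ* and no photosynthetic
reaction-centre (*puf*) genes; *puf* presence labels them
`photosynthesis-capable`; rbcL-negative genomes stay unclassified.

**Taxonomy attribution.** Each KO's per-cell abundance is split across taxa
proportionally to member genes' contributing gene copies; a cluster's
per-sample copies are shared equally among its member genes, each attributed
to its source genome's taxon at the requested rank. Row sums over taxa
reproduce the unsplit KO abundance at every rank (within 1e-9), so
genus-level splits aggregate consistently to phylum-level values.

## Environmental statistics

**Gradient encoding.** The categorical design maps to ordinals: distance to
sea marine=1, brackish=2, fresh=3 (seaward → landward, chosen so the
chloride/sulfate correlations carry their conventional negative sign —
the data determine the coding only up to joint reflection); surface
elevation pioneer=1, low=2, high=3; soil depth surface=0, deep=1.

**Loss on ignition.** The default `loss` mode returns
(DW_before − DW_after)/DW_before × 100, the conventional organic-matter
estimate; an `as_printed` mode returning the residue ratio
DW_after/DW_before × 100 is also provided, and the mode used is always
logged. Mass gain on ignition raises an error.

**Porewater concentrations.** Anion concentrations measured in a 1:10
soil:water extract are converted to per-mL-porewater values using the
fresh−dry weight difference as the native water volume w (density 1 g/mL):
`conc_porewater = conc_extract × (10 × m_fresh + w) / w`. Fully dry soil is
an error.

**Spearman correlation.** rho is the Pearson correlation of mid-ranks
(average ranks on ties). The two-sided p-value uses the t approximation
t = rho·sqrt((n−2)/(1−rho²)) on n−2 degrees of freedom, switching to the
exact permutation distribution (all n! orderings) for n <= 8 or on request.
At the study's n = 18 the α = 0.05 boundary falls between |rho| ≈ 0.45
(p ≈ 0.061) and |rho| ≈ 0.48 (p ≈ 0.044). The correlation table crosses
every target against the eight covariates (chloride, organic matter,
acetate, pyruvate, isocitrate, nitrate, sulfate, reduction index — the fixed
reporting order) with per-test significance at α = 0.05 and no multiplicity
correction by default; a Benjamini–Hochberg switch is provided. Constant
vectors are an error ("undefined correlation"), never a silent zero.

## Synthetic community generator

The generator defines the study conditions under which the package is
tested: a full 3 sites × 3 zones × 2 depth-layers crossing (18 samples), 36
genomes, ten universal single-copy marker KOs (placeholder ids MK01–MK10;
real analyses can substitute an mOTU-style marker set via the config), and
carriers of the four detectable pathways with the field's phylum
attributions (Calvin → Pseudomonadota, WLP → Desulfobacterota/Nitrospirota,
rTCA → Nitrospirota, rGlyP → Chloroflexota/Methylomirabilota). Each pathway
plants complete carriers plus one "partial" carrier holding only the starred
key gene; decoy genomes holding only a pathway's shared genes are available
via the config for caller stress-tests. Complete Calvin genomes additionally
carry *tsd* or *soxZ* (alternating) and no *puf* genes, so the
chemoautotrophy check has positive cases.

Covariates sit on gradient means (chloride 19 → 8 → 0.6 and sulfate
2.7 → 1.1 → 0.2 units/mL seaward → landward; organic matter 22% surface vs
9% deep; reduction index 0.25 vs 0.80; nitrate rising mildly with elevation)
with multiplicative log-normal noise of scale 0.15; at zero noise the
planted monotone structure is exact and the corresponding Spearman
coefficients are ±1. Genome relative abundances are drawn log-normal
(σ = 1) independently per sample and normalized to sum to one — a standard
heavy-tailed community model. Counts are Poisson (gamma-Poisson when an
overdispersion parameter is set) with metaG expectation ∝ sequencing depth ×
genome abundance × gene length, and metaT expectation additionally scaled
for a carrier's pathway genes by exp(Σ β_k z_k(sample)) over the planted
effects; defaults plant the three positive effects observed in the field
data (WLP–reduction, rTCA–nitrate, Calvin–organic matter, β = 1.5 per
standard deviation). Effect magnitudes are not reported by field studies;
β = 1.5 was chosen once as a strong-but-plausible transcriptional response
that a rank test at n = 18 can detect reliably, and is configurable.
The default sequencing depth of 50,000 reads per sample keeps a full run
under a second; all quantities downstream of the marker normalization are
depth-independent by construction, so desk-scale depths change only the
counting noise, not the expectations.

Everything is a pure function of the config seed (independent generator
streams for community, samples and counts), so identical configs produce
byte-identical artifact files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: raw reads and their quality artifacts, assembly
fragmentation and chimerism, binning contamination (QC metrics are drawn,
not earned), strain-level variation within clusters, compositional coupling
between taxa, spatial autocorrelation between neighbouring samples, and
covariate measurement error beyond simple log-normal noise. Recovery results
on synthetic data demonstrate that the pipeline's arithmetic and decision
rules are correct, not that the upstream tools' outputs are reliable.

## Design choices on open questions

* The 95% "identity" vs "ANI" wording for clustering is treated as one and
  the same per-gene nucleotide identity threshold.
* Correlation tables default to the 18 meta-omics samples; n is configurable.
* No multiple-testing correction by default (per-test P < 0.05 reporting),
  BH optional.
* Lineage-support ties between two conflicting pathways remain unresolved,
  with both candidates recorded; arbitration applies to every key-gene-only
  call (exclusive-evidence calls simply have no competitors).
* Multi-mapped reads resolve to a single best hit by default; fractional
  counting is available but not the default.

## Problem sizes

The shipped tests and the acceptance script run the generator at its default
size (36 genomes, ~580 genes, 18 samples, 5 × 10^4 reads/sample), 100-seed
recovery simulations, and 50 random 30-gene clustering instances for the
brute-force oracle comparison; a full pipeline run takes well under a minute
on one CPU.

## Known limitations

* The companion-gene lists beyond the registry's key enzymes are a user
  responsibility; defaults encode only the table shipped with the package.
* The SAM import is a best-effort text converter (identity from the NM tag)
  and is not validated against every mapper's conventions.
* Pathway calling trusts the annotation table; no HMM-based gene finding is
  performed.
* The t-approximation p-value is approximate for n > 8 with heavy ties; the
  exact permutation mode is limited to small n by factorial growth.
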