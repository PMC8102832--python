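# Methods

## Model and procedure

The pipeline treats three omics layers as evidence for a directed regulatory
edge miRNA → gene:

1. the miRNA is differential in **exosomes** between disease and control,
   ideally reversed by treatment;
2. it is differential **in tissue** in the same direction;
3. the gene carries a **seed-match site** for the miRNA in its 3′-UTR;
4. the gene is differential **opposite** to the miRNA across independent
   mRNA datasets (and, without a fold-change floor, in the proteome);
5. the gene sits in the **inflammation-relevant part of the PPI network**
   (enriched pathway or dense interaction module);
6. miRNA and gene expression are significantly **anti-correlated** across
   paired samples.

Each numbered stage is an independent module; the pipeline is their
composition, and every stage's output is usable standalone.

### Differential screen on exosomal counts

Counts are normalized to reads per million (RPM = count/column sum × 10⁶;
each sample column then sums to 10⁶ exactly) and Z-transformed per miRNA
over **all samples jointly** — the same normalization used for cross-group
heat maps, and the one that makes a single z_cut meaningful for every
pairwise comparison. A miRNA is differential between groups a and b when
|mean Z(b) − mean Z(a)| ≥ z_cut (default 1.0, configurable). Direction comes
from the Z delta; the reported log2 fold change is
log2((RPM̄_b + 1)/(RPM̄_a + 1)), which stays defined under a pooled design
with one library per group. No p-value is attached at this layer — with one
to three pooled libraries per group a variance model would be fiction; the
gate to downstream stages is the tissue layer, which does carry p-values.

Constant miRNAs (zero variance) are flagged and zeroed rather than producing
NaNs, and never called differential.

With three replicates per group and z_cut = 1, a null miRNA's ΔZ̄ has
standard deviation ≈ 0.85, so roughly a fifth of null miRNAs are called in
any single comparison and a few percent show spurious reversal patterns.
This is intentional realism: the screen is a high-recall filter, and the
false calls are removed by the tissue-consistency gate (which requires
|log2FC| ≥ 1 and p ≤ 0.05 in the same direction), not by tightening z_cut.

### Seed-match target prediction

The seed is miRNA nucleotides 2–8. With R7 = reverse complement of nt 2–8
and R6 = reverse complement of nt 2–7, a UTR occurrence classifies as:
R7 followed by A → **8mer**; R7 otherwise → **7mer-m8**; R6 not embedded in
an R7 occurrence, followed by A → **7mer-A1**; bare R6 → **6mer**. Each
position is reported once under its highest-ranked type; overlapping
occurrences of the same type are all reported. Coordinates are 0-based
half-open internally, 1-based inclusive in reports.

The retention score is a noisy-OR over sites, 1 − Π(1 − w), with weights
0.9 / 0.75 / 0.6 / 0.3 by site rank and threshold 0.7. The weights are a
deterministic, offline stand-in for proprietary service scores, chosen so
that a single 8mer or 7mer-m8 site is retained, a 7mer-A1 alone is not, and
additional sites monotonically increase confidence. Users with access to a
prediction service can pass its table through the `external` source path and
keep the identical downstream contract. CDS and 5′-UTR sites, conservation
and context features are out of scope.

### Opposite-trend integration

A predicted target enters the candidate set only if its differential
direction opposes **at least one** of its screened regulator miRNAs
(an "oppose all" mode is a flag) and it passes |log2FC| ≥ 2, p ≤ 0.05 in the
same direction in ≥ `min_support` of the mRNA datasets **in which it is
measured** (default: all of them — microarray platforms differ in coverage,
so "all four" is only required of genes all four measured). The proteome
contributes direction evidence with the p rule but no fold-change floor,
because mass-spectrometry fold changes are not on a comparable scale. Genes
whose transcriptome and proteome directions conflict are dropped with a
warning. Provenance counts satisfy
`n_transcriptome + n_proteome − n_both = |candidates|` on every run, and the
pipeline asserts this identity.

### Enrichment

One-sided hypergeometric over-representation (upper tail, computed through
scipy's log-space survival function), BH q-values via statsmodels, rich
ratio = overlap/set size. Significance is flagged on raw p ≤ 0.05 with q
reported alongside; the universe defaults to all genes in the collection and
can be overridden with a measured background. Being a discrete test, its
realized level sits slightly below nominal; the calibration check uses
universe 5000 / sets of 500 / queries of 1000, where the discreteness is
negligible and the null rate of p ≤ 0.05 calls lands within 0.05 ± 0.02.

### Markov Clustering and topology

MCL on the column-stochastic transition matrix of the weighted PPI graph
with per-node self-loops (weight = max incident edge weight, at least 1):
iterate expansion (matrix square), inflation (element-wise power 3.0 with
column renormalization), pruning of entries < 1e-5, until the max column
change < 1e-8 or 100 iterations (non-convergence returns the current
partition with a warning, never an exception). Clusters are the connected
components of the attractor support: rows with positive diagonal mass are
attractors, and nodes supported by a common attractor row merge into one
cluster. The result is a partition, invariant to node input order, and
always refines the graph's connected components.

Inflation 3 is the one prescribed parameter; everything else follows the
canonical MCL description and is configurable. At module edge probability
0.9 against a 0.05 background (20-node module, 100 nodes), the planted
module is recovered *as an exact cluster* in ≈ 19/20 seeds; failure modes
are a single low-degree module node peeling off or, at denser backgrounds, a
pendant background node being absorbed — both canonical MCL behavior, which
is why hub selection takes the largest cluster rather than requiring an
exact module.

Degree is unweighted even on weighted graphs (matching the integer "Degree"
reported by network viewers); neighborhood connectivity is the mean degree
of a node's neighbors, 0 for isolated nodes. Hubs are the union of the top
enriched set's overlap genes and the largest MCL cluster (overridable).

### Anti-correlation screen

Sample Pearson r with the analytic p from the t transform (n − 2 df);
records with constant expression are flagged undefined and excluded.
The permutation control permutes the gene vector with a seeded generator and
reports (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1) (default 1000 permutations);
under the null this is uniform, and it rank-agrees with the analytic p.
BH q is computed over **all tested pairs** (the per-gene alternative is a
documented open choice). The final screen keeps |r| ≥ 0.6 (boundary
inclusive), q ≤ 0.05 and r < 0, sorted by r ascending. Strength labels bin
|r| at 0.4 / 0.6 / 0.8; only the 0.6 cutoff gates the screen. Samples are
paired on shared sample ids; unmatched samples are dropped.

## The synthetic study generator

`generate_study(SynthConfig)` emulates the statistical structure of the
emulated study design, with every planted feature recorded in a
`GroundTruth`:

- **Counts**: negative-binomial (shape 50, i.e. ~14% biological CV — pooled
  libraries are technically tight), library size 10⁶, three groups × three
  replicates. 56 miRNAs are planted down in disease and restored by
  treatment, 60 the mirror, with 8-fold effects. Down-planted baselines are
  set `fold`× higher than up-planted ones so the library share lost by the
  down set matches the share gained by the up set; without this balancing
  the compositionality of RPM pushes every null miRNA down in disease.
- **Tissue table**: the 6 + 30 consistent DEmiRs with matching signs
  (|log2FC| ∈ [1.5, 3], p ≤ 0.01), opposite-signed decoys from the planted
  exosomal set, and tissue-only noise miRNAs.
- **mRNA / protein tables**: 4 datasets sharing a sign-consistent core of
  planted target genes (|log2FC| ≥ 2.5 > threshold 2, p ≤ 0.009) plus
  per-dataset noise genes; a small proteome overlapping the core plus two
  planted protein-only genes and unpredicted noise proteins.
- **Sequences**: random 22-nt miRNAs with pairwise-distinct seeds (the axis
  miRNA uses a canonical mature sequence whose 8mer site is GCACUUUA);
  120-nt UTRs rejection-sampled to contain **no** 7mer-m8/8mer site of any
  consistent miRNA, then one 8mer site of its planted regulator inserted
  into each planted gene's UTR. Planted predictions therefore survive the
  0.7 threshold with certainty, and strong-site predictions off the planted
  set are impossible by construction.
- **PPI**: one dense 12-gene module (edge probability 0.9, including the
  axis gene) over the planted genes plus background nodes at probability
  0.01.
- **Gene sets**: a 9-gene "pathway" overlapping the module by 6 (so
  pathway ∪ module = 15 hubs) plus random decoy sets.
- **Paired expression** (30 samples): planted pairs are constructed to an
  **exact empirical** Pearson r, drawn uniformly in −0.8 ± 0.05, by mixing
  the standardized miRNA vector with orthogonalized noise. Sampling the
  correlation instead (population ρ = 0.8) would leave each planted pair a
  ~2% chance of falling below the 0.6 cutoff at n = 30, so "every planted
  pair passes" could only hold by construction — which is the property the
  generator promises. Non-pair gene rows are independent noise.

One integer seed drives all stages through a `SeedSequence.spawn` split;
identical config ⇒ byte-identical written bundles.

**What the generator does not emulate**: miRNA families sharing seeds,
UTR length/composition bias, correlated noise across mRNA datasets,
batch effects, compositional coupling beyond the balanced design, and
measured-universe mismatch between layers. Passing tests therefore
demonstrate correctness of the inference machinery under the planted model,
not performance on real cohorts, where seed-match precision and microarray
concordance are far lower.

### Worked fixtures

`make_worked_fixture("fig3_counts")` encodes component sets sized so the
integration yields 40 up- and 193 down-regulated transcripts
(233 transcriptome candidates), 3 + 5 proteins with a 3-gene overlap — 238
candidates in total; `make_worked_fixture("hub_union")` carries the 9-gene
cytokine-pathway list and 12-gene core-module list (union 15, wired to 21
miRNAs). Named genes follow the emulated study's printed lists; all other
identifiers are synthetic placeholders, and the fixtures exist to exercise
the arithmetic, not to reproduce data.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| z_cut | 1.0 | group-mean Z-delta for an exosomal call (unstated upstream; exposed) |
| miRNA lfc / p | 1.0 / 0.05 | tissue-layer screening criteria |
| mRNA lfc / p | 2.0 / 0.05 | transcriptome screening criteria |
| target threshold | 0.7 | retention score for predictions |
| min_support | all | mRNA datasets (where measured) that must agree |
| inflation | 3.0 | MCL granularity |
| r_cut / q_cut | 0.6 / 0.05 | final anti-correlation screen |
| n_perm | 1000 | permutation control replicates |

## Numerical and design choices

- log2FC = 0 ties classify as "down" with a warning (deterministic; such
  rows never survive the |logFC| thresholds anyway).
- miRNA ids match across layers after stripping species prefixes
  (hsa-/mmu-/rno-); gene symbols match case-insensitively. All RNA
  operations run on the U alphabet; DNA input is converted on read.
- The Z delta and the pseudocounted fold change can disagree in sign near
  zero change; the reported fold change is clamped to the Z-delta direction
  (magnitude ~1e-9) so the record's direction is single-sourced.
- GMT files carry set members only, so a reloaded collection's universe is
  the member union; pass an explicit universe for a measured background.
- Report JSON uses sorted keys and fixed float formats; identical
  config + seed reproduce byte-identical artifacts.
- Problem sizes in the test and acceptance runs (300 miRNAs × 400 genes,
  20-seed replications, 1000 permutations) are chosen so the full validation
  completes in minutes on one core while keeping every planted structure
  comfortably above its screening threshold.

## Known limitations

- The differential screen is threshold-based, not a moderated-variance
  test; with replicates and raw counts, a count-model test upstream would be
  stricter.
- The target scorer is sensitivity-oriented; it has no conservation or
  context features and will over-predict relative to curated databases.
- Hub selection inherits MCL's granularity: the "core module" is the
  largest cluster, which on sparse candidate graphs can gain or lose a
  peripheral node relative to the planted module.
- Correlation is marginal Pearson over shared samples; no partial
  correlation or confounder adjustment.
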