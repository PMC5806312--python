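# Methods

This package re-implements, as one tested pipeline, the comparative
evolutionary analysis of NBS-LRR disease-resistance genes across six
closely related strawberry (*Fragaria*) genomes: domain-architecture
classification, multi-gene family clustering, pairwise Ka/Ks with
paralog/ortholog contrasts, gene trees with duplication-clade typing,
codon-model positive-selection tests, sequence-exchange (gene-conversion)
detection, chromosomal duplication-hotspot mapping, and a
pathogen-response differential-expression screen. A synthetic
multi-species generator supplies data with known ground truth for every
stage, so the whole pipeline is testable without genome downloads.

## Identification and classification

Candidate genes arrive as two hit lists (a similarity search with
E-values, and a profile search); they are merged after filtering the
first list at E ≤ 1e-4 and deduplicating. A gene is retained as an
NBS-LRR only if its domain table carries at least one NB-ARC and one LRR
hit. Classification uses only the domains N-terminal to the first NB-ARC
hit (the literature's "N-terminal domain" is operationalized by start
coordinate, since no positional rule is standard): two or more TIRs give
TTNL, one TIR TNL', RPW8 followed by CC RPW8-CNL, RPW8 alone RPW8-XNL,
CC alone CNL', and none of the three XNL'. TNL'/TTNL form the TNL
supergroup; everything else is non-TNL. A gene presenting both TIR and
CC/RPW8 (absent from the published taxonomy) is classed by the TIR with
a warning — a documented choice, not an observed case.

## Family clustering

All-versus-all similarity inside each supergroup uses a deterministic
global alignment (match +1, mismatch −1, gap open −5, gap extend −2,
free end gaps). Identity is the percent of matching columns over the
aligned span — internal gaps count against identity, terminal overhangs
do not, so a sequence contained in a longer one scores 100. Coverage is
the percent of the shorter sequence involved in residue pairings (the
denominator is a documented choice; the published criterion names no
denominator). Families are single-linkage connected components of the
graph with edges where identity > 60 **and** coverage > 60 (strict, per
the published wording); size-1 components are singletons. The family
mean identity is averaged over within-family pairs, then over families.

## Pairwise rates (NG86)

Codon alignments are produced by back-translating protein alignments
(each amino acid expands to its source codon; gaps to `---`). Ka and Ks
follow Nei–Gojobori (1986) with Jukes–Cantor correction: per-codon
synonymous site fractions exclude changes to stop codons from the
possible-change set; S is the average of the two sequences' counts and
N = 3·(codons compared) − S, exactly. Differences are averaged over all
minimal mutational pathways, skipping pathways through stops (if every
pathway is blocked, all are counted — the classical fallback). pS or pN
≥ 3/4 makes the corresponding rate undefined (saturated); a pair with
Ks = 0 has undefined Ka/Ks, never +∞. Following the study design, only
pairs with defined Ks < 1 (strict) enter the contrasts. Box summaries
use linear-interpolation quantiles; all two-group tests are Welch
t-tests (the unequal-variance form, since the variant is never stated
with "t-test" in this literature).

Known limitation: NG86's equal-weight change counting ignores
transition/transversion bias. Simulating with κ = 2 biases the estimated
Ka/Ks downward (≈0.18 at a true ω = 0.2 in our conditions); the
estimator-consistency study therefore runs at κ = 1, where the method's
assumptions hold and mean errors are below 0.02 on both Ks and Ka/Ks.

## Gene trees and duplication clades

Trees are built by neighbor joining on Jukes–Cantor distances with
pairwise deletion — a deterministic, dependency-free stand-in for an ML
program, sufficient for branch-length summaries and clade typing; ties
in the Q criterion break by smallest index pair, negative branch lengths
clamp to zero, and externally computed Newick trees can be imported
instead. Unrooted trees are midpoint-rooted before labelling. An
internal node is a duplication node iff its children's species sets
intersect; its clade is species-specific with one species in the
subtree, lineage-specific with two or more (a duplication in a common
ancestor, each duplicate lineage carrying orthologs from several
genomes). Maximal duplication clades are reported without nested double
counting. Branch-length group contrasts take explicit gene-to-group maps
(the original visual grouping is not re-derived).

## Codon models and the selection test

The GY94 rate generator assigns rate π_j·κ^[transition]·ω^[nonsyn] to
single-position codon changes, zero otherwise. For site-class mixtures
(M7: ω ~ Beta(p, q) in 10 equal-probability classes at bin medians; M8:
plus one class of proportion p1 with ω_s ≥ 1) all classes share a single
normalization — one expected substitution per codon per unit branch
averaged over classes — so a high-ω class genuinely evolves faster;
normalizing classes separately would cancel exactly the signal the
M7-vs-M8 contrast measures. Likelihoods come from Felsenstein pruning on
site patterns, gap codons treated as missing data; the reversible
construction makes the likelihood invariant to rooting, and transition
matrices come from one symmetric eigendecomposition per class per
evaluation. Codon frequencies default to F3x4 from the alignment.

Fitting is deterministic multi-start (3 fixed starts) L-BFGS-B on
log/logit-transformed parameters. By default the M7/M8 fits profile the
nuisance parameters — κ and a global branch-length scale on the NJ
tree — at their M0 estimates; both hypotheses share the fixed values, so
the models remain nested (full joint estimation is available via
`profile_nuisance=False`). 2Δln = 2(lnL_M8 − lnL_M7) is clamped at zero
and compared to χ²(df=2): > 5.991 is significant (P < 0.05), > 9.210
highly significant (P < 0.01). Families need ≥ 3 members to be
estimated, matching the published gate. Positively selected sites use
naive empirical-Bayes posteriors over the fitted classes at a 0.95
cutoff (Bayes-Empirical-Bayes priors are deliberately not reproduced).

## Sequence-exchange detection

A Sawyer-type maximal-fragment statistic on the family's polymorphic
columns: +1 per matching column, −penalty per mismatch, best contiguous
segment by a Kadane scan (leftmost-longest ties). The default penalty
equals the number of polymorphic columns, so any mismatch resets the
run — the analogue of zero mismatch tolerance in the classical tool.
Significance permutes the polymorphic-column order jointly across the
family (10,000 permutations by default) and refers each observed pair
score to the null distribution of the family-wide maximum, giving
family-wise ("global") p-values; p = (1 + exceedances)/(1 + permutations)
never returns zero. Events are pairs with global p < 0.05, classified
paralog/ortholog by species identity.

## Duplication hotspots

Gene positions are binned per chromosome in 1 Mb windows (0-based
half-open, assignment by start coordinate) over the complete bin grid.
Within a chromosome the bins form a one-way layout with species as
replicates; Duncan's multiple range test (least significant ranges from
the studentized-range distribution at protection level
1 − (1−α)^(p−1), with the protection rule that no difference inside a
nonsignificant stretch is declared significant) groups the bin means. A
bin is a hotspot when its mean exceeds that of the bin nearest the
chromosome's grand mean and no letter group joins the two. With species
as replicates a flagged bin is elevated jointly across genomes — the
"shared hotspot" notion — which is why this replicate structure was
chosen. Telomeric fractions report each chromosome's share of genes in
hotspot bins within two bins of either end.

## Expression screen

Genes pass the screen when |log₂FC| ≥ 2 **and** Benjamini–Hochberg
FDR ≤ 0.05, both inclusive. logFC uses pseudocount 1 on group means.
The per-gene test is an exact conditional binomial on group-summed
counts after total-count library normalization — a deliberately
transparent stand-in for a negative-binomial package: the pipeline's
contract is the threshold screen, and the stand-in's null calibration is
verified by simulation (super-uniform p-values). Heatmap matrices
restrict to the screened genes and order rows by average-linkage
hierarchical clustering of log₂(x+1) profiles; cross-pathogen overlaps
intersect up- and down-regulated sets separately across experiments.

## Synthetic data generator

The generator emulates the study's data shapes with known truth:

* **Species tree** — six taxa mirroring the *Fragaria* relationships
  (the cultivated octoploid with its woodland progenitor, two further
  diploid/tetraploid pairs), branch lengths on the Ks scale (expected
  synonymous substitutions per synonymous site). Defaults are shallow
  (terminal 0.03, internal 0.02), reflecting a young genus; no
  divergence-time calibration in years is attempted.
* **Gene trees** — pre-speciation duplications graft complete
  species-tree copies on the root edge (each duplicate lineage then
  carries exactly one ortholog per species, the bookkeeping invariant
  tests rely on); post-speciation duplications split random terminal
  edges. Gene loss is off by default; an optional per-leaf loss
  probability exists.
* **Sequences** — evolved down the gene tree under GY94 (uniform codon
  frequencies, κ = 2 by default) with branch lengths in Ks units; the
  synonymous-flow normalization is ω-independent, so site classes stay
  mutually consistent. Stop codons are outside the state space, making
  internal stops impossible by construction. Configs whose root-to-tip
  Ks exceeds 3 are rejected as saturated. Site-wise ω is a single value
  or a discretized-beta mixture with an optional ω_s > 1 class.
* **Architectures, placements, expression** — domain tables drawn from
  the six observed N-terminal layouts with frequencies proportional to
  the published class totals; chromosome placements with planted hotspot
  bins at a configurable enrichment shared across species; expression as
  Gamma–Poisson (negative-binomial) counts with planted log₂ effects.

One master seed feeds per-family child streams; identical configs give
bit-identical output.

What the generator does **not** emulate: indels and alignment error
(sequences are gap-free; gap handling is tested via hand-made fixtures),
intron/UTR structure, polyploid subgenomes, rate heterogeneity beyond
the ω mixture, and expression library-size or batch effects. Passing
recovery tests therefore demonstrates correctness of the estimators
under their own model assumptions, not robustness to real-data
violations of them.

## Calibration studies and problem sizes

The studies in `rgene_evoscan.studies` (also run by
`scripts/acceptance.py`) use sizes chosen to finish in minutes on one
core:

* NG86 recovery: 50 replicate 500-codon pairs at Ks 0.3, ω 0.2, κ = 1.
* M0 recovery: 20 replicates, six taxa × 300 codons at ω 0.2 (mean
  estimate within ±0.15 of truth).
* M7-vs-M8 type I: 50 replicates of four-taxon 100-codon alignments
  simulated under M7 (empirical rejection ≤ 0.10 at nominal 0.05; the
  boundary null makes the test conservative).
* M7-vs-M8 power: 300-codon alignments with p1 = 0.2, ω_s = 3 on the
  six-species topology at a deeper calibration (terminal 0.15, internal
  0.10). At the default shallow depth (~0.25 expected synonymous
  substitutions of total tree length) the data carry too few
  substitutions for any site-model contrast to be identifiable; the
  deeper setting is the power study's defining condition.
* Ks contrast: 8 families with one pre-speciation and one
  post-speciation duplication (stem 0.3): paralog pairs trace to the old
  duplication and show higher Ks than same-lineage orthologs (Welch
  P < 0.01) — the pipeline's headline evolutionary pattern.
* Hotspots: three planted 10×-enriched bins, 60 genes × 6 species,
  all recovered as shared.
* Conversion: 40%-length tracts copied between paralogs, 1000
  permutations, ≥ 90% detection; a 50-family null arm tracks the false
  rate.
* DE screen: 3 vs 3 samples, effect 4 log₂ units, dispersion 0.1
  (≥ 90% recall, ≤ 5% false flags).

## Numerical choices

* Strict inequalities at the 60/60 clustering thresholds and Ks < 1;
  inclusive thresholds at |logFC| ≥ 2 and FDR ≤ 0.05 — both exactly as
  the published criteria are worded.
* Quantiles by linear interpolation; Welch t-tests throughout; t = 0,
  p = 1 returned for exactly identical degenerate groups.
* L-BFGS-B relative tolerance 1e-8 (lnL resolution far below the 0.01
  needed at the 2Δln thresholds); bounds on log-parameters keep κ in
  [0.05, 33], ω in [3e-4, 20], beta shapes in [0.05, 100].
* NJ Q-criterion ties break on the smallest (row, column) index pair;
  negative NJ branch lengths clamp to zero with a warning.
* Permutation p-values use the +1/(n+1) estimator.
* Heatmap row order is made deterministic by a stable pre-sort on gene
  id before clustering.
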