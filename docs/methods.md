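# Methods

This note documents the models, algorithmic choices and limitations of the
package, stage by stage.

## Coordinates and I/O

Internal coordinates are 0-based half-open; GFF3 input/output is 1-based
inclusive, and round-tripping through the two conventions is the identity
(property-tested). Genome sequences are uppercased and restricted to
{A, C, G, T, N}. When a gene carries several mRNAs, the transcript with the
longest total CDS is kept, so each gene contributes exactly one protein —
the convention gene-family surveys implicitly use when they report one row
per gene. Upstream regions are always returned 5'→3' toward the gene
(minus-strand regions are reverse-complemented), with a truncation flag when
a chromosome end shortens the window. The promoter anchor is configurable:
*cis*-element profiling anchors at the transcription start, W-box target
prediction at the ATG (translation start), matching how the two analyses
are defined.

## Family identification and classification

Candidates are found by exact matching of the heptapeptide variant set
{WRKYGQK, WRKYGEK, WRKYGRK, WKKYGQK, WKRYGQK, WRKYGKK} — the canonical motif
plus the variants reported across plant families; both WRKYGEK and WRKYGKK
are retained because published family surveys attribute either to individual
members. Downstream of each heptapeptide the zinc finger is sought within an
80-residue window (comfortably beyond the ~35-residue pattern span) as
C-X₇-C-X₂₃-H-X-C (C2HC, tested first because its fixed spacer makes it the
more specific pattern) or C-X₄₋₅-C-X₂₂₋₂₃-H-X-H (C2H2). The C2H2 second
spacer accepts both 22 and 23 family-wide.

Group calls follow the structural rule (two complete C2H2 domains → I, one →
II, C2HC → III). Proteins with a heptapeptide but no complete finger are
*rescued* to the group of their best reference hit and flagged — mirroring
real family members that have lost one domain yet still cluster with group I.
Subgroups IIa–IIe are assigned by best local-alignment hit (BLOSUM62, gap
open −11 / extend −1) against a labelled reference-domain table, reporting
the score margin over the best other-label reference so low-confidence calls
are visible; ties break to the lexicographically smallest reference id with
a logged warning. The packaged reference table is a constructed, clearly
labelled synthetic stand-in with the correct structural scaffold per class;
users analysing real genomes should substitute a curated reference set
(tab-separated: ref_id, label, sequence) — the classifier itself is
agnostic to where the references come from.

Molecular weight is the sum of average residue masses plus one water
(reported in kDa; tables round half-up to 2 decimals). The isoelectric point
solves net charge = 0 by bisection on pH ∈ [0, 14] to 0.01, using the EMBOSS
pKa set (N-term 8.6, C-term 3.6; C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1). Net charge is strictly decreasing in pH, so the root is
unique. Published tables computed with other pKa sets (e.g. ExPASy) differ
by a few tenths of a pH unit; the shipped 64-gene table is fixture data and
its MW/pI columns are not re-derived.

## Promoter cis-elements

Motifs are IUPAC consensus strings matched exactly, position by position, on
both strands (minus-strand hits are reported at plus-strand offsets of the
reverse-complement match). An N in the promoter matches nothing, including
the N code — conservative treatment of assembly gaps. All overlapping hits
count; no redundancy filtering is applied, so counts can exceed those of
annotation services that collapse overlaps. The packaged library covers the
~26 named elements commonly profiled in stress studies (W-box, light-,
hormone-, stress- and development-related elements); the exact consensus
dialects vary between databases, so the library is plain data
(name / iupac / category) and is meant to be edited. Tests rely only on
planted motifs, never on particular library consensi.

## Duplication, selection and dating

Paralog pairs require protein global-alignment identity > 0.75 (identical
columns over aligned columns excluding terminal gaps) and coverage > 0.75
(both-aligned columns over the longer length) — strict inequalities.
A pair is *tandem* when on one chromosome within 100 kb start-to-start with
no third family member between them (the adjacency requirement can be
switched off), otherwise *segmental*.

Ka/Ks uses Nei–Gojobori (1986) counting on a gap-free codon alignment
back-threaded from the protein alignment: per-codon synonymous site
fractions (substitutions to stop codons count as nonsynonymous) averaged
over the two sequences; differences averaged over all minimal substitution
pathways with equal weight, discarding pathways through stop codons (if all
are blocked, all pathways are used with stop-involving steps counted
nonsynonymous); Jukes–Cantor correction d = −¾ ln(1 − 4p/3), with p ≥ ¾ a
typed saturation error. The counters agree with an exhaustive
pathway-enumeration oracle to 1e−12 on random codon pairs. Note that at a
single-codon scale a synonymous third-position difference already saturates
(p = 3 > ¾); meaningful Ks values need context codons. Duplication age is
T = Ks/(2λ) with λ = 6.1×10⁻⁹ substitutions/site/year, reported in Mya;
Ka/Ks < 1 (tolerance 1e−9 for equality) is purifying, = 1 neutral, > 1
positive, undefined when Ks = 0. Published studies often compute Ka/Ks with
other models (e.g. maximum-likelihood or approximate methods in dedicated
calculators); NG86 values are not expected to match those model-for-model.

Cross-genome orthology is approximated by reciprocal best hits under local
alignment score (ties yield no call), and collinear blocks are maximal
chains of ortholog pairs strictly increasing in one genome's gene rank and
strictly monotone (either orientation) in the other's, extracted greedily
longest-first with a minimum chain length of 3. This deliberately replaces
full orthology-inference and synteny toolchains; it recovers planted 1:1
orthologs and clean collinear runs but has none of their treatment of
paralogy complexes.

## Expression and qPCR

TPM: per-sample length-normalised rates scaled to 10⁶ (column sums are
conserved to 1e−6 relative). DEG calls between two conditions use
log₂FC = log₂((mean TPM_t + 1)/(mean TPM_c + 1)) — the pseudocount keeps
zero-TPM genes finite and is consistent with the log₂(TPM+1) transform —
and a two-sided Welch t-test on log₂(TPM+1) replicates; status requires
p < 0.05 *and* |log₂FC| ≥ 1. The >2-fold induction screen uses the same
pseudocounted ratio. The RNA-seq DE engine behind the original expression
tables is not re-implemented; the thresholds are applied to whatever matrix
is supplied, so published DEG lists are not reproduction targets.

qPCR folds are 2^−ΔΔCt with replicate pairing by (condition, replicate)
against the reference gene (18S by default). Timepoints are compared by
one-way ANOVA followed by Duncan's multiple range test: means sorted
descending, a span-p pair differing when its gap exceeds
R_p = q(1−α_p; p, df_err)·√(MSE/n) with Duncan's protection level
α_p = 1−(1−α)^(p−1); maximal runs of mutually non-significant means share a
letter. Balanced designs only (the study design is n = 3 throughout); with
two groups the procedure reduces exactly to the pooled-variance t-test
decision, which is property-tested.

## Targets, enrichment and networks

A gene is a predicted WRKY target when its 2-kb region upstream of the ATG
carries ≥1 W-box on either strand. Enrichment is the hypergeometric upper
tail per pathway — equivalent to the one-sided Fisher exact test for this
2×2 margin structure — with Benjamini–Hochberg q-values across all tested
pathways; significance requires p < 0.01 and q < 0.05. The background
defaults to all genes in the pathway map and is configurable (whether the
original analysis used all genome genes or all expressed genes as background
is not stated; the pathway-map default is the reproducible choice).

Coexpression edges are Pearson correlations (Spearman available by config)
between TF and non-TF profiles on log₂(TPM+1), retained at |r| ≥ 0.95 with
two-sided p < 0.05 from the t-distribution on n−2 df. The source study
states the threshold inconsistently across sections (p < 0.05 vs p < 0.001;
Pearson vs Spearman); the defaults follow its Methods section and both the
statistic and the cutoffs are exposed in the config. Edge sign is reported
even though biologically interesting retained edges are typically positive.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their arguments including the seed.

- `gen_family_genome` plants WRKY proteins built from the labelled reference
  domains (group I: two C2H2 domains; II: one, with a known subgroup; III:
  C2HC) inside random flanks free of W/C/H (so no spurious heptapeptides or
  fingers), reverse-translates them with random codon choice, splits the CDS
  over 2–7 exons, and places genes on both strands with ≥2.6 kb intergenic
  background at GC 0.40. Planted promoter elements are written at known
  offsets and *chance* occurrences of the same motif are scrubbed from the
  window, so truth positions are exhaustive.
- `gen_duplicate_pair` derives the second CDS by a Poisson number of
  substitutions placed at distinct synonymous/nonsynonymous sites so the
  NG86 proportions match the Jukes–Cantor-implied targets in expectation
  (at most one substitution per codon; never creating stops). Site
  categories come from the same NG86 definitions the estimator uses; this
  circularity is acceptable because the counter is validated separately
  against an exhaustive oracle.
- `gen_expression` draws log₂ baselines from U(3, 8), adds planted
  per-condition effects and per-sample module latent profiles (sd 1.5),
  applies Gaussian noise (default sd 0.2 on the log scale; module members
  can use a tighter `module_noise_sd`), exponentiates and renormalises to
  TPM. The renormalisation couples genes through the library total exactly
  as real TPM does: a strongly varying module or a large planted-effect
  fraction shifts every other gene's TPM. Consequently module-recovery
  checks use transcriptome-scale backgrounds (5,000 genes) and the study's
  4-timepoint × 3-replicate design — with 6 samples, chance |r| ≥ 0.95
  occurs at ~0.4 % per pair and exact recovery is impossible over any large
  background; at 12 samples the chance rate is ~10⁻⁶.
- `gen_ct_table` writes Ct values whose 2^−ΔΔCt folds equal the planted
  folds up to Gaussian Ct noise.

What passing these tests does **not** show: recovery of the published
counts that depend on the deposited genome and read archives — the 64
identified genes, duplicate-pair and ortholog-pair counts, pathway gene
counts, the 263-mRNA/315-edge network, and absolute qPCR magnitudes. Those
require the external data; the synthetic suites validate the machinery that
would process them.

## Problem sizes and numerical choices

Acceptance-level runs use 300-codon pairs × 20 seeds for Ks recovery,
200-gene matrices × 5 seeds for DEG operating characteristics, a
5,000-gene matrix for module recovery, 30-gene genomes for classification
accuracy, and 1,000 random sequences for scanner/oracle agreement — sizes at
which the stochastic bands (±20 % on Ks, power ≥ 0.9, null rate ≤ 0.07) are
stable across seeds. Bisection tolerance for pI is 0.01 pH; Ka/Ks equality
tolerance is 1e−9; correlation |r| ≥ 1 − 1e−12 is treated as exact
collinearity (p = 0). Means in summary tables round half-up at the precision
the annotation table prints (integer bp, 2-decimal kDa/pI).
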