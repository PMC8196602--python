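# Methods

This note documents the statistical procedures implemented in `cnitflow`,
their assumptions, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Pipeline model

The pipeline analyses log2-scale probe-level intensity matrices from two
microarray platforms (gene expression and miRNA) over four biopsy conditions:
calcineurin-inhibitor nephrotoxicity (CNIT), normal allograft (negative
control), acute rejection (AR) and interstitial fibrosis / tubular atrophy
(IFTA) (the two positive-control injuries used for marker specificity).
Matrices are log2 by contract; a `input_scale="linear"` flag applies
log2(x + 1) on load. Array-level background correction (the RMA convolution
model) is out of scope: the pipeline ingests already-summarized probe-level
log2 values.

### Hybridization QC

Archival FFPE tissue yields partially degraded RNA, so two per-sample
statistics gate the cohort **before normalization**:

* **Percent present (%P).** The canonical detection call needs PM/MM probe
  pairs that are absent at this interface, so the call implemented here is a
  background-margin rule: probe *p* is *present* in sample *s* iff
  value(p, s) > median(negative-control values in s) + margin. The margin
  defaults to 1.0 log2 unit (2-fold above background) and is configurable;
  the comparison is strict, and control probes are excluded from the %P
  denominator. Samples pass at %P ≥ 0.50. The cutoff carries a ±15%
  uncertainty band: samples with %P in [0.35, 0.65) are flagged
  *borderline* in the report (a logged warning, not a failure), while the
  operative pass/fail rule remains the 50% line — matching the action the
  filter is meant to take on a failed hybridization.
* **GAPDH 3′:5′ ratio.** ratio = 2^(mean log2 of 3′ probes − mean log2 of 5′
  probes) of the GAPDH housekeeping transcript; high values indicate RNA
  degradation (reverse transcription starts at the 3′ end). Pass iff
  ratio ≤ 3.0 (linear scale).

A sample passes QC iff it passes both. `apply_qc` drops failing columns and
never alters retained values.

### Quantile normalization

All post-QC arrays are forced onto the shared empirical distribution: the
reference is the across-sample mean of per-rank sorted values; each column's
values are replaced by the reference value at their rank. Ties within a
column receive the mean of the reference values across the tied ranks (the
convention of the common reference implementations). Numerical notes:

* on tie-free input the transform is exactly idempotent and all column
  marginals coincide with the reference (asserted to 1e-9);
* tie-averaging perturbs the sorted column vectors, so with ties the
  transform is only approximately idempotent — ties are instead guaranteed to
  stay tied and within-column rank order is preserved;
* fewer than two samples is an error.

%P is computed on raw, pre-normalization values (the QC statistic describes
the hybridization, not the normalized distribution).

### Differential expression

Per probeset, a two-sample **pooled-variance Student t** on log2 intensities
(two-sided), the historical microarray default; Welch's t is available via
`welch=True`. Degenerate probesets with zero pooled variance return p = 1
when the group means are equal and p = 0 (with a logged warning) when they
differ. Fold change is geometric — FC = 2^(difference of log2 group means) —
consistent with testing on the log scale.

Benjamini–Hochberg step-up q-values are computed **within each contrast and
platform** (per-contrast DEG counts imply per-contrast correction). The pass
rule uses the thresholds' exact strictness: p **<** p_cutoff, q **≤**
fdr_cutoff, |FC| **≥** fc_cutoff, with defaults 0.001/0.05/1.5 for gene
expression and 0.005/0.05/2.0 for miRNA.

Probeset→gene collapse: a gene is called iff ≥ 1 passing probeset maps to
it; direction is the majority sign of its passing probesets, ties broken by
the probeset with the largest |mean log2 difference| (a deterministic rule is
required for a clean up/down partition). Passing probesets without a gene
symbol are reported separately, never silently dropped. Gene symbols are
matched case-sensitively; normalization of symbol aliases is left to the
caller.

### Marker specificity

Exact three-way set algebra over gene symbols for CNIT/AR/IFTA (each vs
Normal): seven disjoint regions whose unions reproduce each input set.
Membership ignores direction — a gene up in CNIT and down in AR is still
"common" — because only symbol-level membership makes the unique/common
accounting exactly additive. "Common" means the triple intersection; the
unique-CNIT list (only-CNIT region, directions inherited from the CNIT
contrast) feeds the integration step.

### miRNA–mRNA integration

Candidate edges come from a user-supplied miRNA→target table with evidence
classes (`experimentally_observed`, `predicted_high`, `predicted_moderate`).
An edge is retained iff it is experimentally observed, its miRNA is
differentially expressed (CNIT vs Normal), its gene is in the unique-CNIT
list, and the two directions are strictly opposed (miRNA repression:
up-miRNA/down-gene or vice versa). Expression-correlation pairing is
deliberately not implemented — pairing is by sign, not per-sample
correlation. Every rejected candidate carries exactly one reason, assigned
in the fixed priority order `not_experimentally_observed` >
`same_direction` > `target_not_in_unique_list` > `mirna_not_de`, so the
audit partitions the candidate set. Output order is lexicographic by
(miRNA id, gene symbol). An empty target table is an error; an empty result
is valid.

### Enrichment and upstream regulators

For each set in a collection, the overlap p-value is the one-sided
hypergeometric upper tail P[X ≥ k] with the set restricted to a stated gene
universe (default: all genes mapped on the platform annotation — an open,
defensible reference set; configurable). Query genes outside the universe
are logged and clipped. BH adjustment runs across the whole collection with
the same implementation the DE stage uses.

The **activation z-score** works on signed set members (expected direction
under set/regulator activation, encoded in a GMT dialect as `SYM:+1` /
`SYM:-1`; bare symbols are unsigned and excluded): z = (N⁺ − N⁻)/√(N⁺ + N⁻)
with N⁺ the direction-consistent and N⁻ the inconsistent overlapping
members. With no signed overlapping member the score is *undefined* (an
error / NaN), deliberately distinct from z = 0 (balanced evidence). The
score is the simple unweighted form; weighted and bias-corrected variants
are out of scope. Regulators are "reported" at overlap p < 0.05 and called
activated/inhibited at |z| ≥ 2 (both configurable).

### Clustering and qPCR

"Supervised" hierarchical clustering means feature preselection by DE
status; the clustering itself is standard agglomerative clustering of
samples with distance = 1 − Pearson correlation over the selected features
and average linkage (the microarray-heatmap convention; both configurable).
A zero-variance sample over the selected features is an error naming the
sample. The two-cluster cut is scored against condition labels by
best-injective-mapping agreement (invariant to label renaming on either
side).

qPCR comparisons operate on ΔCt = Ct(target) − Ct(reference gene); lower
ΔCt = higher expression. The two-group test is the same pooled-variance t
as the probeset test; group means carry 95% t-based confidence intervals.

## Synthetic-data generator

`generate_cohort` emulates the study's data structure: per-probe baseline
b_p ~ Normal(8, 1.5) log2 units (a realistic microarray dynamic range),
observed value = baseline + planted condition effect + Normal(0, noise_sd)
noise with noise_sd = 0.3 (mRNA) / 0.4 (miRNA); negative-control probes at
Normal(4, 0.5); GAPDH 5′/3′ probes generated to a configurable true ratio
(default 1.5, passing). The default gene-expression cohort has 2000 probes
on 1600 genes (surplus probes assigned to random genes, giving the
many-to-one multiplicity the collapse step needs), samples 12 CNIT +
12 Normal + 7 AR + 7 IFTA, and planted effects of 1.2 log2 units on
200/80/40 disjoint probesets for CNIT/AR/IFTA — an effect size at which the
study thresholds recover essentially all planted probesets at n = 11 vs 12.
The hybridization-failure model redraws one CNIT sample's informative
probes from Normal(4.5, 0.8), putting its %P far below 50% while leaving
its control probes (and hence its GAPDH ratio) intact. The miRNA cohort is
10 CNIT + 5 Normal with 60 planted effects of 1.5 log2 units at
up-fraction 0.72 — large enough that correlation-distance clustering
separates the groups deterministically. Truth tables record every planted
effect, so recovery statistics are exact.

The deterministic fixtures pin the set-accounting structure: the venn
fixture populates the seven regions with 1245/418/107 unique, 127/45/67
pairwise-only and 66 triple-common genes (the three pairwise-only counts
are the unique solution of the linear identities relating per-set totals to
region counts), with up-fractions 714/1483, 407/678 and 88/285; the
integration fixture designates 13 true miRNAs covering 33 pairwise-distinct
targets plus decoys covering every rejection reason; the collapse fixture
maps 1837 passing probesets onto 1483 genes (354 genes × 2 probesets +
1129 × 1), 714 genes up.

What the generator does **not** emulate: probe-sequence and GC effects,
spatial array artifacts, batch structure, correlated noise between probes of
one gene, miRNA–target expression coupling, and real symbol namespaces.
Passing tests therefore demonstrate the correctness of the statistical
machinery and the set/filter logic under the stated noise model — not
robustness to the artifacts of real hybridizations.

## Known limitations

* The detection call is a background-margin stand-in for the PM/MM-based
  algorithm used on the original platform; absolute %P values are not
  comparable between the two, only the pass/fail behavior is analogous.
  Likewise, spike-in-control QC is not separately modelled.
* No moderated (empirical-Bayes) test, paired designs, or covariate
  adjustment; with very small groups the plain t-test is conservative
  compared with variance-shrinkage approaches.
* Enrichment p-values depend strongly on the chosen universe; the platform
  gene list default is principled but not unique.
* The signed-GMT dialect is this package's own; curated signed
  regulator-target collections must be supplied by the user.
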