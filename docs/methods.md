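# Methods

This note documents the models, conventions and numerical choices behind
`lncmodnet`, in the order the pipeline runs.

## Preprocessing

Genes with a missing fraction strictly greater than 20% are removed;
remaining missing values are filled with 0 and the matrix is transformed
as log2(x + 1). The pseudocount is required to keep filled zeros finite;
the transform is monotone per gene, so every rank-based statistic
downstream is unaffected by whether the input was already log-scaled.
Gene types (lncRNA vs mRNA) come from a `gene_type` column in the input
TSV; no genome-annotation lookup is performed. Clinical stage strings are
normalized to ordinal I–IV by stripping sub-stage letters ("Stage IIIA" →
III), since all stage handling is at the I–IV resolution.

## Correlation and mutual rank

Spearman correlation is computed as Pearson on average ranks, the
tie-robust definition; it reduces to the classical `1 − 6Σd²/(n(n²−1))`
form when ranks are tie-free. Genes with zero rank variance (constant
expression) get a coefficient of 0 with a logged warning rather than NaN,
so mutual ranks remain defined everywhere.

Mutual ranks are bipartite: the rank of a pair is taken within its lncRNA
row (across all mRNAs) and within its mRNA column (across all lncRNAs),
never globally. Ties receive average ranks. Under the positive
orientation rank 1 is the largest coefficient; under the negative
orientation the smallest. The selection cutoff is
`sqrt(n_lnc · n_mrna) · fraction`, with the comparison inclusive
(MR ≤ cutoff). The default fraction is 0.001 — at the ~4342 × 16619 gene
scale this evaluates to ≈ 8.49 — exposed as a configuration knob because
the sensible value depends on matrix size: the cutoff must exceed 1 to
select anything at all, and should span the mutual-rank extent of the
co-expression blocks one hopes to capture.
`synthetic.suggested_mr_fraction` encodes that scaling rule for the
synthetic fixtures: a block of B mRNAs shared by M lncRNAs occupies
mutual ranks up to sqrt(B·M), so the fraction is chosen to put the cutoff
just above that (7% margin).

## Association index

Two lncRNAs are compared through their correlated-mRNA sets over a
universe of n mRNAs (all preprocessed mRNAs). The index
`(|X∩Y|·n − |X||Y|) / sqrt(|X||Y|(n−|X|)(n−|Y|))` is algebraically the
Pearson correlation of the two 0/1 membership vectors, which is the
reading of the set-overlap formula under which its numerator and
denominator are consistent; this is an interpretive choice and is pinned
by an oracle test against indicator-vector Pearson. The index is
undefined for empty or universe-sized sets; such lncRNAs are skipped with
a warning, never given a default value. Edges require the index to be
strictly greater than the threshold (0.7 by default).

## Networks and modules

Modules are connected components with at least 12 nodes, the minimal
assumption given no named community-detection algorithm; components are
labelled P1…/N1… in decreasing size (ties broken by smallest member id).
The scale-free diagnostic is an ordinary least-squares fit of log10
degree density on log10 degree over observed degrees only, with no
log-binning. Betweenness is normalized by (n−1)(n−2)/2. Note that the
planted synthetic networks are unions of near-cliques, so their degree
distributions are *not* power laws — the fit's correctness is checked
against closed-form OLS and exact k^−2 histograms instead.

## Synthetic data generator

Each planted module draws one standard-normal latent factor per tumour
sample. Member lncRNAs and the positive mRNA block load on it with
+`latent_loading`, the negative block with −`latent_loading`, plus iid
Gaussian noise (`noise_sd`); background genes are baseline (5.0 on the
log2-like scale) plus noise, and all values are floored at 0. Normal
samples carry no factors and planted lncRNAs are shifted down by
`tumour_shift`. Defaults (3 modules × 15 lncRNAs with 60 + 60 mRNA
blocks, loading 0.9, noise 0.3, 400 tumour / 100 normal samples, 200
lncRNAs and 800 mRNAs total) give intra-module correlations around 0.9
and well-separated association networks; the background lncRNA count
matters because column-rank noise dilutes with it.

Survival times are exponential with hazard
`exp(Σ β_m·score_m + β_age(age−65) + β_stage(stage−1)) / scale`, where
`score_m` is the standardized mean member-lncRNA expression. Ages are
uniform on 45–85; stage is cut from a latent Gaussian at the empirical
quantiles of a resected-adenocarcinoma-like stage mix (55/25/14/6%), with
`stage_coupling` tilting the latent towards the hazard-weighted module
burden (0 = independent). Censoring is an independent exponential whose
rate is solved by bisection so the expected censored fraction matches
`censoring_rate` (default 0.3). PFS is a deterministic scaling of OS
(factor 0.6) with the same event indicator — enough to exercise the PFS
code paths, not a model of progression dynamics.

What the generator does *not* emulate: FPKM count noise, batch effects,
copy-number-driven expression, overlapping module membership, non-linear
lncRNA–mRNA coupling, informative censoring, or PFS-specific effects.
Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes when that structure is present and calibrates
correctly when it is absent — not that real cohorts satisfy those
assumptions.

## Survival screen and signatures

All four screen thresholds default to 0.05 and are configurable; no
multiple-testing correction is applied across lncRNAs (deliberate, to
keep the screen a sequence of plain hypothesis tests; users who need
family-wise control should tighten the alphas). The steps run
sequentially — the Cox fit is only attempted after the log-rank filter —
while the cheap stage-dependency and differential-expression tests are
computed for every lncRNA for audit purposes.

Two Cox conventions coexist by design: the *screen* tests the binary
high/low group indicator (adjusted for age and ordinal stage I–IV = 1–4),
because group-level hazard ratios are what the screen reports; the
*signature weights* come from per-lncRNA continuous-expression fits with
the same adjustment, because a risk score multiplies a coefficient by
continuous expression. Per-lncRNA (rather than joint) weight fits keep
the weights defined when module members are strongly collinear, which is
the typical case inside a co-expression module. Ties use the Efron
approximation (lifelines' default). Median splits send the median-valued
sample to the low group (strictly-greater-than = high); a constant score
is a degenerate-split error, never silently grouped.

Time-dependent AUC is the cumulative-case / dynamic-control estimator
with inverse-probability-of-censoring weights from the Kaplan–Meier
estimate of the censoring distribution (cases weighted by 1/G(T−),
controls by 1/G(t)); score ties count 1/2. In the censoring-free limit it
reduces exactly to Mann–Whitney pair counting, which the tests pin to
1e−10, and it cross-checks against scikit-survival's estimator under
censoring. Evaluation times without a case or a control report NaN, not
0. Scores follow the higher-score-riskier convention; a flag negates
protective markers.

## Preranked GSEA

Enrichment scores use the weighted running sum: hit increments
proportional to |score|^p (p = 1, normalized to 1 over the set), miss
decrements 1/(N − m), ES the signed extremum. mRNAs are scored per module
by the *mean* mutual rank over module lncRNAs (min-MR would emphasize the
single best lncRNA; mean was chosen as the aggregation that uses the
whole module), computed under the flipped ranking orientation so that a
positive-orientation module's positively correlated mRNAs receive the
highest mutual ranks. Raw mean MR is used directly as the ranking
statistic, without a further rank transform.

The null is gene-set permutation — n_perm random same-size sets drawn
from the ranked list — the only valid null for an externally ranked list;
nulls are shared across query sets of equal size. NES divides ES by the
mean of same-sign permutation scores; nominal p is the same-sign
exceedance fraction; FDR q compares each observed NES against the pooled
permutation NES distribution, positive and negative sides separately,
clipped to [0, 1]. Results are deterministic for a fixed seed.
Report-style selection (top-N by NES at FDR q < 0.001) is available via
`top_results`.

## Pipeline, determinism and problem sizes

Every stage is a pure function of its inputs and configuration; the run
manifest records sha256 checksums of all artifacts, and reruns with the
same config and seed are checksum-identical. The bundled synthetic
fixture (200 lncRNAs × 800 mRNAs × 400 samples, three planted modules)
runs the full simulate → enrich path in well under a minute on one CPU;
calibration suites (null log-rank rate at 200 replicates, Cox recovery at
50 × 1000 subjects) were sized to keep the whole validation suite in the
low minutes while leaving Monte-Carlo error comfortably inside the tested
bands.

## Known limitations

- Modules are connected components; a denser community structure inside
  one component is not resolved (a hook exists for plugging alternative
  detection).
- The screen's sequential, uncorrected tests inherit the usual
  selection-bias caveats of screening procedures.
- The association index's universe-size reading, the mean-MR aggregation
  and the p = 1 GSEA weight are documented conventions; alternatives
  (Jaccard index, min-MR) are available as flags or noted where not.
- Signature hazard ratios on real cohorts depend on cohort composition;
  the package validates procedure correctness on synthetic ground truth,
  not any cohort-specific effect size.
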