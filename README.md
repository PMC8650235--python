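# lncmodnet

Co-regulated long non-coding RNAs (lncRNAs) tend to act together, and
groups of them can carry prognostic information that single transcripts
miss. `lncmodnet` builds **lncRNA association networks** from bulk tumour
expression data, extracts co-regulated lncRNA **modules**, screens them for
**prognostic value**, scores multi-module **risk signatures**, and
characterizes each module functionally by preranked gene set enrichment.
It is aimed at computational biologists working with genes × samples
expression matrices (e.g. TCGA-style FPKM tables) together with per-sample
survival data.

## Method

1. **Correlation.** Every lncRNA–mRNA pair gets a Spearman correlation
   `SCC = 1 − 6Σd²/(n(n²−1))` (computed tie-robustly as Pearson on average
   ranks) across tumour samples.
2. **Mutual rank.** Each pair's SCC is ranked within its lncRNA row and its
   mRNA column; the mutual rank is the geometric mean
   `MR = sqrt(Rank_{X→Y} · Rank_{Y→X})`. Ranking descending picks up
   positive co-expression, ascending picks up negative co-expression.
   Pairs with `MR ≤ sqrt(n_lnc · n_mrna) · f` (f = 0.001 at the ~4.3k × 16.6k
   gene scale, giving a cutoff near 8.49) define each lncRNA's positively
   and negatively correlated mRNA sets.
3. **Association index.** Two lncRNAs X, Y are linked through the overlap
   of their correlated sets N(X), N(Y) inside the mRNA universe of size n:

   `PCC(X,Y) = (|N(X)∩N(Y)|·n − |N(X)||N(Y)|) / sqrt(|N(X)||N(Y)|(n−|N(X)|)(n−|N(Y)|))`

   — exactly the Pearson correlation of the two membership indicator
   vectors. Pairs with PCC > 0.7 form the positive / negative lncRNA
   association networks (PLAN / NLAN).
4. **Modules.** Connected components with ≥ 12 nodes, labelled P1…/N1… by
   size. Topology diagnostics: log–log OLS of degree density (scale-free
   check), degree / clustering / betweenness per node, and an intra- vs
   inter-module association comparison (Wilcoxon rank-sum).
5. **Survival screen.** Per module lncRNA: (i) median-split log-rank test;
   (ii) multivariable Cox proportional-hazards fit of the high/low group
   adjusted for age and TNM stage; (iii) stage dependency (Kruskal–Wallis
   across stages I–IV) and tumour-vs-normal differential expression
   (Wilcoxon). Survivors define the module's signature: per-sample score
   `Σ βᵢ·exprᵢ` with βᵢ the lncRNA's adjusted continuous-expression Cox
   coefficient. Module signatures are pooled by taking the union of their
   weighted lncRNAs. Signatures are evaluated by Kaplan–Meier/log-rank
   (OS and PFS), adjusted Cox hazard ratios, and cumulative/dynamic
   time-dependent AUC with inverse-probability-of-censoring weights.
6. **Enrichment.** mRNAs are ranked per module by mean mutual rank with
   the module's lncRNAs (orientation flipped so the module's own correlated
   mRNAs score highest) and tested against GMT gene sets by weighted-KS
   preranked GSEA with a random-gene-set permutation null (NES, nominal p,
   two-sided FDR q).

A synthetic-data generator plants co-regulated modules (one latent factor
per module), module-dependent Cox survival with age/stage covariates,
independent censoring, and tumour-vs-normal shifts, so the whole pipeline
can be validated against known ground truth.

## Worked example

```python
import json
from lncmodnet import PipelineConfig, run_pipeline
from lncmodnet.synthetic import default_config, suggested_mr_fraction, write_dataset

cfg_syn = default_config(seed=1)              # 3 planted modules, 400 tumour samples
paths = write_dataset(cfg_syn, "example/fixture")
config = PipelineConfig(
    expression_tumour=paths["expression_tumour"],
    expression_normal=paths["expression_normal"],
    clinical=paths["clinical"],
    out_dir="example/run",
    mr_fraction=suggested_mr_fraction(cfg_syn),  # cutoff scaled to fixture size
    n_perm=200,
    seed=1,
)
manifest = run_pipeline(config)
print(json.dumps(manifest.counts, indent=2, sort_keys=True))
```

prints

```json
{
  "mean_pos_set_size": 63.955,
  "mr_cutoff": 32.1,
  "n_edges_negative": 339,
  "n_edges_positive": 327,
  "n_lnc": 200,
  "n_modules": 6,
  "n_modules_negative": 3,
  "n_modules_positive": 3,
  "n_mrna": 800,
  "n_prognostic_lncrnas": 90,
  "n_prognostic_modules": 6,
  "n_screened": 94,
  "n_tumour_samples": 400
}
```

The three planted modules are recovered in both network orientations
(`n_modules = 6`), and nearly all planted lncRNAs pass the three-step
screen. `signatures_summary.json` in the output directory reports, for this
run, a pooled signature with hazard ratio 4.46 (95% CI 3.37–5.91,
p = 1.8e−25) for the high- vs low-score group and a time-dependent AUC of
0.886 at day 336 — the high-score group is high-risk here because the
planted module effects make it so. Equivalent CLI:

```bash
lncmodnet simulate --out example/fixture --seed 1
lncmodnet run --config example/config.yaml --seed 1
```

## Layout

- `src/lncmodnet/io.py` — expression/clinical/GMT readers, preprocessing
  (NA filter > 20%, zero fill, log2(x+1))
- `src/lncmodnet/correlation.py` — Spearman matrix, mutual rank, cutoff,
  correlated-set selection
- `src/lncmodnet/association.py` — association index and edge lists
- `src/lncmodnet/network.py` — graphs, modules, topology diagnostics
- `src/lncmodnet/survival.py` — screen, signatures, KM/log-rank/Cox,
  time-dependent AUC
- `src/lncmodnet/enrichment.py` — module mRNA ranking and preranked GSEA
- `src/lncmodnet/synthetic.py` — ground-truth generator
- `src/lncmodnet/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for modelling assumptions and design choices.
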