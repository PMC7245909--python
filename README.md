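# organmap

Multi-organ transcriptome effect-pattern scoring and serum-metabolome
screening for whole-organism pharmacology studies.

Whole herbs and other multi-component treatments act on many organs at
once, so "where does this drug act, and how strongly?" has no single-gene
answer. `organmap` implements a compact analysis for a two-group animal
study (control `CON` vs treated `RPA`) that turns bulk RNA-seq of several
vital organs and serum NMR metabolomics into one interpretable picture:

1. **Per-organ differential expression** — Welch's t on log2(FPKM + 1)
   with Benjamini–Hochberg correction; a gene is a DEG when fold change
   > 1.5 (or < 1/1.5) *and* FDR < 0.05.
2. **Organ effect model** (the core). For organ *i*, PCA reduces the
   expression matrix and the first principal component PC01 summarizes
   each sample; the normalized between-group shift is

   *y*ᵢ = (mean PC01 of treated − mean PC01 of control) / (max PC01 − min PC01),

   with the range taken over both groups pooled, so |*y*ᵢ| ≤ 1. The
   organ's DEG total *x* is fuzzified by four trapezoidal membership
   functions μ₁…μ₄ over the count axis (knots 300, 400, 550, 650, 800,
   900; linguistic terms "least", "less", "more", "most") and the
   max-operator rule assigns the winning term's weight (0.3, 0.5, 0.7,
   0.9). The per-organ **radar score** |*y*ᵢ| × weight, drawn on a polar
   chart, is the drug's organ-level effect pattern at a glance.
3. **Serum metabolome screening** — a 6 × 5 benchmark of dimension
   reductions (PCA, t-SNE, Laplacian eigenmaps, Isomap, LLE, wavelet
   transform) crossed with classifiers (NB, RF, BPNN, kNN, SVM) under
   repeated stratified CV; an SVM ROC feature model with leakage-free
   in-fold feature selection; OPLS-DA (Trygg–Wold) with R²X / R²Y / Q²
   and VIP scores, screening differential metabolites by VIP > 1.0 plus
   t-test p < 0.05; and a Pearson correlation network over metabolites.
4. **Synthetic study generator** — log-normal expression and Gaussian
   metabolite intensities with known injected effects, emulating the
   7-organ, n = 3/group transcriptome and n = 7/6 metabolome design, so
   the whole pipeline is testable end to end with no external data.

## Worked example

```python
import organmap as om

config = om.SimulationConfig(seed=7)          # the default 7-organ study
pairs = []
for organ in config.organs:
    expr, _ = om.simulate_organ_expression(config, organ)
    records = om.call_degs(expr)              # FC > 1.5, FDR < 0.05
    pairs.append((om.pc01_summary(expr), om.summarize_organ(records, organ)))

for r in om.organ_effect_scores(pairs):
    print(r.organ, r.n_degs, r.weight, round(r.y_i, 3), round(r.radar_score, 3))
```

prints

```
organ     DEGs weight     y_i   radar PC01 rate
heart        0    0.3   0.614   0.184     0.229
liver      758    0.7   0.959   0.672     0.834
spleen       0    0.3   0.376   0.113     0.231
lung         0    0.3   0.485   0.145     0.221
kidney       0    0.3   0.662   0.199     0.245
brain      408    0.5   0.977   0.488     0.820
adrenal      0    0.3   0.937   0.281     0.573
```

Read: the liver ranks first (758 DEGs recovered at n = 3 → weight 0.7;
near-maximal PC01 shift 0.959 → radar score 0.672), the brain second, and
organs without injected effects fall to the 0.3 weight band with small
scores — the injected liver ≫ brain > rest pattern is recovered. The
metabolome branch of the same seed gives

```
OPLS-DA: R2X = 0.350, R2Y = 0.997, Q2 = 0.922
screen: 16 differential metabolites; top 3:
  m006  VIP = 1.988  p = 7.73e-09
  m012  VIP = 1.893  p = 1.31e-05
  m010  VIP = 1.858  p = 1.40e-05
```

recovering the 16 injected differential features (high Q² = strong
cross-validated class prediction).

The same stages are available from a shell:

```bash
organmap simulate --outdir run/ --seed 7
organmap degs --expr run/expr_liver.tsv --out run/degs_liver.tsv
organmap organ-effect --expr-dir run/ --out run/radar.svg
organmap oplsda --data run/metabolome.tsv
organmap run --outdir full_run/ --seed 7     # everything, with a JSON report
```

## Layout

| module | contents |
| --- | --- |
| `organmap.simulate` | synthetic study generator with ground truth |
| `organmap.degs` | DEG calling and per-organ up/down summaries |
| `organmap.organ_effect` | PC01 amplification, fuzzy weights, radar scores |
| `organmap.benchmark` | reductions × classifiers table, SVM ROC model |
| `organmap.oplsda` | OPLS-DA, VIP, metabolite screen, correlation network |
| `organmap.io` / `organmap.cli` | TSV/CSV readers-writers, run orchestration |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
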