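# stepcourse

Step-model profiling of staged RNA-seq time courses.

Differentiation processes — the motivating system is the in-vitro maturation
of human memory B cells (MBC) through preplasmablasts (prePB) and
plasmablasts (PB) into antibody-secreting plasma cells (PC) — are sampled as
a short series of ordered stages with a few replicates each. `stepcourse`
dissects such a count matrix end to end:

1. **Normalization** — median-of-ratios size factors: for sample *j*,
   `s_j = median_g ( K_gj / (∏_j K_gj)^(1/m) )` over the genes with strictly
   positive counts everywhere, then `normalized = K_gj / s_j`.
2. **Active-expression calling** — the distribution of stage-mean
   log2 expression is bimodal (background vs. transcribed); a two-component
   Gaussian mixture fitted to the pooled values yields a data-driven cutoff
   at the equal-posterior crossing, and genes are categorized by their
   activity footprint across stages (all-stages / stage-specific /
   multi-stage / inactive).
3. **Differential expression** — for each pair of consecutive stages, a
   negative-binomial Wald test (`K_gj ~ NB(s_j·q_g·2^(x_j·β_g), μ + αμ²)`)
   with moment dispersions shrunk toward a mean–dispersion trend,
   Benjamini–Hochberg adjustment pooled across all contrasts (global FDR),
   and the abundance (mean normalized count ≥ 64 in one group) and
   fold-change (≥ 2) filters.
4. **Step-pattern classification** — the core method: every gene's
   replicate-level log2 trajectory is fitted by all piecewise-constant
   models with 0, 1 or 2 transition points; BIC (or nested F-tests) selects
   one; transitions smaller than 1 log2 unit are demoted. The selected model
   maps to the four temporal patterns — one-step-up, one-step-down,
   two-step-up-down, two-step-down-up — and a transition stage
   ("up-at-prePB" = low at MBC, high from prePB onward).
5. **Regulator annotation & ORA** — pattern groups are crossed with
   user-supplied transcription-factor / epigenetic-enzyme catalogs and
   tested for gene-set over-representation with the exact hypergeometric
   tail against the actively-expressed universe.

A synthetic-data generator plants known step programs under NB noise with
library-size confounding, so the whole pipeline is testable without
external data.

## Worked example

```python
import stepcourse as sc

sim = sc.simulate(sc.SimulationConfig(n_genes=2000, seed=42))
norm = sc.MedianOfRatiosNormalizer().fit_transform(sim.counts)
prof = sc.stage_profile(norm, sim.design)

thr = sc.ActiveExpressionClassifier(threshold="auto", random_state=0).fit(prof)
cls = thr.predict(prof)
print("threshold:", round(thr.threshold_.value, 2))

de = sc.NegativeBinomialDE().fit(sim.counts, sim.design)
print(de.summary_.to_string(index=False))

active = set(cls.index[cls["category"] != "inactive"])
fits = sc.StepPatternProfiler().fit(prof, sorted(active & de.de_genes_))
print(fits.summary_.to_string(index=False))
```

prints (abridged):

```
threshold: 9.62
      contrast    up  down  total
MBC__vs__prePB 182.0 151.0    333
 prePB__vs__PB 196.0 155.0    351
    PB__vs__PC 166.0 167.0    333
         union   NaN   NaN    729
           label transition_stage  n_genes
     one-step-up            prePB       83
     one-step-up               PB       90
two-step-up-down            prePB      100
...
```

The fitted threshold (9.62 normalized counts) sits at the crossing between
the simulation's background mode and its expressed mode; the DE summary
counts up/down genes per consecutive-stage contrast plus their union; the
step summary is the count of genes per temporal pattern and transition
stage. Comparing the fitted patterns with the generator's truth table via
`sc.evaluate_recovery` gives 97% label accuracy on this dataset.

The same pipeline runs from the shell:

```sh
stepcourse simulate --out sim --n-genes 2000 --seed 42
stepcourse run-all --counts sim/counts.tsv --design sim/design.tsv \
    --tf tf_list.txt --gene-sets pathways.gmt --out results
```

For a real dataset, point `--counts` at a genes × samples TSV of raw counts
and `--design` at a sample sheet (`sample_id`, `stage`, `replicate`); the
stage order is declared with `--stage-order`, never inferred.

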