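# dmhseq

Cell typing and genotype-contrast differential expression for
dorsomedial-hypothalamus (DMH) single-cell and bulk RNA-seq.

The package re-implements, as a tested and reusable pipeline, the
transcriptomic analysis used to characterise DMH cell populations in a
two-genotype mouse experiment (wild type vs a knockout of the RIIβ
regulatory subunit of protein kinase A):

* **QC** — discard cells with < 500 UMIs or > 40% mitochondrial reads;
  keep genes with ≥ 2 counts in ≥ 5 cells.
* **Normalization** — scale each cell to the median total transcript
  count, log₂-transform after a pseudocount:
  `v[g,c] = log2(count[g,c] / total[c] · median_total + 1)`.
* **Variable genes** — rank genes by dispersion (variance/mean) scaled
  against the median dispersion of their mean-expression bin (50
  equal-frequency bins, robust z), keep the top 1000.
* **Embedding and clustering** — Barnes–Hut t-SNE of the standardized
  variable genes; deterministic density clustering in the 2-D map with
  nearest-centroid back-assignment, iterated on the neuron subset.
* **Annotation** — clusters are called neuronal/non-neuronal by a
  two-component Gaussian mixture on the aggregated medians of *Snap25*,
  *Syp*, *Tubb3*, *Elavl2*; neuron clusters are GABAergic when
  median *Slc32a1* > median *Slc17a6* and glutamatergic for the reverse;
  non-neuronal clusters take the argmax over canonical markers (*Agt*
  astrocytes, *Flt1* endothelial, *Cx3cr1* microglia, *Opalin*
  oligodendrocytes, *Pdgfra* OPC, *Vtn* pericytes, *Acta2* vascular
  smooth muscle).
* **Differential expression** — per-gene negative-binomial GLM
  (`variance = μ + φμ²`, log link, two-group Wald or LRT) with
  median-of-ratios size factors for bulk samples and total-count size
  factors for cells; Benjamini–Hochberg adjustment; a gene is a DEG when
  |log₂FC| ≥ log₂(1.5) and adjusted p ≤ 0.05.
* **Pathway scoring** — mean normalized expression of a gene set per
  cell/cluster, Pearson score–score correlation, and hypergeometric
  over-representation of query lists in named sets.

Because no raw data are deposited for the original experiment, the
package ships a first-class synthetic generator (`dmhseq.synth`) that
emulates the DMH dissection — eight marker-defined cell classes, a
GABAergic/glutamatergic neuron split, NB counts with lognormal library
sizes and mitochondrial fractions, and the genotype effects of interest
(full *Prkar2b* ablation, ~1.5-fold *Prkar1a* up-shift, coordinated
shifts of PKA-activity and GABA-transport gene sets) — together with the
ground truth needed to score recovery.

## Worked example

```python
import dmhseq as d

cfg = d.GeneratorConfig(seed=1)            # 2000 genes, 1500 cells/genotype
m, truth = d.simulate_counts(cfg)
res = d.run_pipeline(m, seed=1)
print(d.profiles_frame(res.profiles))
```

prints the annotated round-1 clusters:

```
 cluster_id  n_cells  neuron_score  gmm_posterior_high  neuron        cell_type
          0      954         5.292                 1.0    True          neurons
          1      823         5.287                 1.0    True          neurons
          2      384         1.422                 0.0   False       astrocytes
          3      234         1.453                 0.0   False oligodendrocytes
          4      154         1.416                 0.0   False              opc
          5      148         1.585                 0.0   False        microglia
          6      130         1.435                 0.0   False      endothelial
          7       87         1.486                 0.0   False              vsm
          8       86         1.508                 0.0   False        pericytes
```

The two neuron clusters split cleanly in the neurons-only re-clustering
round (`profiles_frame(res.neuron_profiles)`):

```
 cluster_id  n_cells  median_Slc32a1  median_Slc17a6      nt_class
          0      954           5.330           1.420     GABAergic
          1      823           1.456           5.239 glutamatergic
```

The recovered partition matches the generative truth with an adjusted
Rand index of 0.999.  Testing the genotype contrast within the
GABAergic class:

```python
de = d.sc_group_test(m, truth.cells["nt_class"].to_numpy(), "GABAergic",
                     contrast=("WT", "KO"))
print(de.summary())
```

```
Negative-binomial differential expression
==============================================
contrast:        KO vs WT  (n = 502 vs 454)
test:            wald
genes:           2000 (0 untestable)
calling rule:    |fold| >= 1.5 and BH-adjusted p <= 0.05
DEGs:            8 (4 up, 4 down)
```

The ablated *Prkar2b* is recovered with a −∞ log₂ fold change and an
adjusted p of ~0; *Prkar1a* comes out strongly significant with a
positive estimate (0.54 here) that fluctuates around its true value of
log₂(1.5) ≈ 0.585 — exactly the calling threshold, so the fold rule
admits it in only about half of the runs (see `docs/methods.md`).

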