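# liveraging

Analysis toolkit for **aging-trajectory plasticity** in liver multi-omics:
how early-life toxicant exposures disrupt the gene-expression changes that
normally occur as the liver matures, and how those disruptions read out in
the epigenome and in human disease cohorts.

## The problem

Between weaning and young adulthood the mouse liver remodels its
transcriptome: a defined set of genes retains the *plasticity* to change
expression with age (up or down). Developmental exposures — endocrine
disruptors, dioxins, particulates — preferentially reprogram exactly these
plastic genes. The package implements the analysis stack for that question:

- **Differential calling** with the standard rule: BH-adjusted FDR < 0.05
  and linear fold change > 1.5× (genes via CPM + Welch *t* on
  log₂(CPM+0.5); peaks via a library-normalized G-test on tiled window
  counts with adjacent-window merging).
- **Trajectory classification.** For a gene in both the aging signature
  and an exposure signature: *attenuated* if the exposure opposes the
  aging direction (an aging-up gene "remains low", an aging-down gene
  "remains high"), *accelerated* if it reinforces it.
- **Regulatory mapping.** Promoter windows (TSS ± 3 kb, strand-aware,
  half-open), *enhancer anchors* (overlapping/book-ended catalog enhancers
  merged, gene links unioned), ≥1-bp peak-to-gene assignment, and
  polarity-aware concordance: an active mark (H3K27ac, H3K4me1, H3K4me3)
  is concordant when it moves with expression, a repressive mark
  (H3K27me3, H3K9me3) when it moves against it. Genes partition into
  promoter-only / enhancer-only / both / neither categories.
- **Enrichment.** Hypergeometric ORA, preranked GSEA (weighted KS running
  sum, ES/NES, empirical p), and a permutation test for whether two
  exposures' enriched-pathway lists overlap beyond chance: 10,000
  permutations matched to the list sizes, normal fit, upper-tail p.
- **Signature activity.** Per-gene z-scores across samples; the summed
  z-score statistic `score(s) = Σ_{g∈up} z_gs − Σ_{g∈down} z_gs`; Pearson
  correlation between signatures and against ordinal disease severity;
  mouse→human homolog mapping with conflict handling.
- **Synthetic study generator** with full ground truth (planted aging and
  exposure effects, concordant/discordant mark peaks, an enhancer catalog
  with ~8 links per gene, severity-driven cohorts), so every stage has a
  recovery target.

## Worked example

```python
from liveraging import (SimulationConfig, simulate_study, call_degs,
                        derive_signature, classify_trajectories, overlap_fraction)

bundle = simulate_study(SimulationConfig(n_genes=800, n_exposure_genes=160, seed=3))
m = bundle.expression
aging = derive_signature(call_degs(m, m.sample_ids(age="wk3", exposure="vehicle"),
                                   m.sample_ids(age="mo5", exposure="vehicle")), "aging")
exposure = derive_signature(call_degs(m, m.sample_ids(age="mo5", exposure="vehicle"),
                                      m.sample_ids(age="mo5", exposure="TBT")), "TBT")
calls, summary = classify_trajectories(exposure, aging)
```

prints (via `python examples/02_differential_and_trajectories.py`):

```
aging signature: 36 up / 88 down genes
TBT signature:   72 up / 57 down genes
overlap: 71/129 of the exposure signature (55%) are aging-plasticity genes
  attenuated: 52   accelerated: 19
```

So 55% of the exposure's differential genes are aging-plasticity genes, and
for 52 of the 71 shared genes the exposure *blocks* the normal age change
(the generator planted attenuated:accelerated at 5:2 — recovered here as
52:19). The `examples/` directory has one script per capability
(simulation, differential + trajectories, anchors + concordance,
enrichment + overlap network, cohort scoring, full pipeline); each prints
the numbers it computes and what they mean.

The same flow runs from the shell:

```bash
liveraging run-all --seed 1 --out results/run1   # writes report.json + intermediates
```

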