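# chromexpress

Integrative analysis of histone-mark ChIP-seq and RNA-seq in FACS-sorted
planarian stem cells under an RNAi knockdown-vs-control design. The
package implements, as a tested and reusable pipeline, the computational
stages of such a study:

- **Exogenous spike-in (ChIP-Rx) normalization.** Fragments aligned to a
  combined target + spike-in reference (*Drosophila* S2 chromatin added at
  a fixed proportion per cell) are partitioned by genome, deduplicated on
  exact coordinates, and the target coverage of each sample is scaled by
  α = 10⁶ / (spike-in fragment count). The matching scaled input track is
  subtracted per bin. Because the spike-in measures IP and library
  efficiency per cell, genuine genome-wide shifts between conditions
  survive this scaling — whereas library-size scaling forces every sample
  to the same total and erases them.
- **Expression-compartment classification.** A gene is enriched in the
  X1 (G2/M stem cells), X2 (G1 stem cells and progeny) or Xins
  (differentiated cells) compartment when strictly more than 50% of its
  expression is observed there; otherwise it is unclassified.
- **Differential-expression selection** from a per-gene (log₂FC, p)
  table: up-regulated means log₂FC ≥ log₂ 1.5 and p < 0.05; down-regulated
  symmetric. The DE fit itself is consumed as input.
- **TSS metagene profiles**: strand-aware per-gene windows of ±2 kb
  around the TSS from subtracted tracks, averaged per class with SD
  bands, plus knockdown/control log₂-ratio profiles.
- **Hypergeometric enrichment** of DE lists against the classes
  (upper-tail exact test, significant at p < 0.01) and generic term
  enrichment ordered by mean log₂FC.
- **Mark/expression integration**: per-gene mean change of subtracted
  signal over TSS ± 2 kb, Spearman-correlated with expression log₂FC per
  class and mark — with average-rank ties, exact permutation p-values for
  n < 10, the |log₂FC| ≥ 1 filtered variant, and significance at p < 0.001.

A synthetic-data module generates every input with planted ground truth
(three marks + input, two conditions, ~15% spike-in, three expression
classes, a Gaussian-copula coupling between promoter mark changes and
expression changes), so the whole pipeline is exercised and validated
without any download.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/02_spike_normalization.py
```

prints:

```
simulated 1000 genes on a 6 Mb chromosome
class sizes: {'Xins': 300, 'X2': 300, 'X1': 300, 'none': 100}
planted DE: {'unchanged': 950, 'down': 25, 'up': 25}
shift 0.5: spike-normalized ratio 0.5003, library-size ratio 1.0002
shift 1.0: spike-normalized ratio 1.0003, library-size ratio 1.0002
shift 2.0: spike-normalized ratio 1.9996, library-size ratio 1.0002
shift 4.0: spike-normalized ratio 3.9964, library-size ratio 1.0000
```

Each line plants a genome-wide knockdown yield shift and reports the
knockdown/control ratio of genome-wide subtracted signal: spike-in
scaling recovers the planted shift to within a fraction of a percent,
while library-size scaling reports ~1.0 for every shift — it cannot see
global changes at all. Continuing with `03_classify_and_de.py` through
`06_enrichment.py` classifies genes (100% agreement with planted labels),
recovers the planted DE counts exactly, writes per-mark metagene profiles,
and produces the correlation report, in which the planted X1 / H3K4me1
inverse coupling (ρ = −0.5) is the only cell significant at p < 0.001
(recovered ρ = −0.47, p ≈ 3×10⁻¹⁸, n = 300).

The same stages are available as one command over a YAML config:

```bash
chromexpress run-all --config demo.yaml --seed 42
```

where a minimal `demo.yaml` is

```yaml
seed: 42
output_dir: demo_out
simulate: {}
```

This writes normalized bedGraph tracks, classification, DE, metagene,
correlation and enrichment tables plus a `manifest.json` with checksums;
reruns are byte-identical. Subcommands `simulate`, `normalize`,
`classify`, `de` and `enrich` expose the individual stages.

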