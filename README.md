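# cytobalance

Analysis toolkit for cytonuclear transcriptional coordination in nascent
autopolyploids. Starting from gene-level RNA-seq read counts (real or
simulated), it quantifies how nuclear, plastid and mitochondrial
transcriptional outputs respond to whole-genome duplication:

- **TPM quantification** (`cytobalance.quantify`) — reads-per-kilobase
  normalization, replicate means, per-gene ploidy-ratio distributions.
- **Annotations** (`cytobalance.annotations`) — genome-of-origin from locus
  ids (`AT1G`–`AT5G` / `ATCG` / `ATMG` / `ERCC-`), exon-union gene lengths
  from GFF3, organelle-targeting classes and interaction tiers from a
  targeting table.
- **Spike-in dosage normalization** (`cytobalance.spikenorm`) — proportional
  ERCC spiking rules, transcriptome-size estimates, and expression per
  genome copy (plant reads scaled by spike reads).
- **Compartment stoichiometry** (`cytobalance.stoichiometry`) — targeted
  fractions, organelle/nuclear bulk ratios, organelle-to-targeted balance
  ratios, ratio CVs by interaction tier, chimeric-complex correlations.
- **Statistics** (`cytobalance.stats`) — Kruskal–Wallis with tie
  correction, Dunn post-hoc with Benjamini–Hochberg adjustment, one-way
  ANOVA with Bonferroni-corrected t-tests, OLS regression.
- **qPCR copy number** (`cytobalance.qpcr`) — ΔΔCq fold changes of
  organelle-genome copy number against the geometric mean of two nuclear
  reference genes.
- **Synthetic data** (`cytobalance.synthetic_data`) — a fully specified
  tri-genome generative model (gamma-multinomial counts, ploidy-dependent
  organelle genome copy numbers, class dosage multipliers, tier-coupled
  ratio noise, proportional spike pools, qPCR plates) with a shipped
  `paper_calibrated` preset and a truth record for recovery testing.

## CLI

```sh
# write a synthetic experiment (counts, annotation, metadata, spike design, qPCR plates)
cytobalance simulate --preset paper_calibrated --seed 42 --out simulated/

# figure-table report (fig2...fig13 TSVs + stats + run manifest)
cytobalance analyze --counts simulated/counts.tsv \
    --annotation simulated/annotation.tsv --meta simulated/samples.tsv \
    --out report/

# organelle copy-number estimates from a qPCR plate
cytobalance qpcr --plate simulated/qpcr_plate.tsv --out qpcr_report/
```

All commands also accept `--config file.yaml` with the same keys as the
flags. Exit codes: 0 success, 2 usage error, 3 data error.

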