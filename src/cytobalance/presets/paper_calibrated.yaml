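n_nuclear_genes: 5000
n_plastid_genes: 80
n_mito_genes: 50
n_spike_species: 92
class_proportions:
  plastid: 0.12
  mitochondrion: 0.1
  dual: 0.06
  other: 0.52
  unknown: 0.2
tier_proportions:
  none: 0.5
  complexed: 0.3
  direct: 0.2
base_rates:
  plastid:
  - 1.5
  - 1.2
  mitochondrion:
  - 0.8
  - 1.2
  dual:
  - 1.5
  - 1.2
  other:
  - 0.0
  - 1.2
  unknown:
  - -0.5
  - 1.2
plastid_gene_rate:
- 2.2
- 1.0
mito_gene_rate:
- 2.0
- 1.0
spike_rate:
- 0.0
- 1.5
organ: leaf
ploidy_levels:
- 2C
- 4C
reps_per_ploidy: 3
organelle_genome_response:
  4C:
    plastid: 0.76
    mitochondrion: 1.01
  8C:
    plastid: 0.6
    mitochondrion: 0.95
dosage_multiplier:
  4C:
    plastid: 0.9
    mitochondrion: 1.05
    dual: 0.95
    other: 1.1
    unknown: 1.1
  8C:
    plastid: 0.8
    mitochondrion: 1.0
    dual: 0.9
    other: 1.15
    unknown: 1.15
tier_coupling:
  none: 0.55
  complexed: 0.88
  direct: 0.985
ratio_noise_sd: 0.45
tier_shared_sd: 0.02
organelle_gene_noise_sd: 0.05
coordination_mode:
  plastid: coordinated
  mitochondrion: boosted
organelle_boost:
  4C:
    plastid: 1.0
    mitochondrion: 1.25
  8C:
    plastid: 1.0
    mitochondrion: 1.35
dispersion: 0.05
depth: 5000000
spike_fraction: 0.02
rna_per_dna: null
qpcr_noise_sd: 0.02
seed: 42
complexes:
- complex_id: RUBISCO
  organelle: plastid
  chimeric: true
  members:
    ATCG00490: 700.0
    AT1G67090: 150.0
    AT5G38430: 60.0
    AT5G38420: 25.0
    AT5G38410: 12.0
- complex_id: PSII
  organelle: plastid
  chimeric: true
  members:
    ATCG00020: 1200.0
    ATCG00270: 130.0
    ATCG00280: 90.0
    ATCG00580: 45.0
    ATCG00710: 18.0
    ATCG00080: 8.0
    AT5G66570: 120.0
    AT1G06680: 60.0
    AT4G21280: 28.0
    AT1G79040: 12.0
    AT2G30570: 5.0
    AT3G21055: 2.5
- complex_id: OXPHOS_III
  organelle: mitochondrion
  chimeric: true
  members:
    ATMG00220: 200.0
    AT3G27240: 60.0
    AT5G40810: 25.0
    AT4G32470: 10.0
    AT2G40765: 4.0
    AT1G51980: 1.7
- complex_id: OXPHOS_II
  organelle: mitochondrion
  chimeric: false
  members:
    AT5G66760: 80.0
    AT3G27380: 30.0
    AT5G40650: 12.0
    AT1G08480: 5.0
mito_rrna_gene: ATMG00020
mito_rrna_share: 0.45
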