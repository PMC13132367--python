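# cdc1niche

Reusable pipeline for three computational arms of cDC1 / CD8 T-cell tumor
immunology analysis, plus seeded synthetic-data generators so the whole
pipeline is testable at desk scale:

1. **Cohort signatures** (`cdc1niche.signatures`) — bulk RNA-seq TMM
   normalization and log2-CPM, cross-cohort gene-signature derivation
   (detectability filter → meta-signal → Spearman importance filter →
   cross-cohort intersection), kernel-CDF rank-enrichment scoring (the
   'gsva' method of Hänzelmann et al., implemented from scratch), 1–10
   min-max rescaling for display, Mann–Whitney response-group comparisons
   and correlation panels.
2. **mIF spatial statistics** (`cdc1niche.mif`) — triclass-Otsu marker
   thresholding, priority-rule phenotyping (BATF3+ → cDC1, else CD8+ →
   CD8T, else CD3+ → CD4T, else other), border trimming, occupancy-grid
   tissue area, per-phenotype densities, cDC1→T nearest-neighbour
   distances and triad radii, rank-sum group tests, median-split
   log-rank/Kaplan–Meier and per-decile Cox models.
3. **Spatial-transcriptomic niches/hubs** (`cdc1niche.hubs`) — molecule-count
   QC, two-method candidate detection (KDE-valley thresholding on canonical
   gene sums ∧ Leiden cluster annotation) with a consensus rule, 10-µm-radius
   hub construction aggregating neighbouring transcriptomes, cDC1-rich /
   cDC1-devoid classification (≥ 1 BATF3/XCR1/CLEC9A molecule), hub
   differential expression (pluggable rank-sum default, BH-corrected),
   preranked GSEA, and median-ratio-normalized anchor-gene Spearman
   correlations for tumor-compartment validation data.

`cdc1niche.synthetic` provides the matching generators: negative-binomial
bulk cohorts with latent cell-type abundances and response labels, planar
point patterns with tunable T-cell attraction to cDC1 positions, and
cell×gene Poisson matrices with canonical-marker and near-cDC1
activation-gene elevation. All generators are deterministic in a single
seed and retain hidden truth for recovery tests.

## CLI

One subcommand per stage; configuration is a flat key-value YAML file
(unknown keys are rejected before anything runs). Every run writes a
`manifest.json` with the resolved parameters, seed, input checksums and
per-stage row counts.

```sh
cdc1niche simulate-tissue --config tissue.yaml --out out/ --seed 1
cdc1niche simulate-bulk   --config bulk.yaml   --out out/
cdc1niche simulate-st     --config st.yaml     --out out/
cdc1niche signatures      --config sig.yaml    --out out/
cdc1niche mif             --config mif.yaml    --out out/
cdc1niche hubs            --config hubs.yaml   --out out/
cdc1niche run             --config any.yaml            # stage named inside
```

Example `mif.yaml`:

```yaml
stage: mif
cells: sample0.csv,sample1.csv
clinical: clinical.csv
margin_um: 20
bin_um: 50
outdir: out/mif
seed: 1
```

File formats: counts as gzip TSV (`gene` column + sample columns) or
MatrixMarket triplet with `.genes.txt` / `.columns.txt` sidecars; cell
tables as CSV (`cell_id,x_um,y_um,BATF3,CD3,CD8[,...]`, microns); clinical
tables as CSV (`sample_id,response[,os_time,os_event]`); gene sets as GMT.

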