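# biogeo

Statistical toolkit for the latitudinal biogeography of sediment microbial
communities — bacteria, archaea and fungi surveyed as OTU tables along an
Arctic shelf-to-basin transect (60–80 °N), or any comparable amplicon
survey with per-sample geography and environmental covariates.

It is written for microbial ecologists who want the full numerical chain
of a marine-sediment biogeography study as tested, scriptable Python
rather than an ad-hoc collection of R calls:

* **Alpha/beta diversity** — richness and Shannon index (nats) on rarefied
  counts; Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).
* **Distance–decay relationship (DDR)** — OLS of community similarity
  (1 − Bray–Curtis) on great-circle distance over all sample pairs, slope
  reported per 100 km.
* **Permutation tests** — Mantel, PERMANOVA (Anderson's pseudo-F from
  squared distances), ANOSIM (rank-based R), MRPP (weighted within-group
  δ), all with label/row shuffling and p = (#extreme + 1)/(n_perm + 1);
  plus nonmetric MDS (Kruskal stress-1).
* **Constrained ordination** — CCA on the chi-square–standardized table
  with VIF > 10 pruning and Monte-Carlo significance; variation
  partitioning into pure-environmental, pure-spatial, shared and residual
  fractions via permutation-adjusted R².
* **Specialist detection** — specificity (share of an OTU's per-habitat
  mean abundance) and occupancy (within-habitat presence frequency);
  both ≥ 0.7 flags a habitat specialist.
* **Co-occurrence networks** — per region: prevalence > 50%, Spearman
  |ρ| > 0.7 with Benjamini–Hochberg-adjusted p < 0.05; topology as nodes,
  links, avgK = 2L/N, average clustering coefficient, and Newman
  modularity of the greedy (CNM) partition.
* **Synthetic transect generator** — 72 stations with latitude-trending
  covariates, domain-specific community turnover (archaea fastest),
  planted region specialists and correlated OTU blocks, so every stage
  can be validated against a known ground truth.

## Worked example

Generate the default synthetic transect and fit the distance–decay
relationship per domain:

```python
from biogeo import synth, tables, diversity, spatial, specocc

cfg = synth.SynthConfig(seed=1)
meta = synth.generate_metadata(cfg)
geo = spatial.haversine_matrix(meta)
for domain in ("bacteria", "archaea", "fungi"):
    counts = synth.generate_community(cfg, meta, domain)
    rare = tables.rarefy(counts, int(counts.sum(axis=1).min()), seed=1)
    fit = spatial.distance_decay(diversity.bray_curtis(rare), geo)
    rel = tables.relative_abundance(rare)
    specialists = specocc.classify_specialists(specocc.spec_occ(rel, meta["region"]))
    print(f"{domain:9s} slope={fit.slope:+.4f}/100km  r2={fit.r_squared:.3f} "
          f"p={fit.p_value:.2e}  specialists={len(specialists)}")
```

which prints

```
bacteria  slope=-0.0068/100km  r2=0.444 p=0.00e+00  specialists=12
archaea   slope=-0.0095/100km  r2=0.346 p=4.47e-238  specialists=12
fungi     slope=-0.0028/100km  r2=0.044 p=1.18e-26  specialists=12
```

Community similarity decays with distance in every domain, fastest for
archaea and slowest for fungi — the turnover ordering planted by the
generator — and the 12 planted region specialists per domain (3 per 5°
latitude band) are recovered exactly by the specificity–occupancy rule.

The same analysis runs end-to-end from the command line:

```bash
biogeo run --config run.toml      # full pipeline + checksum manifest
biogeo synth --outdir data --seed 1
biogeo ddr --community bc.tsv --geo geo.tsv --per 100
biogeo specocc --counts otu.tsv --metadata meta.tsv --out specialists.tsv
biogeo network --counts otu.tsv --metadata meta.tsv --outdir nets
biogeo ordination --counts otu.tsv --metadata meta.tsv --outdir ord
```

## Layout

```
src/biogeo/
  synth.py        synthetic transect generator (planted ground truth)
  tables.py       TSV I/O, rarefaction, aggregation, latitude bins
  diversity.py    richness, Shannon, Bray-Curtis, region comparisons
  spatial.py      haversine, distance-decay, Mantel, latitude regressions
  permtests.py    PERMANOVA / ANOSIM / MRPP / NMDS
  ordination.py   VIF pruning, CCA, variation partitioning, taxa-env rho
  specocc.py      specificity-occupancy and specialist classification
  network.py      co-occurrence edges, graph building, topology
  validation.py   null-calibration and planted-structure recovery checks
  pipeline.py     end-to-end orchestration with manifest + substream seeds
  cli.py          click-based command line
```

See `docs/methods.md` for the statistical conventions, generator design
and known limitations.
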