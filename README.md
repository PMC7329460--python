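# semifield

Genomic prediction for semi-field row trials: GBLUP mixed models with
direct and indirect (neighbor) genetic effects and an 11-position
running-sum spatial field, AI-REML variance-component estimation,
line-mean variance partitioning (heritabilities, relative variance
components, genetic CV), and leave-one-line-out genomic prediction with
accuracy and inflation statistics. Includes the grain-trait derivation
(nitrogen content from yield and protein), the minirhizotron root-image
editing/aggregation pipeline, and a synthetic-data generator emulating
the facility (beds built in pairs, wet/dry harvest areas per row,
two-sided neighbors, virtual border rows, camera and depth-interval
effects).

## Layout

| module | contents |
| --- | --- |
| `semifield.kinship` | marker IO/validation, mean imputation, VanRaden (method 1) relationship matrix |
| `semifield.phenotypes` | nitrogen content, root-image editing steps 1–4, depth intervals, TRL/IRL aggregation, descriptive stats |
| `semifield.design` | facility layout, neighbor and running-sum spatial incidences, model presets GM1/GM2/RM1/RM2 |
| `semifield.reml` | dense AI-REML with EM fallback and boundary pinning; BLUEs/BLUPs; AI-based standard errors; dual (V-route and MME-route) implementations |
| `semifield.partition` | line-mean phenotypic variance, RVCs, narrow/broad-sense heritability, genetic CV |
| `semifield.cv` | corrected phenotypes, leave-one-line-out GEBVs, scaled accuracy, inflation regression |
| `semifield.simulate` | marker panels (optionally family-structured), layouts, grain/root trait records under the generative models |
| `semifield.cli` | `semifield` command-line interface and end-to-end orchestration |

## CLI

```bash
semifield simulate config.yaml --outdir sim        # write a synthetic dataset
semifield g-matrix markers.csv G.csv               # VanRaden G
semifield root-edit images.csv --report edit.json  # editing + TRL/IRL
semifield fit --model GM2 --trait GY --markers m.csv --phenotypes p.csv --layout l.csv
semifield partition --model GM1 --trait GY ...     # heritabilities / RVCs
semifield cv --model GM2 --trait GY ...            # leave-one-line-out CV
semifield run run.yaml --outdir out                # end-to-end with manifest
```

A minimal simulation config:

```yaml
seed: 1
n_lines: 84
n_markers: 1000
beds: 4
rows_per_bed: 150
n_families: 12        # 0 = unrelated lines
variances: {g: 0.24, l: 0.2, g_n: 0.03, l_n: 0.05, r: 0.06, s1: 0.01, s2: 0.02, e: 0.3}
```

An end-to-end `run` config holds either `simulation: {...}` (as above) or
`inputs: {markers: ..., phenotypes: ..., layout: ...}`, plus `model`,
`trait` and `cv` options.

## Input conventions

* Marker tables: CSV/TSV, header of marker ids, first column line id;
  PLINK `.raw` additive exports are also accepted.
* Grain phenotypes: one row per (bed, row, harvest area).
* Root images: `bed,tube,camera,depth_m,length_cm,line[,valid]`; editing
  applies, in order: failure removal, the 1.2–2.0 m depth window (eight
  0.2 m intervals by default, overridable), a per-interval mean ± 3 sd
  filter, and restriction to genotyped lines, reporting per-step
  retention counts.
* Spatial model: each record loads on the 11 locations centred on its
  row position; five virtual locations pad each end of a field, the two
  beds of a pair form one contiguous position line, and pairs share
  location levels (configurable via `build_layout`).
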