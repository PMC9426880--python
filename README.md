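# dsurf

Two-stage density surface modelling (DSM) of aerial line-transect surveys,
with a synthetic survey generator that makes every stage verifiable against a
known truth.

**Stage 1** fits multiple-covariate distance-sampling (MCDS) detection
functions (half-normal / hazard-rate keys, log-linear scale covariates,
AIC ranking with a parsimony rule, Cramér–von Mises goodness of fit) and
converts detections into Horvitz–Thompson-corrected abundances per 2.5-km
transect segment.

**Stage 2** compresses segment-level landscape covariates with
correlation-matrix PCA (latent-root retention, 0.40/0.60 loading
interpretation), fits a Tweedie GAM of corrected segment abundance on a
bivariate thin-plate coordinate smooth and PC-score smooths with a log
effort-area offset (REML smoothing, shrinkage penalties, profiled Tweedie
power, all-subsets AIC selection), propagates detection-function uncertainty
into the model covariance, and projects the fitted surface onto a 1-km²
prediction grid: density / SE / CV maps, parkwide totals with log-normal
intervals, threshold-area summaries, and Spearman comparison between two
density surfaces.

## Layout

| module | role |
| --- | --- |
| `dsurf.survey_data` | domain types, CSV dialect, truncation, segmentization, observation→segment assignment |
| `dsurf.detection` | MCDS key functions, conditional MLE, p̂, AIC ranking, C-vM GOF |
| `dsurf.abundance` | Horvitz–Thompson segment/survey abundance, CDS totals, log-normal CIs |
| `dsurf.covariates` | standardization + correlation-matrix PCA, retention and interpretation rules |
| `dsurf.smooths` | low-rank thin-plate regression splines with null-space shrinkage |
| `dsurf.dsm` | Tweedie GAM, REML, all-subsets selection, variance propagation, term tests |
| `dsurf.prediction` | grid prediction, totals, threshold areas, surface rank correlation |
| `dsurf.synthetic` | seeded landscape/population/survey simulator with known truth |
| `dsurf.pipeline` / `dsurf.cli` | end-to-end orchestration and `dsurf` command line |

## CLI

```sh
# generate a synthetic survey (obs.csv, segments.csv, grid.csv, truth.json)
dsurf simulate --scenario paper_like --seed 7 --out sim/

# run the full two-stage pipeline
dsurf run --obs sim/obs.csv --segments sim/segments.csv --grid sim/grid.csv \
          --out run/ --truncation 350 --seed 1

# individual stages
dsurf ingest --obs sim/obs.csv --segments sim/segments.csv --truncation 350
dsurf fit-detection --obs sim/obs.csv --truncation 350 --keys hn,hr \
                    --covars canopy,cloud_cover --all-subsets
dsurf pca --segments sim/segments.csv --out pca.json
dsurf report --cells run/cells.csv --threshold 2 --compare moose_cells.csv
```

`dsurf run` writes per-stage CSV artifacts plus `report.json` with a
provenance block (input hashes, seed, version); identical inputs and
configuration give byte-identical reports.

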