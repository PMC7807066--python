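# emusdm

Ensemble species-distribution modelling (SDM) for presence-only atlas data,
re-implementing the consensus protocol used to hindcast (mid-Holocene) and
forecast (2070) the range of the emu *Dromaius novaehollandiae* — and
exercising every stage on synthetic landscapes where the true niche is known,
so the whole pipeline is testable without any external data download.

**Who it is for:** ecologists and method developers who want a reproducible,
fully scripted version of the standard ensemble-SDM workflow (record
cleaning, bias-aware pseudo-absences, multi-algorithm fitting, skill-gated
TSS-weighted ensembling, dispersal-bounded range change, MESS extrapolation
diagnostics), plus a ground-truthed synthetic testbed to validate it.

## The model

Occurrence records `y` are related to environmental predictors `x` (e.g.
bioclim variables bio1–bio19) through an ensemble of suitability models.
For a candidate model *i* with holdout true skill statistic
`TSS_i = sensitivity + specificity − 1`, the ensemble prediction at a cell is

```
S(x) = Σ_i w_i · p_i(x),   w_i = TSS_i / Σ_j TSS_j,
```

where only models with `TSS ≥ 0.7`, `AUC ≥ 0.9` and `Kappa ≥ 0.7` enter the
sum. `S` is binarized at the threshold that maximises TSS, and range change
between two climates is the cell-count change of the binary range:
`(n_other − n_current)/n_current × 100` under unlimited dispersal, and
`(n_overlap − n_current)/n_current × 100` under no dispersal.

Pseudo-absences (needed because atlas data are presence-only) are drawn with
cell weight `(1 − d/d_max) · b`, where `d` is a kernel density of presence
environments in principal-component space and `b` a sampling-effort bias
layer estimated by point-density analysis of analogue-species sightings —
so "absences" sit in unlike environments but mirror the observers' spatial
bias, at a 1:1 ratio with presences and ≥ 30 km from any other point.

The synthetic testbed generates autocorrelated predictor fields, defines a
true logistic niche `P(presence) = logit⁻¹(β₀ + Σ β_v x_v + Σ γ_v x_v²)`,
observes presences through a nonuniform bias surface, and applies known
affine climate shifts — so recovery of the niche and of range change can be
scored exactly.

## Worked example

The numbered scripts under `analysis/` run the full study on the synthetic
landscape (seed 1 by default):

```bash
python analysis/01_simulate_landscape.py 1
python analysis/02_clean_and_thin.py 1
python analysis/03_pseudoabsences.py 1
python analysis/04_select_predictors.py 1
python analysis/05_fit_gate_project.py 1
python analysis/06_novelty_and_recovery.py 1
```

Output of the fitting/projection step (seed 1):

```
candidates: 54 (9 algorithms x 6 repeats)
holdout TSS: median 0.710, range 0.258-0.935
gates TSS>=0.7 / AUC>=0.9 / Kappa>=0.7 kept 23 members
binarization threshold (max TSS on ensemble): 0.381; Boyce 0.953
range change (past vs current): 17970 -> 8806 cells (overlap 8806); -51.00% with unlimited dispersal, -51.00% with no dispersal
range change (future vs current): 17970 -> 12907 cells (overlap 12728); -28.17% with unlimited dispersal, -29.17% with no dispersal
```

and of the recovery check against the known truth:

```
niche recovery: Spearman rho = 0.931 on 10000 unseen cells
range change (past): true -56.35%, estimated -51.00% (error 5.36 pp)
range change (future): true -31.29%, estimated -28.17% (error 3.11 pp)
```

Reading: of 54 candidate models, 23 cleared the skill gates; their
TSS-weighted ensemble ranks habitat almost identically to the true niche on
cells that contributed no training point (ρ = 0.93), and its
unlimited-dispersal range-change estimates land within a few percentage
points of the true change of the niche's 0.5-level set. The Boyce index
(0.95) says presences concentrate in cells the ensemble rates highly.

The same pipeline runs from a YAML config (or on real CSV/raster inputs)
via the CLI:

```bash
emusdm run config.yaml            # end-to-end
emusdm clean raw.csv clean.csv    # individual stages: clean, thin,
emusdm thin clean.csv thin.csv    # pseudoabs, vif, evaluate,
emusdm rangechange a.asc b.asc    # rangechange, mess, simulate, ...
```

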