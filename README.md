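# cfmeth

Circulating cell-free DNA (cfDNA) methylation diagnostics for
MCTA-Seq-style data: biomarker selection from paired tissue and plasma
MEPM matrices, a positivity-counting panel classifier, a LASSO-logistic
methylation score, consensus-clustering CIMP subtyping, and a
multi-cancer tumor-origin typing rule — together with a ground-truthed
synthetic cohort generator for end-to-end evaluation.

## The problem

MCTA-Seq enriches hypermethylated CpG islands anchored at CGCGCGG motifs
and reports, per sample and per CpG site, the number of fully methylated
molecules normalized to **MEPM** (methylated alleles per million mapped
molecules). Tumors shed hypermethylated DNA into plasma, so a panel of
CpG-island markers that are (i) hypermethylated in tumor tissue,
(ii) close to an amplification anchor, (iii) strongly methylated in
tumors, and (iv) nearly silent in healthy plasma can detect cancer from
a blood draw. This package implements that pipeline for pancreatic
cancer (PAC) screening and its extension to distinguishing PAC from
hepatocellular (HCC), colorectal (CRC) and gastric (GC) cancer.

The analysis chain, module by module:

| module | what it does |
| --- | --- |
| `cfmeth.io` / `cfmeth.types` | MEPM matrices + sample sheets + site catalogs (TSV/BED-like), QC (`total_molecules >= 10,000`), stratified 6:4 cohort splits |
| `cfmeth.simulate` | synthetic tissue/plasma/multi-cancer cohorts with planted markers and known ground truth |
| `cfmeth.diffmeth` | per-site two-tailed Mann–Whitney tests (exact enumeration for n ≤ 12), BH-FDR, pseudocounted fold changes |
| `cfmeth.markers` | the four-criteria marker selection (p < 0.01, motif distance < 60 bp, ≥ 10 MEPM, normal-plasma positivity < 5%) and pairwise cancer-vs-cancer panels |
| `cfmeth.panel` | positive-marker counting, Brier-scored Monte Carlo panel sizing, count cut-off calibration on independent normals, ROC/AUC |
| `cfmeth.score` | LASSO feature selection (10-fold CV, 1-SE rule) + logistic refit; score = Coef₀ + Σᵢ Coefᵢ·Aᵢ, positive iff score > 0 |
| `cfmeth.consensus` | consensus clustering (Ward on log1p MEPM, subsampled), choice of k, CIMP labeling by panel total methylation |
| `cfmeth.multipanel` | multi-panel origin call: non-cancer iff all panels negative, otherwise the panel with the highest exact positive fraction |

## Worked example

Build the packaged synthetic discovery study (30 PAC patients across
stages I–IV, 31 healthy controls, 120 planted markers among 3000 sites),
calibrate the counting classifier on an independent 96-sample normal
set, and fit the methylation score:

```python
import numpy as np
import cfmeth as cf

config = cf.default_config()                    # packaged synthetic study, seed 42
plasma, truth = cf.simulate_plasma_cohort(config)        # 30 patients / 31 controls
normals, _ = cf.simulate_plasma_cohort(
    config, n_cases_by_stage={}, n_controls=96, cohort_label="calibration"
)

panel = cf.MarkerPanel("PAC", tuple(truth.planted_markers["PAC"]))
cutoff = cf.calibrate_count_cutoff(normals, panel, policy="max")
panel = panel.with_cutoff(cutoff)

counts = cf.panel_counts(plasma, panel)
y = np.array([1 if s.is_cancer else 0 for s in plasma.samples])
auc, _ = cf.roc_auc(counts.to_numpy(), y)
print(f"count cut-off > {cutoff}")
print(f"median positive count: controls {counts[y==0].median():.0f}, patients {counts[y==1].median():.0f}")
print(f"specificity {(counts[y==0] <= cutoff).mean():.3f}, sensitivity {(counts[y==1] > cutoff).mean():.3f}, AUC {auc:.3f}")

results = cf.MethylationScoreModel(plasma, candidate_markers=list(panel.marker_ids)).fit(seed=42)
print(f"LASSO kept {len(results.score_model.marker_ids)} markers; "
      f"sign rule correct for {100 * results.accuracy():.1f}% of samples")
```

prints

```
count cut-off > 6
median positive count: controls 0, patients 46
specificity 1.000, sensitivity 1.000, AUC 1.000
LASSO kept 9 markers; sign rule correct for 100.0% of samples
```

A sample is called positive when its positive-marker count strictly
exceeds the cut-off learned from normals alone; the methylation score is
the fitted logistic linear predictor on raw MEPM values, thresholded at
zero. `results.summary()` shows the selected markers and coefficients,
and `cfmeth.plotting.waterfall_plot(results.scores)` draws the ranked
score bars.

The same objects drive the rest of the pipeline: `select_cancer_markers`
reproduces the panel from tissue + plasma instead of ground truth,
`consensus_cluster` + `assign_cimp` find the high-methylation (CIMP)
tumor subgroup, and `type_samples` assigns plasma samples to
PAC/HCC/CRC/GC, non-cancer, or indeterminate.

## Command line

Every step is also a `cfmeth` subcommand operating on the TSV formats:

```bash
cfmeth simulate --seed 42 --out sim/
cfmeth qc --matrix sim/plasma.tsv --out plasma_qc.tsv
cfmeth select --tissue sim/tissue.tsv --plasma plasma_qc.tsv --catalog sim/sites.bed --out panel.tsv
cfmeth calibrate --matrix sim/normals.tsv --panel panel.tsv
cfmeth classify --matrix plasma_qc.tsv --panel panel.tsv --out calls.tsv
cfmeth score train --matrix plasma_qc.tsv --panel panel.tsv --model model.tsv
cfmeth type --matrix plasma_qc.tsv --panels panel.tsv --out typing.tsv
```

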