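# cbbct

Dynamic contrast cone-beam breast CT (CBBCT) analysis for neoadjuvant
chemotherapy (NAC) response prediction: a digital phantom simulator,
fat-normalized kinetic and morphometric lesion features, and the
statistical workflow that relates them to pathologic complete response
(pCR).

## The problem

During NAC, breast tumors of eventual pathologic complete responders
shrink more and enhance less than those of non-responders. Dedicated
breast CT acquires a pre-contrast sweep and post-contrast sweeps at 60,
120 and 180 s, three times over treatment (pre-, mid-, late-NAC). The
analysis question is which quantitative lesion parameters measured on
those exams predict pCR (Miller-Payne grade 5), and how well a
multivariable model of the late-treatment parameters performs.

This package is for methodologists and imaging scientists who need that
measurement-and-inference chain as tested, reusable code. Because no
patient scans are publicly available, a phantom generator produces
synthetic exams whose feature distributions match the published pooled
summaries, so every stage — segmentation, kinetics, morphometry, group
tests, ROC, model selection — can be exercised and validated end to end.

## Model and features

Fat-referenced enhancement at post-contrast phase *t*:

    ΔHU(t) = (HU_lesion(t) − HU_fat(t)) − (HU_lesion(0) − HU_fat(0))

with `base = HU_lesion(0) − HU_fat(0)` the pre-contrast fat-corrected
attenuation. Per exam the package measures:

| feature | definition |
|---|---|
| lesion density | pre-contrast ROI mean, HU |
| one/two/three-minute enhancement | ΔHU at 60/120/180 s, HU |
| maximum enhancement ratio | (base + max ΔHU) / base |
| wash-in rate | 100 · (max ΔHU / base) / T_peak, %/s |
| washout rate | 100 · ((ΔHU_peak − ΔHU_final) / base) / (T_final − T_peak), %/s |
| diameter | max extent on the largest axial cross-section, mm |
| calculated volume | π/6 · d₁d₂d₃, mm³ |
| segmented volume / surface area | threshold segmentation; voxel volume and iso-surface mesh area |
| reductions | 100 · (baseline − current)/baseline vs the pre-NAC exam, % |

Cohort analysis per timepoint: Welch t / Mann-Whitney U (Shapiro-Wilk
gate), chi-square or Fisher for covariates, per-parameter ROC with Youden
cutoffs and DeLong confidence intervals, pairwise DeLong AUC comparisons,
then a univariable screen (p < 0.05) feeding a backward-stepwise logistic
model of pCR. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

Simulate a 40-patient cohort (45% responders), extract features at all
three timepoints, analyze the late exam and fit the response model:

```python
from cbbct import pipeline
from cbbct.phantom import AcquisitionSpec, CohortParams

params = CohortParams(n_patients=40, pcr_prevalence=0.45,
                      diameter=(30, 10), diameter_bounds=(8, 60))
acq = AcquisitionSpec(voxel_size=1.5, grid_shape=(64, 64, 64), noise_sd=5.0)
res = pipeline.run_all(params, acq, seed=7, out_dir="demo")

print(res["analyses"]["late"]["roc"][["auc", "cutoff"]].round(3))
pm = res["model"]
print("retained:", pm.result.retained)
print(f"model AUC={pm.roc.auc:.3f} cutoff={pm.roc.cutoff:.3f} "
      f"sens={pm.roc.sensitivity:.3f} spec={pm.roc.specificity:.3f}")
```

Output (abridged):

```
                             auc    cutoff
one_min_enh                0.970    16.145
diameter_mm                0.843    12.816
seg_volume_mm3             0.882   904.500
washout_rate               0.538     0.000
max_enh_ratio              0.970     1.077
seg_volume_reduction_pct   0.962    79.869
retained: ['seg_surface_reduction_pct']
model AUC=0.962 cutoff=0.250 sens=1.000 spec=0.885
```

Read it as: at the late exam, enhancement parameters (one-minute
enhancement, maximum enhancement ratio, wash-in) and shrinkage parameters
(volumes, reductions) separate responders from non-responders with AUCs
near 0.9-0.97, while the washout rate is uninformative (AUC ≈ 0.5) — the
simulated groups differ in uptake, not washout. With this cohort's strong,
mutually correlated effects the stepwise model keeps a single reduction
parameter; its apparent ROC has AUC 0.962 with the Youden cutoff on the
predicted-probability scale (0.250). `demo/` then contains the cohort
feature table, per-timepoint comparison/ROC/DeLong/covariate tables, the
model JSON, and a run log recording each statistical choice.

The same chain is scriptable from a shell:

```bash
cbbct simulate --n 40 --prevalence 0.45 --seed 7 --out-dir sim/
cbbct extract  --manifest sim/manifest.csv --out features.csv
cbbct analyze  --features features.csv --timepoint late --out-dir out/
cbbct model    --features features.csv --timepoint late --out-dir out/
```

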