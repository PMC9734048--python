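# neuroflex

Dynamic brain-network flexibility analysis for parcellated resting-state
fMRI: sliding-window functional connectivity, multilayer (temporal)
community detection, flexibility statistics, covariate-adjusted group
contrasts, and importance-ranked predictive models — plus a synthetic
cohort generator so the whole chain runs and is tested without any
external data.

## The problem

Executive dysfunction in conditions such as ADHD has been linked to how
*flexibly* the brain reconfigures its functional communities over time.
Given an ROI time series matrix (T timepoints x R regions) per subject, the
pipeline estimates, for every region, the *neural flexibility*

    f_i = n_i / N

where `n_i` is the number of times region i changes its community label
between consecutive time windows and `N = W - 1` is the number of possible
changes.  Communities are found by maximizing multilayer modularity

    Q = (1/2mu) sum_{ijsr} [ (A_ijs - gamma k_is k_js / 2m_s) d_sr
                             + d_ij omega 1(|s-r|=1) ] d(g_is, g_jr)

over all node-layer copies with a generalized Louvain heuristic, repeated
across seeds (metrics are averaged over repetitions).  Layers `A_s` are
windowed Pearson correlation matrices, FDR-thresholded within each window.
Group differences in flexibility are tested with OLS contrasts adjusted
for age, sex, head motion and site; region-wise flexibility feeds XGBoost
classification (patient vs control) and severity-regression models with a
ranked-importance top-N feature search under ten-times ten-fold CV and an
independent-test evaluation.

Audience: researchers working with parcellated resting-state time series
who want a tested, deterministic reference implementation of the
flexibility pipeline, and methodologists who want its statistics and
community detection exercised against oracles.

## Worked example

```python
from neuroflex import (
    SyntheticConfig, generate_cohort, PipelineConfig,
    cohort_flexibility, group_contrast_table,
)

cfg = PipelineConfig(
    synthetic=SyntheticConfig(
        n_tdc=20, n_adhd_unmedicated=20, n_adhd_medicated=0,
        switch_rate_tdc=0.10, switch_rate_adhd_unmedicated=0.04,
        master_seed=7,
    ),
    n_reps=10, detection_seed=1,
)
cohort = generate_cohort(cfg.synthetic)
whole, systems, nodes = cohort_flexibility(cohort, cfg)
res = group_contrast_table(whole, cohort.subjects, contrast="ADHD-TDC")[0]
print(f"TDC  mean flexibility: "
      f"{whole.loc[cohort.subjects.group == 'TDC', 'whole_brain'].mean():.4f}")
print(f"ADHD mean flexibility: "
      f"{whole.loc[cohort.subjects.group == 'ADHD', 'whole_brain'].mean():.4f}")
print(f"ADHD-TDC contrast: beta = {res.beta:.4f}, p = {res.p:.2e}")
```

prints

```
TDC  mean flexibility: 0.0251
ADHD mean flexibility: 0.0140
ADHD-TDC contrast: beta = -0.0093, p = 2.59e-03
```

The cohort plants a lower community-switching rate in the patient group
(0.04 vs 0.10 per window boundary); the pipeline recovers it as a negative,
highly significant whole-brain flexibility contrast after covariate
adjustment.  (Estimated flexibility is smaller than the planted rate
because 30-volume windows smooth over state changes and strong interlayer
coupling favours persistent labels — the comparison between groups, not the
absolute level, is the quantity of interest.)

The same analysis runs from the shell:

```bash
neuroflex run-all --out runs/demo --seed 7 \
    --subjects-per-group 20 20 0 --reps 10
```

writing time series, layer stacks, community assignments, a tidy
flexibility table, contrast tables, model metrics and a manifest with
checksums under `runs/demo/`.

## Caveat on the default feature-selection protocol

The default top-N search ranks features once on the *full* training cohort
and then cross-validates each prefix.  Because the ranking has seen all
training labels, the CV curve is an optimistically biased estimate of
generalization; treat the independent-test metrics as the honest numbers,
or use `top_n_search(..., nested=True)` to re-rank inside every training
fold.
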