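# oscillomark

Neuronal activity is not a passive bystander of diffuse glioma: activity-dependent
secretion of neuroligin-3 (NLGN3) promotes glioma growth, which predicts that
patients with *lower* brain activity should show lower NLGN3 expression in tumor
tissue and *longer* progression-free survival (PFS). `oscillomark` implements the
clinical analysis pipeline that tests this prediction with magnetoencephalography
(MEG): it turns source-space signals into regional broadband oscillatory power,
derives peritumor/global/non-tumor activity scores from tumor-mask dilation and
atlas overlap, links them to immunohistochemically graded NLGN3 expression with
exact rank tests, and quantifies their prognostic value for PFS with Cox
proportional-hazards models validated by leave-one-out and permutation analyses.

It is written for clinical neuroscientists and biostatisticians who want the full
chain — imaging-derived biomarker, ordinal pathology grade, right-censored
survival — reproducible from a single patient table, plus a synthetic-cohort
generator to exercise every stage without any data download.

## The model

For patient *i* with regional broadband power `P_i = (P_i1, …, P_iR)` over `R = 78`
cortical parcels and peritumor region set `S_i` (parcels overlapping the tumor
mask dilated twice with a 3×3×3 box kernel):

- peritumor activity `A_i^peri = mean_{r∈S_i} P_ir`, global `A_i^glob = mean_r P_ir`,
  non-tumor `A_i^non = mean_{r∉S_i} P_ir`, each z-scored across the cohort;
- association with the 3-tier NLGN3 grade via Kruskal–Wallis
  `H = 12/(N(N+1)) Σ n_j (R̄_j − (N+1)/2)²` (tie-corrected) and post-hoc
  Mann–Whitney `U = min(U₁, U₂)` with the exact enumerated null for small
  untied samples;
- prognosis via the Cox model `λ_i(t) = λ₀(t) exp(β z_i)`, maximizing the Breslow
  partial likelihood by Newton–Raphson; `HR = exp(β)` is the hazard ratio per SD
  of activity, with Wald 95% CI and p-value;
- robustness via 24 leave-one-out refits and a 1000-shuffle permutation null of
  the Cox p-value (add-one empirical p).

The packaged table (`oscillomark.fixture_path()`) is a transcription of a
published cohort of 24 newly diagnosed WHO 2007 grade II–IV diffuse glioma
patients with preoperative MEG, resection, NLGN3 immunohistochemistry and
follow-up to progression.

## Worked example

```python
from oscillomark import load_patient_table, analyze_cohort

df = load_patient_table()          # packaged 24-patient cohort
report = analyze_cohort(df, seed=1)
print(report[report["reference"].notna()].to_string(index=False))
```

```
                 metric      value  reference  tolerance passed
               n_events  17.000000     17.000      0.000   True
median_event_time_weeks  87.000000     87.000      0.500   True
            kw_h_global  11.134199     11.130      0.020   True
      u_moderate_vs_low   2.000000      2.000      0.000   True
     u_high_vs_moderate   1.000000      1.000      0.000   True
    p_high_vs_moderate    0.047619      0.048      0.001   True
          cox_hr_global   2.103245      2.100      0.030   True
   cox_hr_global_no_gbm   2.119865      2.120      0.030   True
biv_hr_oba_volume_model   2.288612      2.290      0.030   True
          biv_hr_volume   1.019823      1.020      0.020   True
   biv_hr_oba_age_model   2.330075      2.330      0.030   True
         km_split_n_low  12.000000     12.000      0.000   True
        km_split_n_high  12.000000     12.000      0.000   True
              loo_min_p   0.004159      0.004      0.003   True
              loo_max_p   0.035442      0.036      0.003   True
```

Reading: 17 of 24 patients progressed (median 87 weeks among events). Global
activity z-scores differ across NLGN3 tiers (H(2) = 11.13); the moderate tier
sits almost entirely above the low tier (U = 2), and the exact test still
resolves the 3-vs-6 comparison (U = 1, p = 2·2/84 ≈ 0.048). One SD of global
activity roughly doubles the progression hazard (HR 2.10, 95% CI 1.22–3.64),
robust to excluding the two glioblastomas (HR 2.12), to adjustment for tumor
volume (HR 2.29) or age (HR 2.33), to any single patient (all 24 leave-one-out
p < 0.05), and to the cohort-specific permutation null (empirical p ≈ 0.01).

The same pipeline runs from the shell:

```
oscillomark report                       # scorecard above
oscillomark survive patients.csv --km-split median
oscillomark associate patients.csv
oscillomark validate patients.csv --perm 1000 --seed 7
oscillomark simulate --n-patients 50 --seed 3 --out sim/
```

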