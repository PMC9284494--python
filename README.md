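# chronomics

Individual-focused analysis of longitudinal multiomics profiles: each
subject's omics time series (transcripts, cytokines, clinical labs, gut and
nasal microbes) are classified into temporal classes by spectral methods,
co-behaving signals are grouped, and subjects are connected into a
similarity network whose communities are compared on clinical phenotypes.
The package is aimed at profiling studies in which a few dozen participants
are followed over months to years at irregularly scheduled visits, so that
classical evenly-sampled time-series tools do not apply.

## Method

For subject *s* and omic *i*, the observed series `X_is(t_j)` is referenced
to its first observed visit, `X̃_is = X_is − X_is(0)`, and scaled to unit
Euclidean norm, `Q_is = X̃_is / ‖X̃_is‖₂`. A Lomb–Scargle periodogram
`P_is` is evaluated at the harmonics `f_k = k/(N·δ)` of the series' time
frame (N stamps, nominal spacing δ), which handles missed visits and uneven
sampling natively. The inverse cosine transform of the powers gives
lag-domain autocorrelations `ρ_isk`.

Significance is calibrated per subject by a bootstrap: series are drawn
from the subject's own data and their observed values resampled with
replacement onto their time stamps (destroying temporal order, preserving
the marginal distribution). The 0.95 quantiles of the null autocorrelations
give per-lag cutoffs `ρ_ck`; the 0.95/0.05 quantiles of the null extremes
of `Q` give per-length spike cutoffs. Each signal is then assigned the
smallest lag *l* with `ρ_isl ≥ ρ_cl` (class *Lag l*); failing that,
*SpikeMax* / *SpikeMin* if one visit exceeds the extreme cutoffs; otherwise
*NoTrend*. Empirical p-values are the null exceedance probabilities of the
(selection-corrected) class statistics, with Benjamini–Hochberg control at
FDR 0.05 across each subject's signals per class. Signals of one class are
grouped by two-tier agglomerative clustering (complete linkage): first on
autocorrelation vectors, then on `Q` within groups (which separates sign
flips that autocorrelations cannot see), with cluster counts chosen by
silhouette.

Across subjects, periodograms are computed on the cohort's common time
frame and, for every omic *i* shared by subjects *p, q*, the Spearman
correlation matrix `S_i` is thresholded at `s_c` (the 0.99 quantile of a
bootstrap null of 50,000 resampled series):

    [R_i]_pq = 1 if [S_i]_pq > s_c else 0,     A = Σ_i R_i

so the subject network's edge weights count the omics on which two
subjects behave similarly. Communities are found by k-means on a
one-dimensional spectral embedding of `A`, with k chosen by silhouette
(inertia reported as an elbow diagnostic), and phenotype measures (BMI,
SSPG, Matsuda, DI, isrMax) are compared between communities with two-sided
Mann–Whitney U tests, stratified by sex.

A synthetic-cohort generator produces data with this exact statistical
structure — scheduled visits with skips, five modalities dominated by
transcripts, missing values, planted lag responders and spikes, planted
communities sharing temporal templates, and planted phenotype shifts —
together with the full ground truth, so every stage is testable without any
external download.

## Worked example

```python
from chronomics import (SyntheticConfig, generate_cohort, run_pipeline,
                        PipelineConfig)

cfg = SyntheticConfig(n_subjects=8,
                      n_omics_per_modality={"transcript": 90, "cytokine": 10},
                      visits_per_subject=(10, 16),
                      frac_lag_responders={1: 0.1}, frac_spike_max=0.05,
                      n_communities=2, n_shared_omics=20, seed=23)
ds, meta, truth = generate_cohort(cfg)
res = run_pipeline(ds, meta, PipelineConfig(min_omics=90,
                                            bootstrap_classification=10_000,
                                            bootstrap_network=10_000, seed=0))

subject = res.dataset.subjects[0]
print(res.classifications[subject]["class"].value_counts().to_dict())
print("s_c =", round(res.s_c, 3), "k =", res.communities.k)
```

prints

```
{'NoTrend': 63, 'Lag1': 17, 'SpikeMax': 6, 'Lag3': 4, 'Lag2': 4,
 'Lag5': 2, 'SpikeMin': 2, 'Lag4': 2}
s_c = 0.721 k = 2
```

Subject `S000` carries 100 series; 17 are called *Lag 1* (the generator
planted 10% lag-1 responders plus 20 community-template omics, which are
themselves slowly varying), 8 are spike calls, and the rest show no
temporal trend at the 0.95 bootstrap cutoffs. The detected communities
(k = 2, sizes 4 + 4) match the planted ones exactly for all 8 subjects.
With only four subjects per side, the planted BMI shift is not significant
in this toy run (Mann–Whitney U = 3, p = 0.2) — phenotype comparisons need
the larger cohorts used in the verification studies below.

The same stages are available from the shell:

```
chronomics synth --config cfg.yaml --seed 4 --out cohort/
chronomics preprocess --in cohort/data.tsv --min-omics 90 --out filtered.tsv
chronomics classify --in filtered.tsv --bootstrap 100000 --seed 1 --out classes.tsv
chronomics pipeline --data cohort/data.tsv --meta cohort/metadata.tsv \
    --min-omics 90 --out results/
```

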