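# tpenet

Noninvasive brain-network markers for separating **temporal-plus epilepsy
(TPE)** — seizure onset in the temporal lobe *plus* adjacent structures,
typically the insula — from classical **temporal lobe epilepsy (TLE)**.
Distinguishing the two before surgery matters: standard anterior temporal
lobectomy fails far more often when the epileptogenic zone extends beyond
the temporal lobe, and the gold-standard answer (stereo-EEG) is invasive.

The package implements the full analysis chain on two noninvasive
modalities:

* **Individual FDG-PET metabolic networks.** From a normal-control cohort's
  regional uptake we take means μ, SDs σ and the Pearson matrix R over a
  56-region hemisphere. A subject with uptake x gets z-scores
  e_i = (x_i − μ_i)/σ_i and the network **W_ij = exp(−|e_i − e_j|) · R_ij**:
  concordant deviation preserves the normal edge, discordant deviation
  attenuates it. W is thresholded at sparsities 0.20–0.65 and summarized by
  small-worldness (σ, γ, λ vs degree-preserving random graphs), global/local
  efficiency, and insular degree (Dc) and clustering (Ncf).
* **Scalp-EEG recurrence quantification analysis (RQA).** Time-delay
  embedding (delay from the first AMI minimum, dimension from the
  false-nearest-neighbor test), recurrence plots at a fixed 5% recurrence
  rate outside a Theiler band, and 13 recurrence measures (RR, DET, L,
  Lmax, ENTR, LAM, TT, Vmax, RTmax, T2, RTE, Clust, Trans), averaged over
  1000 random 10-s windows per channel.
* **Cohort machinery.** 1:1 propensity matching (logistic scores, greedy
  nearest neighbor, caliper 0.1), a Lilliefors-gated Wilcoxon/paired-t
  comparison per feature, and a five-classifier bench (XGBoost, logistic
  regression, SVM, random forest, naive Bayes) under stratified 10-fold CV
  with DeLong AUC comparisons and SHAP interpretation.

Patient data of this kind are not publicly depositable, so
`tpenet.synthetic` generates cohorts with controllable group effects —
focal hypometabolism shared by both groups, insular connectivity
attenuation that is stronger in TPE, EEG with a group-graded deterministic
component, and covariate imbalance for the matcher. See `docs/methods.md`
for the model and every numerical convention.

## Worked example

```python
from tpenet.synthetic import gen_nc_uptake, gen_patient_cohort, gen_eeg_recording
from tpenet.metabolic import build_nc_reference, build_individual_network
from tpenet.graphs import graph_feature_profile
from tpenet.rqa import rqa_protocol

ref = build_nc_reference(gen_nc_uptake(52, seed=1))
cohort = gen_patient_cohort(25, seed=2)            # 25 TLE + 25 TPE

sid = cohort.uptake.subject_ids[30]                # a TPE patient
net = build_individual_network(cohort.uptake.values[30], ref, subject_id=sid)
feats = graph_feature_profile(net, n_rand=10, seed=3)
print(f"{sid}: sigma={feats.sigma:.3f} gamma={feats.gamma:.3f} lambda={feats.lambda_:.3f}")
print(f"   insular degree (aIns/pIns): {feats.dc_ains:.1f} / {feats.dc_pins:.1f}")

rec = gen_eeg_recording(0.45, n_channels=2, duration=40.0, fs=128.0, seed=4)
rqa = rqa_protocol(rec, n_iter=20, seed=5, embed_mode="per_channel")
print(f"   RQA: RR={rqa['RR']:.3f} DET={rqa['DET']:.3f} LAM={rqa['LAM']:.3f} T2={rqa['T2']:.1f}")
```

prints

```
TPE005: sigma=1.348 gamma=1.457 lambda=1.069
   insular degree (aIns/pIns): 19.7 / 14.9
   RQA: RR=0.050 DET=0.793 LAM=0.559 T2=26.8
```

Read: this patient's metabolic network is small-world (σ > 1: clustered
like a lattice, short paths like a random graph), with the insular degrees
aggregated across the sparsity grid; the EEG recurrence plot at the fixed
5% recurrence rate is moderately deterministic (79% of recurrence points on
diagonal lines) with a mean recurrence time of ~27 samples.

The whole study — cohort, matching, 50 × 22 feature matrix, paired
statistics, classifier bench — is one call:

```python
from tpenet.pipeline import StudyConfig, run_study
res = run_study(StudyConfig.desk_scale(), seed=0)
print(res.features.shape, res.reports["xgboost"].metrics())
```

A thin CLI mirrors the stages: `tpenet simulate`, `tpenet network`,
`tpenet graph`, `tpenet rqa`, `tpenet match`, `tpenet compare`,
`tpenet classify` (see `--help` on each).

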