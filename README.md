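# viscereb

Directed (effective) connectivity of a four-region "visual–cerebellum"
network from resting-state BOLD, for researchers studying how chronic
spinal-cord compression (degenerative cervical myelopathy) reshapes
visual–motor circuits.  The package implements the full analysis chain as
a tested, reusable library — synthetic-cohort generation, temporal
preprocessing, Bayesian estimation of directed couplings, group-level
empirical Bayes with model reduction, clinical correlation, and
support-vector prediction of motor function with permutation-based
family-wise-error control — so every stage can be validated on data with
known ground truth.

## The model

Four regions — primary visual cortex (PV), left/right secondary visual
cortex (SV_L, SV_R), cerebellum (C) — carry latent neural states x(t)
obeying a linear stochastic system

    dx/dt = A x + w(t)

where A is the 4×4 effective-connectivity matrix: A[i, j] (1/s) is the
directed influence of region j on region i, and self-connections are
parameterized as a_ii = −0.5·exp(θ_i) < 0.  BOLD observations are the
hemodynamic (double-gamma) convolution of x sampled at TR = 2 s plus
noise.  Subject-level inversion yields a Gaussian posterior over the 16
vectorized couplings (exact Kalman likelihood, Laplace approximation);
a hierarchical model θ_s ~ N(β, D) pools subjects, and closed-form
Bayesian model reduction prunes couplings whose removal improves the
group evidence, with a coupling called significant when its posterior
probability Pp = 1/(1+exp(−ΔF)) exceeds 0.95.  Motor function (JOA score)
is predicted from the 16 couplings by linear ε-SVR with within-fold
feature selection over 20 retained fractions; significance uses the
maximal-|r| permutation null, so the p-values are FWE-corrected by
construction.

## Worked example

```python
from viscereb import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(master_seed=1, mvpa_n_perm=1000))

pat = bundle.group_graphs["patient"]
con = bundle.group_graphs["control"]
print(sum(pat["significant"].values()), "patient couplings significant")
print([k for k, kept in con["retained"].items() if not kept])
print(bundle.clinical_correlations["C->SV_L~recovery_os"]["r"])
print(bundle.mvpa_summary["best_r"], bundle.mvpa_summary["min_p_fwe"])
```

On the default synthetic cohort (27 patients, 11 controls, 180 volumes)
this prints, with seed 1:

```
8 patient couplings significant
['SV_L->PV', 'SV_R->PV', 'C->PV', 'SV_R->SV_L', 'C->SV_L', 'SV_L->SV_R', 'C->SV_R', 'PV->C', 'SV_L->C', 'SV_R->C']
0.4870065372949391
0.4142908823283416 0.3996003996003996
```

Reading: in the patient group the strong couplings (the feedforward
visual pathways, the elevated cerebellum↔SV_L connections and the four
self-connections) pass the Pp > 0.95 rule, while the control group's
reduced model prunes all four cerebellum↔secondary-visual connections —
the planted group structure, in which those pathways exist only in
patients — along with the weak feedback couplings that n = 11 subjects
cannot support.  The correlation between the estimated C→SV_L coupling
and left-eye acuity recovery (r = 0.49, n = 27) reflects the planted
clinical link attenuated by subject-level estimation noise.  The SVR
prediction of the motor score reaches r = 0.41 at its best feature
fraction but is not significant after family-wise-error correction
(p_FWE = 0.40) — at n = 27 the maximal-statistic null is wide, a property
of the procedure quantified in `docs/methods.md`.

The same stages are available as a command-line tool
(`viscereb simulate | preprocess | invert | group | correlate | mvpa |
report`), each writing plain NIfTI/TSV/CSV/JSON artifacts.

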