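# megconn

Band-limited MEG source connectivity and network statistics for two-group
resting-state designs.

`megconn` implements, as a tested reusable library, the analysis chain used
to ask whether a genetic (or any other two-group) factor alters resting-state
brain functional connectivity:

1. **Preprocessing** — high-order linear-phase FIR band-pass filtering
   (theta 4–8, alpha 8–12, beta 12–30, gamma 30–45 Hz; order-1500 Hamming
   design, two-pass for zero net phase shift), consecutive 4-s epoching,
   amplitude-threshold artifact rejection and random trial-count
   equalization (20 trials per subject).
2. **Source reconstruction** — scalar LCMV beamformer
   `w_s = (l_s' C_r⁻¹ l_s)⁻¹ l_s' C_r⁻¹` with trace-scaled diagonal loading
   `C_r = C + 0.15·(tr C / n)·I`, per-sensor-type leadfield normalization,
   and first-principal-component ROI representative time series on a
   72-parcel cortical atlas model.
3. **Connectivity** — phase-locking value per ROI pair,
   `PLV = |T⁻¹ Σ_t exp(i(φ_i(t) − φ_j(t)))|`, phases from the analytic
   signal, computed per trial and averaged.
4. **Network-based statistics (NBS)** — per-link ANCOVA
   (`FC ~ group + age`, drop-one F with p < 0.005), direction-consistent
   connected components of at least 10% of the ROIs (7 of 72), component
   statistic = ΣF, and family-wise error control via the maximal statistic
   over group-label permutations (5000 in a production run).
5. **Downstream biomarkers** — per-subject subnetwork strength (mean PLV
   over the subnetwork's links), age-adjusted strength ANCOVA, Spearman
   correlations with cognitive scores, and single-feature leave-one-out
   logistic classification with full confusion-matrix reporting
   (accuracy, sensitivity, specificity, PPV, NPV, Clopper–Pearson CI).

Because raw MEG from such studies is rarely shareable, the package includes
a first-class **synthetic cohort generator**: coupled narrowband phase
oscillators with a planted antero-posterior subnetwork whose coupling is
weaker in the test group, linear sensor mixing, an age covariate, and
cognitive scores tied to the planted subnetwork's synchrony. Every stage of
the chain is validated end to end against this generator.

## Worked example

```python
from megconn import (SimulationConfig, cohort_plv_stack, generate_metadata,
                     nbs_permutation)

config = SimulationConfig(sampling_rate=250.0, seed=11)   # 36 subjects, 72 ROIs
fc = cohort_plv_stack(config)           # (36, 72, 72) PLV matrices
table = generate_metadata(config)       # group, age, cognitive scores
result = nbs_permutation(fc, table, p_threshold=0.005, n_perm=500, seed=99)
for sub in result.subnetworks:
    print(sub.n_nodes, len(sub.links), round(sub.network_stat), sub.p_fwer)
```

prints

```
8 12 3515 0.0
```

— one subnetwork of 8 nodes and 12 links with diminished connectivity in
the test group, network statistic 3515, and a permutation FWER p-value
below 1/500: the planted occipito-frontal motif, recovered exactly (its
per-subject strength averages 0.150 in the reference group vs 0.123 in the
test group, the planted operating point). The scripts in `examples/`
walk through each capability: cohort simulation, single-subject
preprocessing to PLV, NBS detection, biomarker evaluation, and the
file-based end-to-end pipeline with its reproducibility manifest.

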