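# laggedsense

Lagged repeated-measures correlation between changes in smartphone-sensed
behaviour and subsequent changes in depression, anxiety, and social-anxiety
severity.

Digital-phenotyping studies collect passive smartphone streams — GPS fixes,
call/SMS logs, foreground-app samples, participant-labelled semantic
locations — alongside scheduled symptom questionnaires (PHQ-8, GAD-7,
SPIN). A recurring question is *temporal precedence*: does a change in
sensed behaviour precede a change in symptoms, or the other way round?
`laggedsense` implements the full analysis chain for that question, for
researchers in psychiatry and mobile sensing who want a tested, reusable
pipeline rather than one-off analysis scripts:

1. **Sensor features.** Per 2-week window: the seven classic GPS mobility
   features (location variance, number of location clusters, location
   entropy H = −Σ pᵢ ln pᵢ and its normalised form H/ln k, circadian
   movement from Lomb–Scargle energy in the 23.5–24.5 h period band, total
   distance, average velocity), daily semantic-location durations with
   label propagation from assessment weeks, daily call/SMS aggregates, and
   daily app-category durations.
2. **Feature groups.** Every base feature is z-scored across the full
   sample and averaged with unit weights into 14 interpretable groups
   (*Locations*, *Time*, *Transitions*, six semantic-location durations,
   *Calls*, *Text Messages*, and three app categories).
3. **Symptom profiles.** k-means on the 32 baseline questionnaire items
   (8 + 7 + 17), with elbow-based selection of k.
4. **Lagged inference.** For consecutive check-ins 1 and 2, the
   sensor→symptom direction correlates Sn₂ − Sn₁ (windows *preceding* each
   check-in) with Sx₂ − Sx₁; the symptom→sensor direction correlates
   Sx₂ − Sx₁ with Sn′₂ − Sn′₁ (windows *proceeding* each check-in). The
   correlation is the repeated-measures correlation

   r_rm = sign(b) · √( SSₓ / (SSₓ + SS_resid) ),

   the common within-participant slope from an ANCOVA with
   participant-specific intercepts, with df = N_obs − n − 1 and
   Benjamini–Hochberg FDR correction within each measure × cluster ×
   direction family. Single missing assessments in a pair are
   within-person mean-filled; pairs lacking a sensor window are dropped
   from that direction.

Because raw cohorts of this kind are rarely shareable, the package ships a
first-class synthetic cohort generator (`synthetic_cohort`) whose latent
behavioural-activation state drives all sensor streams and whose coupling
between behaviour change and subsequent symptom change is a calibrated,
injectable parameter — so the whole pipeline can be validated by parameter
recovery.

## Worked example

Generate a 200-participant synthetic cohort with a forward coupling of
ρ = −0.3 between the *Locations* feature group and subsequent depression
change, then run the lagged analysis:

```python
import laggedsense as ls

cfg = ls.SimConfig(n_participants=200, coupling_rho=-0.3, seed=1)
bundle, windows = ls.generate_feature_cohort(cfg)
z, _ = ls.standardize_features(windows)
groups = ls.aggregate_groups(z)
table = ls.run_lagged_analysis(bundle.assessments, groups, measures=("PHQ8",))
print(table[table.group == "Locations"][
    ["measure", "group", "direction", "n", "dof_inference",
     "r_rm", "p_raw", "p_bh"]].to_string(index=False))
print(ls.power_sample_size(0.2, 0.05, 0.90))
```

prints

```
measure     group       direction   n  dof_inference      r_rm        p_raw         p_bh
   PHQ8 Locations sensor->symptom 200            799 -0.295520 1.316600e-17 1.843240e-16
   PHQ8 Locations symptom->sensor 200            799  0.034529 3.290678e-01 5.758687e-01
255
```

The injected forward coupling is recovered (−0.296 for a target of −0.3)
and survives FDR correction, while the reverse direction — symptom change
predicting subsequent behaviour change — is correctly null: the pipeline
distinguishes temporal precedence. The final line is the sample size
needed to detect |ρ| = 0.2 at α = .05 with power .90 (n = 255, from
n = ((z₁₋α/₂ + z_power)/atanh ρ)²).

A full event-stream cohort (raw GPS/comm/app CSVs per participant) comes
from `generate_cohort` or the CLI:

```bash
laggedsense simulate --config sim.yaml --out cohort/ --seed 7
laggedsense validate cohort/
laggedsense analyze cohort/ --out results.csv
```

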