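# elmh

Four-quadrant classification of workplace mental health from a 44-item
questionnaire, for psychometricians and occupational-health researchers
who want not just a severity score but a *confidence-aware* class.

Most screening tools stratify respondents by a summation score alone.
This package implements a pipeline that adds a person-fit dimension: a
continuous-response Rasch model places each respondent at a severity
measure θ (logits) and scores how well their response *pattern* fits
the model with the outfit mean square,

    outfit = (1/L) · Σ_j (O_j − E_j)² / W_j,

where `E_j = m + (M−m)·σ(θ−δ_j)` is the model-expected response on item
j and `W_j = (M−m)²·p_j(1−p_j)` its model variance.  Cutting the plane
at 0 logits and outfit 2.0 yields four classes:

| quadrant | meaning       | confidence |
|----------|---------------|------------|
| II       | mental illness | high      |
| III      | healthy        | high      |
| I        | "false MI" — misfitting pattern | low |
| IV       | "false health" — misfitting pattern | low |

Around this core the package provides: a synthetic-cohort generator
with known severities, difficulties and labeled aberrant (careless)
responders; exploratory factor scoring for the instrument's 8 domains
(eigenvalue ≥ 1 retention, varimax principal components, Bartlett
scores, and the published sum→score regression shortcuts); a
108-parameter micro-CNN (per-class 3×3 filter + sigmoid + 2×2 max pool
+ fully connected output, 4×(10+17) parameters) trained to reproduce
the quadrant labels from raw responses; a linear-discriminant baseline;
and a survey sample-size utility.  Estimators follow scikit-learn
conventions (`fit`/`transform`/`predict`, fitted attributes with a
trailing underscore).

## Worked example

```python
from elmh import (SimulationConfig, simulate_cohort, fit_model_bundle,
                  label_cohort, assess_respondent)

cohort = simulate_cohort(SimulationConfig(seed=11))   # 352 x 44 Likert
bundle = fit_model_bundle(cohort.to_numpy())          # EFA + Rasch fit
fit, labels, counts = label_cohort(cohort.to_numpy())
print(counts)

report = assess_respondent(cohort.to_numpy()[0], bundle,
                           person_id="p001")
print(report.measure, report.outfit, report.quadrant, report.confidence)
```

prints

```
{'I': 16, 'II': 76, 'III': 250, 'IV': 10}
-0.26340332044717896 0.5847419060576188 III high
```

The cohort splits into the four classes, dominated by quadrant III
(healthy) with small misfit classes I/IV — the structure a real survey
of this kind shows.  Respondent `p001` sits slightly below 0 logits
with outfit well under 2.0: a high-confidence "healthy" result.
Training the micro-CNN on these labels
(`from elmh import MicroCNN; MicroCNN(seed=0).fit(X, y).score(X, y)`)
reaches ≈ 0.94 apparent accuracy with exactly 108 parameters.

The same pipeline is available from the shell:

```sh
elmh simulate --seed 11 --out cohort.csv
elmh fit --responses cohort.csv --out model.json
elmh classify --model model.json --responses cohort.csv --out labels.csv
elmh train-cnn --model model.json --responses cohort.csv --labels labels.csv
elmh assess --model model.json --answers answers.csv --out report.json
elmh samplesize --population 1521        # -> 307
```

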