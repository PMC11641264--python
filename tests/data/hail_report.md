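# Disease risk report

## Prevalence

| Disease status | No. | % | 95% CI |
|---|---|---|---|
| Disease | 200 | 2.1% | 1.8–2.4% |
| No disease | 9207 | 97.9% | |
| Total | 9407 | 100.0% | |

## Case distribution by determinant

### Age

| Level | No. | % | 95% CI |
|---|---|---|---|
| 40–49 years | 51 | 25.50% | 19.5–31.5% |
| 50–59 years | 69 | 34.50% | 27.9–41.1% |
| 60–69 years | 55 | 27.50% | 21.3–33.7% |
| 70–79 years | 17 | 8.50% | 4.6–12.4% |
| ≥80 years | 8 | 4.00% | 1.3–6.7% |

### Gender

| Level | No. | % | 95% CI |
|---|---|---|---|
| Male | 105 | 52.50% | 45.6–59.4% |
| Female | 95 | 47.50% | 40.6–54.4% |

### Education

| Level | No. | % | 95% CI |
|---|---|---|---|
| Illiterate | 5 | 2.50% | 0.3–4.7% |
| Literate | 195 | 97.50% | 95.3–99.7% |

### Comorbidity

| Level | No. | % | 95% CI |
|---|---|---|---|
| Diabetes Mellitus | 93 | 46.50% | 39.6–53.4% |
| Hypertension | 41 | 20.50% | 14.9–26.1% |
| Asthma | 4 | 2.00% | 0.1–3.9% |
| CVD | 2 | 1.00% | 0.0–2.4% |
| Cataract | 22 | 11.00% | 6.7–15.3% |

## Posterior risk by determinant (Bayes)

Prior P(D) = 0.0559966 (calibrated)

| Factor | Level | No. | % of cases | % of population | Chance of disease (%) | Feasible |
|---|---|---|---|---|---|---|
| age | 40–49 years | 51 | 25.5% | 16.95% | 8.42 | yes |
| age | 50–59 years | 69 | 34.5% | 8.48% | 22.78 | yes |
| age | 60–69 years | 55 | 27.5% | 3.55% | 43.38 | yes |
| age | 70–79 years | 17 | 8.5% | 1.34% | 35.52 | yes |
| age | ≥80 years | 8 | 4% | 0.6% | 37.33 | yes |
| gender | Male | 105 | 52.5% | 57.78% | 5.09 | yes |
| gender | Female | 95 | 47.5% | 42.22% | 6.3 | yes |
| education | Illiterate | 5 | 2.5% | 0.62% | 22.58 | yes |
| education | Literate | 195 | 97.5% | 99.38% | 5.49 | yes |
| comorbidity | Diabetes Mellitus | 93 | 46.5% | 16.17% | 16.1 | yes |
| comorbidity | Hypertension | 41 | 20.5% | 25% | 4.59 | yes |
| comorbidity | Asthma | 4 | 2% | 4.05% | 2.77 | yes |
| comorbidity | CVD | 2 | 1% | 5.5% | 1.02 | yes |
| comorbidity | Cataract | 22 | 11% | 4% | 15.4 | yes |

## Top 7 determinant levels

| Level | Chance of disease (%) |
|---|---|
| 60–69 years | 43.38 |
| ≥80 years | 37.33 |
| 70–79 years | 35.52 |
| 50–59 years | 22.78 |
| Illiterate | 22.58 |
| Diabetes Mellitus | 16.1 |
| Cataract | 15.4 |

## Diagnostics

- factor 'age' covers only 30.92% of the reference population; posteriors cannot marginalize back to the prior

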