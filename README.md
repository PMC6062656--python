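# cews — centile-based early warning scores

Toolkit for building and evaluating band-based early-warning scores (EWS)
for hospital vital signs, centred on the *centile-based* approach: instead of
supervised threshold tuning, sub-score thresholds are read off the
kernel-smoothed cumulative distribution of each vital sign (10th/5th/1st and
90th/95th/99th centiles for sub-scores 1/2/3; one-sided 20th/10th/2nd for
SpO₂; 10th/1st and 90th/99th at 0.1 °C for temperature).

What's included:

- **`cews.model`** — band-table scoring engine (`sub_score`,
  `aggregate_score`, vectorised frame scoring). Bands store printed inclusive
  endpoints at the charting resolution; internally they partition the real
  line half-open, so non-integer monitor values score deterministically.
- **`cews.derivation`** — kernel-smoothed CDF (Gaussian kernels, bandwidth
  `h = 1.06·σ̂·n^(−1/5)`), centile inversion, rounding, and band-table
  assembly (`derive_band_table`, `derive_ews`).
- **`cews.preprocessing`** — admission inclusion rules (adult, ≥1 complete
  observation set, non-palliative, not discharged alive before midnight on
  the admission day), implausibility/missingness validation, score-neutral
  mean imputation.
- **`cews.outcomes`** — composite-outcome labelling (cardiac arrest /
  unanticipated ICU admission / death) within a horizon `T`, first-event
  censoring, window `(t_obs, t_obs + T]`.
- **`cews.evaluation`** — mid-rank AUC (= Mann–Whitney concordance), DeLong
  confidence intervals, step-wise average precision with stratified
  bootstrap CIs, and the per-variable threshold-substitution analysis.
- **`cews.cohort`** — seeded synthetic cohort generator (parametric
  marginals with exact quantile functions, latent severity driving both
  vital-sign derangement and event hazard) so every stage is testable
  without hospital data.
- Shipped scoring systems (`cews.io.builtin_definition`): `ccews`
  (continuous-data centile EWS), `mcews` / `mcews_o2` (manually-charted
  centile EWS without/with the +2 supplemental-oxygen increment), and
  `news` (UK National Early Warning Score) as a comparator.

## CLI

All stages are file-composable subcommands of `cews`:

```sh
cews simulate   --out run/ --seed 1 --n-admissions 2000
cews preprocess --observations run/observations.csv --admissions run/admissions.csv \
                --out run/cleaned.csv --report run/report.json
cews derive     --observations run/cleaned.csv --oxygen-increment 2 \
                --out run/derived_ews.yaml
cews score      --observations run/cleaned.csv --ews mcews_o2 --out run/scored.csv
cews label      --observations run/cleaned.csv --events run/events.csv \
                -T 12 -T 24 -T 48 --out run/labeled.csv
cews evaluate   --labeled run/labeled.csv --ews mcews_o2 --ews news \
                --out run/metrics.json
cews substitute --labeled run/labeled.csv --base ccews --donor mcews \
                --out run/substitution.json
```

or run everything at once on a synthetic cohort:

```sh
cews pipeline --out run/ --seed 1 --n-admissions 2000
```

File formats: CSV for observations/admissions/events (documented headers,
empty cell = missing, ISO-8601 timestamps), YAML for scoring systems and
centile specs, JSON for metrics and reports.

## Conventions worth knowing

- Rounding of inverted centiles is round-half-away-from-zero; σ̂ uses the
  n−1 denominator. Both are documented, switchable choices.
- The published manual respiratory-rate row prints overlapping 8–11 / 11–12
  cells; under the half-open centile convention the score-2 band is 8–10 and
  RR = 11 scores 1.
- AVPU maps A→0 and V/P/U→3 in all shipped systems; diastolic blood
  pressure is recorded but never scored.
- Labelling window is half-open: an event exactly at `t_obs` excludes the
  observation, an event exactly at `t_obs + T` counts as positive.
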