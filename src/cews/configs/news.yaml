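# UK National Early Warning Score (Royal College of Physicians, 2012),
# transcribed as a band-table config.  Includes the +2 oxygen increment.
name: news
provenance: UK National Early Warning Score (RCP 2012) transcription
oxygen_increment: 2
avpu_map: {A: 0, V: 3, P: 3, U: 3}
variables:
  heart_rate:
    resolution: 1
    bands:
    - {score: 3, upper: 40}
    - {score: 1, lower: 41, upper: 50}
    - {score: 0, lower: 51, upper: 90}
    - {score: 1, lower: 91, upper: 110}
    - {score: 2, lower: 111, upper: 130}
    - {score: 3, lower: 131}
  respiratory_rate:
    resolution: 1
    bands:
    - {score: 3, upper: 8}
    - {score: 1, lower: 9, upper: 11}
    - {score: 0, lower: 12, upper: 20}
    - {score: 2, lower: 21, upper: 24}
    - {score: 3, lower: 25}
  temperature:
    resolution: 0.1
    bands:
    - {score: 3, upper: 35.0}
    - {score: 1, lower: 35.1, upper: 36.0}
    - {score: 0, lower: 36.1, upper: 38.0}
    - {score: 1, lower: 38.1, upper: 39.0}
    - {score: 2, lower: 39.1}
  systolic_bp:
    resolution: 1
    bands:
    - {score: 3, upper: 90}
    - {score: 2, lower: 91, upper: 100}
    - {score: 1, lower: 101, upper: 110}
    - {score: 0, lower: 111, upper: 219}
    - {score: 3, lower: 220}
  spo2:
    resolution: 1
    admissible: {min: 0, max: 100}
    bands:
    - {score: 3, upper: 91}
    - {score: 2, lower: 92, upper: 93}
    - {score: 1, lower: 94, upper: 95}
    - {score: 0, lower: 96}
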