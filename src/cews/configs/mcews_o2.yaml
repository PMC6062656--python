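# Manual centile-based EWS with the additional score of 2 when the patient
# is on any supplemental oxygen support.  Band tables identical to mcews.yaml.
name: mcews_o2
provenance: manual centile-based EWS with supplemental-oxygen increment
oxygen_increment: 2
avpu_map: {A: 0, V: 3, P: 3, U: 3}
variables:
  heart_rate:
    resolution: 1
    bands:
    - {score: 3, upper: 42}
    - {score: 2, lower: 43, upper: 49}
    - {score: 1, lower: 50, upper: 53}
    - {score: 0, lower: 54, upper: 104}
    - {score: 1, lower: 105, upper: 112}
    - {score: 2, lower: 113, upper: 127}
    - {score: 3, lower: 128}
  respiratory_rate:
    resolution: 1
    bands:
    - {score: 3, upper: 7}
    - {score: 2, lower: 8, upper: 10}
    - {score: 1, lower: 11, upper: 12}
    - {score: 0, lower: 13, upper: 21}
    - {score: 1, lower: 22, upper: 23}
    - {score: 2, lower: 24, upper: 28}
    - {score: 3, lower: 29}
  temperature:
    resolution: 0.1
    bands:
    - {score: 3, upper: 35.4}
    - {score: 1, lower: 35.5, upper: 35.9}
    - {score: 0, lower: 36.0, upper: 37.3}
    - {score: 1, lower: 37.4, upper: 38.3}
    - {score: 3, lower: 38.4}
  systolic_bp:
    resolution: 1
    bands:
    - {score: 3, upper: 83}
    - {score: 2, lower: 84, upper: 90}
    - {score: 1, lower: 91, upper: 100}
    - {score: 0, lower: 101, upper: 157}
    - {score: 1, lower: 158, upper: 167}
    - {score: 2, lower: 168, upper: 184}
    - {score: 3, lower: 185}
  spo2:
    resolution: 1
    admissible: {min: 0, max: 100}
    bands:
    - {score: 3, upper: 84}
    - {score: 2, lower: 85, upper: 90}
    - {score: 1, lower: 91, upper: 93}
    - {score: 0, lower: 94}
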