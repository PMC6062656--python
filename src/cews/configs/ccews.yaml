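# Centile-based EWS derived from continuously-acquired bedside-monitor data.
name: ccews
provenance: centile-based EWS derived from continuously-acquired monitor data
oxygen_increment: 0
avpu_map: {A: 0, V: 3, P: 3, U: 3}
variables:
  heart_rate:
    resolution: 1
    bands:
    - {score: 3, upper: 50}
    - {score: 2, lower: 51, upper: 58}
    - {score: 1, lower: 59, upper: 63}
    - {score: 0, lower: 64, upper: 104}
    - {score: 1, lower: 105, upper: 112}
    - {score: 2, lower: 113, upper: 127}
    - {score: 3, lower: 128}
  respiratory_rate:
    resolution: 1
    bands:
    - {score: 3, upper: 7}
    - {score: 2, lower: 8, upper: 10}
    - {score: 1, lower: 11, upper: 13}
    - {score: 0, lower: 14, upper: 25}
    - {score: 1, lower: 26, upper: 28}
    - {score: 2, lower: 29, upper: 33}
    - {score: 3, lower: 34}
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
    - {score: 3, upper: 85}
    - {score: 2, lower: 86, upper: 96}
    - {score: 1, lower: 97, upper: 101}
    - {score: 0, lower: 102, upper: 154}
    - {score: 1, lower: 155, upper: 164}
    - {score: 2, lower: 165, upper: 184}
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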