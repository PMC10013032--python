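model:
  adaptation:
    gamma: 0.8
    rule: none
    trigger: any
  component_policy: all
  effector_delays: null
  effector_policy:
    drink:
    - 2
    food:
    - 1
    oxygen:
    - 3
  initial_thresholds:
  - 1.0
  - 1.0
  - 1.0
  m: 3
  n: 1
  p: 3
  processing_delays: null
  routing:
    drink: 2
    food: 1
    oxygen: 3
outputs:
  summary: null
  trace: null
run:
  seed: 0
  ticks: 45
schema_version: 1
stimuli:
  explicit: []
  generator:
    horizon: 30
    modality_weights:
      drink: 1.0
      food: 1.0
      oxygen: 1.0
    rate: 0.3
    strength_bounds:
    - 2.0
    - 5.0
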