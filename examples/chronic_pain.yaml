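model:
  adaptation:
    gamma: 0.8
    rule: multiplicative
    trigger: any
  component_policy: all
  effector_delays: null
  effector_policy: all
  initial_thresholds:
  - 3.0
  m: 1
  n: 1
  p: 1
  processing_delays: null
  routing:
    '*': 1
outputs:
  summary: null
  trace: null
run:
  seed: 0
  ticks: 55
schema_version: 1
stimuli:
  explicit:
  - modality: pain
    payload: {}
    strength: 2.5
    tick: 0
  - modality: pain
    payload: {}
    strength: 2.5
    tick: 8
  - modality: pain
    payload: {}
    strength: 2.5
    tick: 16
  - modality: pain
    payload: {}
    strength: 2.5
    tick: 24
  - modality: pain
    payload: {}
    strength: 2.5
    tick: 32
  generator: null
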