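model:
  adaptation:
    gamma: 0.8
    rule: none
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
  ticks: 20
schema_version: 1
stimuli:
  explicit:
  - modality: pin_prick
    payload: {}
    strength: 5.0
    tick: 0
  generator: null
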