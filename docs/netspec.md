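# Scenario document schema (version 1)

Scenario documents are YAML mappings validated strictly (unknown keys are
rejected; errors carry `/section/key` paths). `fopnet build` emits a
filled-in document; the bundled `examples/*.yaml` are canonical instances.

```yaml
schema_version: 1        # required literal

model:                   # net parameters (all optional, defaults shown)
  m: 1                   # receptors, >= 1
  n: 1                   # system components, >= 1
  p: 1                   # effectors, >= 1
  initial_thresholds: [3.0]      # length m, finite, >= 0
  processing_delays: [1]         # length n, integer ticks >= 1
  effector_delays: [1]           # length p, integer ticks >= 1
  routing: {"*": 1}              # modality -> receptor index (1-based); "*" wildcard
  adaptation:
    rule: none                   # none | multiplicative
    gamma: 0.8                   # > 0; used by multiplicative
    trigger: any                 # any | sub | supra
  component_policy: all          # "all" or modality -> [component indices]
  effector_policy: all           # "all" or modality -> [effector indices]

stimuli:
  explicit:                      # listed impacts (ticks non-decreasing)
    - {tick: 0, modality: pin_prick, strength: 5.0, payload: {}}
  generator:                     # optional stochastic train, merged in
    rate: 0.3                    # expected stimuli per tick (> 0)
    horizon: 30                  # ticks covered (>= 0)
    strength_bounds: [1.0, 5.0]  # ordered, >= 0
    modality_weights: {food: 1.0, drink: 1.0}

run:
  ticks: 30                      # >= 0
  seed: 0                        # feeds the generator and the run

outputs:                         # optional default paths for `fopnet run`
  trace: trace.jsonl
  summary: summary.tsv
```

Serialization is canonical (sorted keys, block style), so
`read(write(doc)) == doc` and re-serializing a bundled spec is
byte-identical.

## Trace format

Traces are line-delimited JSON with canonical key order: a `HEADER` line
(schema tag, initial live-token count, ticks, seed), one line per event
(`TRANSFER`, `SPLIT`, `UNITE`, `STOP`, `CHARACTERISTIC`; dense `seq`
numbers), a `TICK` line per tick with the live-token count, and a `FINAL`
snapshot mapping places to token ids and tokens to their histories.
`fopnet trace-audit` validates the conservation ledger of such a file.
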