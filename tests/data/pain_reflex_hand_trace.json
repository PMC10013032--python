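{
  "description": "Pre-registered manual tick-by-tick walk of the acute pain-reflex scenario: one supra-threshold stimulus (strength 5.0 > threshold 3.0) staged at tick 0 in a 1-receptor/1-component/1-effector net with unit processing and effector delays, under the engine's scheduling convention (synchronous ticks; per-tick transition order En0, En1, I1, S, S1, O1, En2; a token moved at tick t is frozen until t+1; the S transition unites arrivals and emits splits within one tick).",
  "path": ["e0", "e1", "i1_1", "i1_2", "s", "s1_1", "s1_3", "s1_2", "s", "o1_1", "o1_3", "o1_2", "e2"],
  "arrival_ticks": {
    "e1": 0,
    "i1_1": 1,
    "i1_2": 2,
    "s": 3,
    "s1_1": 3,
    "s1_3": 4,
    "s1_2": 5,
    "s_return": 6,
    "o1_1": 6,
    "o1_3": 7,
    "o1_2": 8,
    "e2": 9
  },
  "zeta_tick": 9,
  "latency": 9
}
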