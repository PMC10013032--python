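# fopnet

An executable **reduced generalized net** — a Petri-net extension in which
transition conditions are predicate-valued index matrices, tokens carry
timestamped characteristic histories, and all events refer to a global tick
clock — together with a ready-made instantiation: a parameterized model of a
system that lives by exchanging *foreign objects* with its environment.
Impacts enter through thresholded receptors, are processed by internal
components, and leave again through effectors, while feedback signals retune
the receptor thresholds. The bundled scenarios read this as physiology: the
acute pain reflex, chronic pain lowering the pain threshold
(hypersensitivity), and the body's intake/excretion exchange.

The package is for modellers who want discrete-event, hand-traceable
stimulus–response simulations with a full audit trail, and for anyone who
needs the reduced generalized-net machinery (index matrices, token
split/unite/stop lifecycles, conservation-ledger traces) as a library.

## The model

A reduced net is a four-tuple **E = ⟨A, K, X, Φ⟩**: transitions, tokens,
initial characteristics, and the characteristic function that appends a
record to a token's history whenever it moves. Each transition is a triple
**Z = ⟨L′, L″, r⟩** of input places, output places, and a condition *r* in
index-matrix form: cell *r(i, j)* holds a predicate, and a token in input
place *i* may move to output place *j* exactly when the predicate is true.
Execution is synchronous: every transition fires once per tick in declared
order, and a token moved at tick *t* is frozen until *t + 1*.

The stimulus–response net for *m* receptors, *n* components and *p*
effectors wires up environment transitions En0/En1/En2, receptors I_k with
resident threshold tokens τ_k, the system core S with resident status token
ω, component delay lines S_k and effector delay lines O_k — in total
m + n + p + 4 transitions and 4m + 3(n + p + 1) + 1 places over six declared
token types. A receptor passes an impact ε inward only when its strength
**strictly exceeds** the current threshold; otherwise τ_k absorbs it
(registered, not transmitted) and ε stops functioning. Threshold adaptation
is a feedback loop: the core splits off a κ token carrying the new threshold
(multiplicative rule θ ← γ·θ per trigger), which travels to the receptor and
rewrites τ_k.

## Worked example: the pin-prick reflex

```sh
fopnet run examples/pain_reflex.yaml
```

prints the per-stimulus summary

```text
stimulus	tick	modality	strength	threshold_at_arrival	registered	responded	latency
0	0	pin_prick	5.0	3.0	y	y	9
```

One stimulus of strength 5.0 hits the single receptor at tick 0, exceeds the
pain threshold 3.0, and the withdrawal reaction (the ζ token) reaches the
environment at tick 9 — the latency fixed by the path
e0 → e1 → i1_1 → i1_2 → s → s1_1 → s1_3 → s1_2 → s → o1_1 → o1_3 → o1_2 → e2
under unit processing and effector delays. Run it twice with the same seed
and the trace files are byte-identical.

The chronic-pain scenario shows the adaptation loop: with θ0 = 3.0, γ = 0.8
and a repeated stimulus of constant strength 2.5, the first impact is
sub-threshold, the threshold then falls to 3.0·0.8 = 2.4, and every later
impact elicits a response:

```python
>>> from fopnet import run_scenario, summarize
>>> summarize(run_scenario("chronic_pain"))
   stimulus  tick modality  strength  threshold_at_arrival registered responded  latency
0         0     0     pain       2.5                3.0000          y         n      NaN
1         1     8     pain       2.5                2.4000          y         y      9.0
2         2    16     pain       2.5                1.9200          y         y      9.0
3         3    24     pain       2.5                1.5360          y         y      9.0
4         4    32     pain       2.5                1.2288          y         y      9.0
```

Other entry points: `fopnet build --m 2 --n 1 --p 2` emits a scenario
document, `fopnet validate` checks one, and `fopnet trace-audit` replays a
trace file's conservation ledger (`live(t+1) = live(t) + splits − unions −
stops` at every tick).

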