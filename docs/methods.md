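# Methods

## The formalism

`fopnet` executes *reduced* generalized nets: Petri-net-like structures in
which each transition Z = ⟨L′, L″, r⟩ routes tokens from its input places
L′ to its output places L″ under an index-matrix condition r — a matrix
indexed by (input place, output place) whose cells are named boolean
predicates evaluated against the moving token, the net state and the
current tick. Tokens are information carriers: each keeps an append-only
history of (tick, characteristic) records, written by the characteristic
function Φ whenever the token transfers. The net itself is the four-tuple
⟨A, K, X, Φ⟩ — transitions, token registry, initial characteristics,
characteristic hooks — exposed verbatim as `GNet.as_four_tuple()`. The
components the reduction omits (transition priorities and durations, place
capacities, token priorities) are omitted deliberately: every firing takes
one tick, places are unbounded, and ordering is fixed by declaration.

Three token lifecycle events extend plain transfer:

* **split** — a token stays put and spawns children beside it (each with
  parent provenance and an initial characteristic);
* **unite** — co-located tokens merge; the named host survives and the
  constituents' histories are merged by a stable tick-ordered merge, the
  absorbed tokens stop functioning;
* **stop** — a token ceases to function (the fate of a signal that fails a
  threshold gate).

Every state change emits exactly one trace event with a dense sequence
number. Traces therefore support an offline conservation audit:
`live(t+1) = live(t) + split-births − unite-deaths − stops` must balance at
every tick, and `fopnet trace-audit` re-checks this (plus sequence density
and tick monotonicity) from the trace file alone.

## Scheduling semantics

Execution is synchronous. One `step()` fires every transition once, in the
net's declared order, then advances the clock. Two conventions make runs
deterministic and hand-traceable:

1. **Freeze-on-move.** A token moved or created at tick *t* may not act
   again before *t + 1*; no token ever crosses two transitions in one tick.
2. **First-enabled routing.** Under the default policy a token moves to the
   first enabled output column in declared column order (a first-enabled
   self-loop means "stay"). Model-specific policies (split/unite/stop
   choreography) override this per transition but use the same index-matrix
   predicates to decide.

A token whose condition row has no enabled column simply stays in place and
nothing is recorded; the formalism prescribes no drop rule, and we chose
the least destructive behavior.

Determinism: given the same net specification and seed, serialized traces
are byte-identical (canonical JSON, global token-id counter in emission
order). The run owns a single seeded generator which any stochastic hook
must draw from; the bundled model is itself deterministic given its
stimulus train, so the seed matters only for train generation.

## The stimulus–response net

`build_fop_net(FOPConfig(m, n, p, ...))` wires m receptors, n processing
components and p effectors between three environment transitions. Resident
tokens: ε* (the environment, place e0), ω (system status, place s), τ_k
(threshold of receptor k, place i{k}_3), φ_k (effector k, place o{k}_3).
These placements are our convention — they are the tokens the transition
descriptions keep "staying" in those places and uniting with arrivals.

Per tick, in order: En0 injects one impact token ε per due stimulus (a
split off ε*, so ε* persists to absorb the eventual reaction) and absorbs
any returning total-reaction token ζ; En1 routes ε to the receptor its
modality maps to; I_k compares the impact strength with τ_k's current
threshold — **strictly greater-than passes**, equality is sub-threshold —
and either forwards ε or lets τ_k absorb it with a registration record
("time-moment, strength, under the threshold"); S unites arrivals into ω
and then splits off work orders σ (to components chosen by the component
policy), reaction orders π (to effectors chosen by the effector policy) and
threshold updates κ; S_k and O_k are delay lines that hold arrivals and
release σ′/φ′ after the configured number of ticks (each arrival yields
exactly one release); En2 fuses whatever effector outputs are present that
tick into one ζ — no waiting barrier across effectors — and ζ finally
re-enters the environment. A π token arriving at an effector unites with
φ_k, mirroring the ε/τ_k union at the receptor; the source formalism leaves
that arrival unspecified and the convention is flagged in the code.

Enumerating this wiring gives **m + n + p + 4 transitions** (En0, En1, En2,
m receptors, the core S, n components, p effectors) and
**4m + 3(n + p + 1) + 1 places**; six token types are declared (ε*, ε, ω,
φ, τ, κ) with σ, σ′, π, φ′, ζ arising in-flight as split/union products.
The transition enumeration exceeds the closed-form count formula carried
alongside the model by exactly one — the formula does not count the central
S transition — and the acceptance suite reports both numbers rather than
reconciling them; the places formula matches enumeration exactly.

### Parameters

| parameter | units | default | role |
| --- | --- | --- | --- |
| `m`, `n`, `p` | count | 1, 1, 1 | receptors / components / effectors |
| `initial_thresholds` | impact strength | 3.0 per receptor | gate for W-type pass predicates |
| `processing_delays` | ticks (≥1) | 1 per component | component response latency |
| `effector_delays` | ticks (≥1) | 1 per effector | effector release latency |
| `routing` | modality → receptor | `{"*": 1}` | which receptor registers a modality |
| `component_policy` | modality → components | `"all"` | who processes a registered impact |
| `effector_policy` | modality → effectors | `"all"` | where a processed response exits |
| `adaptation` | rule | `none` | threshold feedback (below) |

Threshold adaptation: the `multiplicative` rule proposes θ ← θ·γ per
trigger (γ = 0.8 default; γ < 1 models sensitization, γ > 1 habituation).
The trigger is configurable — sub-threshold registrations, supra-threshold
ones, or any — because the formalism does not pin it down; the chronic-pain
scenario uses "any". Proposals compound on the last *proposed* value, not
the currently effective one, so j triggers always yield θ0·γ^j even while a
κ token is still in transit; the effective threshold changes only when κ
reaches the receptor (two-tick feedback latency: κ is split off at the core
one tick, unites with τ_k the next). New thresholds must be finite and
non-negative; anything else is rejected at the update point.

An impact whose modality no receptor claims stays in e1 and a warning is
logged — there is no drop rule to appeal to, and a silent disappearance
would falsify the conservation ledger's story.

## The abstract reference model

`impact_reaction` implements the companion formalization independent of the
net engine: environment E and system S exchange reactions R_S = F_E(E,S,t)
and R_E = F_S(S,E,t) at time-moments produced by advance maps τ_E, τ_S
(which must strictly advance; a non-advancing map raises rather than loop).
The two event streams are merged by timestamp with system-side first on
ties — the interleaving is unconstrained in the formalism, and this merge
is our recorded choice. The thresholded variant gates each reaction through
a magnitude function σ against a threshold π: delivery requires strict
inequality, matching the receptor convention, and an undelivered reaction
is state-inert. With zero thresholds and positive magnitudes the gated
model reproduces the ungated one entry-for-entry — a closed-form limit the
test suite checks on random specifications, tying the two formalizations
together.

## Synthetic stimuli and what the tests show

The stimulus generator draws per-tick Poisson arrival counts (rate =
expected stimuli/tick), uniform strengths within bounds, and modalities
from normalized weights, all from one seeded generator — same parameters
and seed, same train, exactly. This emulates an environment producing
independent, memoryless impacts of bounded magnitude. It does **not**
emulate features real physiological input has: temporally correlated or
bursty stimulation, graded receptor populations, noise in transduction, or
continuous-valued response magnitudes. Passing tests therefore demonstrate
the discrete-event logic — routing, thresholding, delays, feedback, and
conservation — not quantitative physiology; the model reports occurrence
and latency of responses, never their magnitude, because the underlying
formalism assigns none.

Scenario defaults (θ0 = 3.0, strengths 5.0/2.5, γ = 0.8, unit delays) are
package choices made for legible hand traces and are labelled as defaults
in the configs. The chronic-pain train spaces stimuli 8 ticks apart so the
κ feedback lands at the receptor before the next impact arrives, making the
onset of hypersensitivity exactly the closed-form crossing θ0·γ^j < 2.5
(j = 1: the second stimulus responds first). The pain-reflex latency of 9
ticks was derived by a manual walk of the path committed before the engine
existed (`tests/data/pain_reflex_hand_trace.json`) and is checked exactly.

Problem sizes in the test and acceptance suites — 200 stimulus trains for
the exclusivity property, 100 random nets for the brute-force firing
oracle, 50 random specs for the gate-free limit, 64 dimension combinations
for the structural counts — were chosen so the whole battery completes in a
few seconds while still exercising each property across its input space.

## Numerical and degenerate-input conventions

* Threshold comparisons are strict (`>`); equality takes the sub-threshold
  branch everywhere, in the net and in the reference model.
* Ties in routing are broken by declared column order; simultaneous
  arrivals are processed in declared input-place order, then place
  insertion order.
* A unite keeps the host's identity; a ζ token is formed by retagging the
  first effector output it fuses from (token ids keep their birth tag, the
  type tag reflects the current role).
* Zero-tick runs, empty stimulus trains and empty input places are all
  legal no-ops; negative ticks, zero/negative delays, non-finite or
  negative thresholds, unordered trains and empty split specs are rejected
  with structural errors before any state changes.

## Known limitations

* Single system vs environment only; composing multiple systems into
  super-/subsystem hierarchies is out of scope.
* Boolean predicates only — no fuzzy or interval truth values on signals
  or thresholds.
* No response-magnitude semantics: summaries report occurrence and latency.
* The full (non-reduced) net machinery — priorities, capacities, durations,
  net algebra over index matrices — is intentionally absent.
* Spent work orders (σ after their response) remain resident in their
  component loop place for the rest of the run; state grows linearly with
  registered impacts, which is harmless at the scales the package targets
  but worth knowing for very long runs.
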