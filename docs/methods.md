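# Methods

## The world model

A world is an ordered finite list of cognizers.  Cognizer *i* owns a finite
state set and a total deterministic cognition function fᵢ from the world's
joint state to its own next state; the induced product map
F(u) = (f₁(u), …, f_n(u)) drives all dynamics.  States are opaque string
labels with a declared ordering — no numeric semantics are assumed.
Cognition functions are stored as explicit lookup tables; a builder accepts
a callable and tabulates it over the world's joint-state set, so all
downstream code sees tables and any attempt to register two successors for
one joint state is a hard construction error (determinism is constitutive,
not checked after the fact).  The joint-state set defaults to the full
product of the member state sets; a restricted subset may be declared, in
which case construction verifies that F maps the subset into itself.
Trajectories are therefore exactly reproducible; over a finite joint-state
set every orbit enters a cycle within |joint states| steps, and `orbit`
returns the transient and cycle explicitly.

The *environment* of a focal cognizer is the tuple of all other cognizers'
states in declaration order.  (No canonical ordering is forced by the
formalism; declaration order is this package's convention.)  A cognizer in
a given own-state *discriminates* two environment states when its
successors under them differ; the uncertainty classes of "same successor"
form its discrimination partition.  An optional per-cognizer neighborhood
declaration expresses local causation as a static audit: the cognition
table must be constant in every non-neighbor coordinate.  The induced map
F is treated purely as the product of the member cognition functions; no
world-level cognition is modelled (the world has nothing external to
cognize).

## Probability, entropy, information

Events are subject-dependent: an event labeling maps a focal cognizer's
state transitions, many-to-one, to event labels.  A labeling with a
default label is total; a labeling without one deliberately leaves
unlabeled transitions as non-events, so the event alphabet can be exactly
the outcomes of interest (e.g. draw results) rather than every bookkeeping
step.  Two estimators are computed from trajectories (or from collections
of independently initialized trajectories — transition streams never cross
trial boundaries):

* `p_cog(traj, cond, labeling, event)` — among the events following the
  conditioning cognition, the fraction that are the focal event type.  The
  "following" event is the first labeled transition after the condition
  (exactly the t+1 transition under a total labeling); an optional `lag`
  selects later events.  A condition with no following events is
  *undefined*, raised as an error, deliberately distinct from a ratio of 0.
  Conditions are a single concrete state pair (`CognitionCondition`) or any
  transition carrying a label under a second, conditioning labeling
  (`EventCondition`) — the latter lets "reach for the preferred color" act
  as one cognition although many concrete state pairs realize it.
  Conditioning is on the focal cognizer's state change only, not on a
  (state change, perceived environment class) pair.
* `p_overall(traj, labeling, event)` — the unconditioned relative frequency
  over all labeled focal transitions.  The full distribution over the event
  alphabet is the `umwelt_summary`: the subject-dependent environment of
  the focal cognizer in that trajectory.

The external variants are the same counting engine pointed at an observer
cognizer, guarded by a static non-influence audit: every other cognizer's
table must be constant in the observer coordinate.  No mechanism for
"observation without influence" is modelled beyond this audit.

Entropy is Shannon entropy in bits, H = −Σ pᵢ log₂ pᵢ with 0·log₂0 := 0,
over count-backed distributions (probabilities are always ratios of
integer counts).  The amount of information is the signed difference
I = H_before − H_after; a negative value is surfaced, not clamped.
Distributions must be normalized to 1 within 1e-9; entropy equalities in
tests are asserted to 1e-12.

A refinement note: splitting an uncertainty class (editing the focal table
so that previously merged environment states get distinct successors) can
*raise* the entropy of an individual refined condition — a subclass may be
more mixed than the pooled class.  What refinement can never increase is
the conditional entropy H(event | cognition) averaged over conditions, by
concavity of entropy; that averaged quantity is what the package's
refinement property asserts and what the tests verify by exhaustive
enumeration on small worlds.

## The ball-box experiments

A player repeatedly draws one ball from a box of ten (two orange, three
red, five blue in the standard configuration), observes it, returns it.
Each trial is a short run of a deterministic four-cognizer world — `box`,
`balls`, `noise`, `player` — and all randomness enters through the seeded
initial conditions of the trial:

* the hidden configuration is a uniform cyclic rotation of the declared
  ball list, so each ball is equally likely at every position and the
  opaque-box draw distribution equals the composition exactly;
* the `noise` cognizer freezes the trial's discrete draws (informedness,
  uninformed reach position, percept-confusion cell, grasp quantile) and is
  constant within the trial.  Only the axes a configuration actually needs
  are instantiated, so e.g. the fully transparent box has a single noise
  state and the player's perception partition is all-singletons.

The player's within-trial phases are ready → see → reach → grasp → hold
(with at most one retry after a slip).  Perception: with probability equal
to the discrimination accuracy (defaulting to the wall transparency, an
identity link; overridable) the player correctly locates the best-ranked
color present and perceives the whole configuration; otherwise the reach is
uninformed — uniform over positions — and the *reported* percept is drawn
from a confusion kernel over colors that prefers the adjacent hue
(orange↔red weight 2, others 1; a configuration table, discretized onto six
equiprobable cells by largest-remainder allocation).  Behind a fully opaque
wall there is no through-wall percept at all (recorded as `none`).  The
kernel biases only the percept label, never the draw outcome: this is the
only arrangement under which the accuracy→0 limit reproduces the opaque
box (composition frequencies) and the accuracy→1 limit the transparent one
(certainty), both of which are asserted trajectory-identically in tests.

Ball agency is the balls' own cognition: when reached for, the targeted
ball slips with probability equal to its grasp difficulty (resolved against
the trial's frozen grasp quantile, 10 cells), sending the player to the
next-ranked color present; the second attempt succeeds.  One evasion per
trial is enough to produce the "second-best color" phenomenology; deeper
retry chains are out of scope.

The numbered variant replaces colors with numbers 1–10 and a number→gift
code.  Code knowledge k acts per trial: with probability k the player uses
the true code and targets the ball coding the preferred gift; otherwise the
reach is uninformed, as in the opaque box.  This is the simplest mechanism
matching the stated limits (k=0 uniform, k=1 certainty) of "semiotic
transparency", for which no operational scale is fixed; the interpolation
in k is linear, P(target) = k + (1−k)/10.

A Laplacian-demon observer can be attached: an extra cognizer that copies
the entire joint state with a one-step delay and that, by construction,
influences nothing (the audit verifies it).  Because its state determines
the whole system state, every conditional certainty computed on the demon
is exactly 0 or 1, while its overall event frequencies match the system's.

Exact quantities (the classical 3/10, the k∈{0,1} numbered-box
probabilities) are computed by enumerating the equiprobable initial
conditions and running the same deterministic world on each — permitted
whenever no Bernoulli axis is strictly between 0 and 1, so every initial
condition carries equal weight.

What the trial generator does *not* emulate: continuous perception noise,
position-dependent grasp kinematics, learning across trials, and
any coupling between trials (trials are exchangeable by construction).
Passing tests therefore certify the counting machinery and the stated
limit behavior, not realism of the perception model.

## Inverse-causality measurement

`ic_operation` groups a measurer's observed transitions by departing
baseline and introduces one fresh symbol per distinct observed successor,
named `<baseline>#<k>` in first-observation order (only distinctness
matters; the naming is a convention).  The identity transition
baseline→baseline receives a symbol by default — "no external change" is
itself a registered distinction — suppressible for minimal tables.
Transitions departing declared non-baseline states are relaxation returns
and are skipped; departing an undeclared state makes IC undefined (an
error), because symbols derived from a drifting, undeclared reference
cannot signify anything.  Multiple declared baselines partition the
analysis: symbols are never merged across baselines.  Soundness — distinct
successors imply distinct (baseline, symbol) predecessors on the augmented
sequence — holds by construction and is re-checked by an independent
exhaustive scan (`ic_sound`) in the tests.

`cascade_simulate` replays measurement forward in time with a one-layer-
per-step convention: the sensor changes only when an external event fires
(its states are data; nothing inside the system entails them), each
downstream layer responds one step later to the previous layer's baseline
departure through an explicit coupling table, and every deviated
sub-measurer relaxes to its most recently departed baseline on the
following step (the default relaxation window of one step; configurable
per measurer).  A missing coupling entry for an observed departure is an
error naming the entry.  The effector relaxes like any measurer even
though its states are transformations rather than symbols.  Recursive IC
(`ic_recursive`) applies the operation level by level; second-level and
higher symbol tables are flagged as signifying nonlocal states.  The
nonlocal signification is carried as provenance metadata on user-supplied
couplings — no correlation-learning machinery is included.

`classify_cascade` accepts sensor–reader–effector and
sensor–reader–interpreter–effector chains as well-formed (the interpreter
is optional), diagnoses a non-measurer in the sensor slot as
hallucination-prone (its state changes need not reflect external states),
and anything missing an effector, out of order, or with a broken
downstream measurer as malformed.

## Chemotaxis demo

The cell is a sensor–reader–effector cascade on a 1-D integer lattice with
discrete ligand levels (chosen to stay entirely within the finite-state
formalism; no continuous gradients or kinetic fits).  Parameters, with
defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `levels` (M) | 8 | methylation baselines m0…mM of the receptor |
| `adaptation_rate` | 0.2 /step | probability of one-unit methylation drift toward the ambient level |
| `tumble_base` | 0.10 /step | spontaneous tumble probability |
| `tumble_up` | 0.02 /step | tumble probability right after a sensed rise |
| `tumble_down` | 0.90 /step | tumble probability right after a sensed fall |

Each step the receptor departs its methylation baseline iff the ambient
level differs from it (`up`/`down`), relaxing the next step; the switch
relays the departure one step later (`act+`/`act-`); the motor responds one
further step later; a run moves one lattice cell along the heading, a
tumble re-draws the heading uniformly from {−1, +1}.  Methylation is the
shifting baseline: it drifts one unit toward the ambient level at the
adaptation rate, so after a concentration step the motor response is
transient and the long-run tumble frequency in any uniform field returns
to the spontaneous rate regardless of the level — the cell measures
changes, not levels.  Demethylation is folded into the same symmetric
drift rather than modelled as a separate pathway; positions beyond the
declared field are clamped to the edge with a logged warning.  The
receptor track of any simulation satisfies the measurer contract under its
declared multi-baseline set.  Gradient climbing is asserted as a sign test
across 20 seeded cells on a monotone staircase field.  The relay collapses
the kinase and its diffusible carrier into one switch layer; quorum-style
four-layer cascades are representable with the generic cascade machinery
but no worked example is shipped.

## Problem sizes and numerical conventions

Simulated checks use 10,000 trials for frequency estimates (standard error
≈ 0.005 on a probability near 0.3), 20 seeds for chemotaxis window
comparisons (4-standard-error bands on binomial window frequencies), and
100 seeded random fixtures for the IC soundness and estimator-recount
oracles.  Exact claims (enumerated probabilities, certainty ratios,
cascade traces) are asserted with no tolerance at all.  Ties in the
experiments are broken deterministically: the informed reach targets the
lowest position holding the best-ranked color, and the uninformed retry
moves to the next position along.  Degenerate inputs raise typed errors
rather than returning sentinel values: empty trajectories, zero
conditioning events, unnormalized distributions, non-closed joint-state
sets, influential observers, undeclared baseline departures, and missing
coupling entries each have a dedicated exception.

## Known limitations

* All state spaces are finite and all dynamics deterministic; stochastic
  transition kernels are out of scope (randomness only ever enters through
  seeded initial conditions or seeded per-step draws in the chemotaxis
  walk, which is a deliberately coarser layer than the cognizer worlds).
* The perception/confusion model of the semi-transparent box is one
  admissible operationalization; only color confusion is modelled, not
  positional error in the grasp.
* Coupling structures are static: no learning or evolutionary modification
  of measurer couplings is provided.
* The umwelt summary is a descriptive statistic of a trajectory, not a
  claim about hypothetical long-run propensities.
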