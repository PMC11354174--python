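# cogsys

Finite deterministic **cognizers-system** modelling for theoretical biology:
subject-internal probability and entropy estimation, inverse-causality
symbol induction, and a discrete bacterial-chemotaxis demonstration.

## The problem

How does a living system — which can never step outside itself to observe
its environment — come to register external states, estimate the
probabilities of the events that happen *to it*, and adapt?  `cogsys`
implements a minimal formal setting for that question:

* a **cognizer** is any entity (a molecule, a ball, a player, a bacterium)
  with a finite state set **Cᵢ** and a deterministic *cognition function*
  fᵢ : ∏ⱼ **Cⱼ** → **Cᵢ** mapping the joint state of the world to its own
  next state;
* a **world** of cognizers evolves by the product map
  F(u) = (f₁(u), f₂(u), …); iterating F from an initial joint state u₀
  yields the trajectory u₀, F(u₀), F²(u₀), … — identical states always
  have identical successors (the causal principle);
* **events** are subject-dependent: a labeling of the focal cognizer's own
  state changes, many-to-one.  From a trajectory the package computes
  - *P_cog*, the certainty of an event type among the events following a
    specified cognition (state change) of the focal cognizer, and
  - *P_overall*, the relative frequency of an event type over all of the
    focal cognizer's labeled state changes —
  each in an internal (in-system cognizer) and an external (audited
  non-influential observer) variant, with Shannon entropies
  H = −Σ pᵢ log₂ pᵢ and information amounts I = H_before − H_after on top.
  The full P_overall distribution is the subject-dependent environment
  (*umwelt*) of the focal cognizer;
* **inverse causality** (IC) is the contrapositive of determinism: distinct
  successors imply distinct predecessors.  A sensor that repeatedly departs
  a single baseline state to different states violates it on its face; the
  *IC operation* repairs the books by introducing one fresh internal symbol
  per distinct observed successor behind the baseline.  Those symbols are
  the system's internal stand-ins for external states it can never observe
  directly.  Replayed forward in time this becomes a
  sensor → reader → (interpreter) → effector cascade of *measurers* —
  cognizers with a return-to-baseline contract;
* the **chemotaxis demo** instantiates the cascade as a run-and-tumble cell
  on a 1-D lattice: an MCP-like receptor whose methylation level is a
  shifting baseline, a CheA/CheY-like switch, and a two-state flagellar
  motor.  The cell detects *changes* in ligand concentration rather than
  the concentration itself, adapts to steps, and climbs gradients.

## Worked example

Ten balls in a box — two orange, three red, five blue.  Behind an opaque
wall the player's reach cannot discriminate configurations; behind a
transparent wall a red-preferring player always gets red:

```python
import cogsys as cs

exp = cs.experiment_A()                      # opaque box
dist = exp.enumerate_draws()                 # exact, by enumeration
run = exp.run(10_000, seed=1)                # seeded repeated trials
r = cs.p_overall(run.trajectories, exp.outcome_labeling, "red")
h = cs.entropy(cs.umwelt_summary(run.trajectories, exp.outcome_labeling))

b = cs.experiment_B()                        # transparent box
rb = cs.p_cog(b.run(1000, seed=1).trajectories,
              b.reach_condition(), b.outcome_labeling, "red")
```

prints, via the obvious `print` calls:

```
exact: {'blue': 0.5, 'orange': 0.2, 'red': 0.3}
simulated P_overall(red) = 0.3100  (3100/10000)
umwelt entropy = 1.4948 bits
transparent box P_cog(red | reach red) = 1.0  (1000/1000)
```

The exact enumeration gives the classical 3/10 for red; the simulated
relative frequency converges to it; the umwelt entropy approaches the
1.4855 bits of the (0.2, 0.3, 0.5) composition; and perfect discrimination
plus preference turns the draw into a certainty.

Symbol induction from a bare sensor record — two distinct departures from
the baseline `a0` earn two fresh symbols (plus one for "nothing changed"):

```python
m = cs.Measurer("a", ("a0", "a1", "a2"), baselines=("a0",))
seq = cs.SensorSequence("a", ("a0", "a1", "a0", "a2", "a0", "a0"))
cs.ic_operation(seq, m).entries
# {('a0', 'a1'): 'a0#0', ('a0', 'a2'): 'a0#1', ('a0', 'a0'): 'a0#2'}
```

A command-line interface mirrors the library:

```sh
cogsys simulate --config world.json --init "x|p" --steps 10 --out traj.tsv
cogsys probability --traj traj.tsv --labeling labels.json --event switch
cogsys experiment --name B --n 1000 --seed 7 --out trials.tsv
cogsys ic infer --sequence sensor.txt --baselines a0
cogsys chemotaxis --levels 8 --adaptation 0.2 --field field.tsv \
        --steps 500 --seed 3 --out track.tsv
```

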