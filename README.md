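# causact

Symbolic-probabilistic recognition of fine-grained actions and goals from
ambient sensor streams.

The package grounds a precondition-effect causal model (written in a small
s-expression dialect) into a structured state space, attaches probabilistic
semantics to it — duration-driven action termination, log-linear
goal-directed action selection, goal persistence — and runs Bayesian
filtering over the resulting latent space against sensor likelihoods
produced by a decision-tree observation model. It ships everything needed
to evaluate the approach end to end on synthetic data:

| module                  | what it does |
| ----------------------- | ------------ |
| `causact.domain`        | dialect parser, grounding, reachability graph, plan enumeration, goal distances |
| `causact.dynamics`      | the structured transition kernel: duration CDFs/hazards, softmax action selection, goal priors, sampling and exact scoring |
| `causact.observation`   | decision-tree observation model (optimistic/pessimistic protocols, Laplace-smoothed class distributions, text serialization) |
| `causact.inference`     | exact marginal filter and particle filter; action decoding; multiple-goals and pooled-goals estimation |
| `causact.hmm`           | 8-state HMM baseline with count-estimated transitions and the joint (common-start-state) HMM for goal recognition |
| `causact.preprocessing` | raw sensor records → deduplicated, forward-filled, max-windowed tables; annotation-to-window alignment |
| `causact.kitchen`       | synthetic kitchen corpus generator: goal-directed runs simulated from the model itself, with noisy sensor emissions and ground-truth annotation |
| `causact.experiments`   | accuracy, exhaustive feature-subset sweeps, leave-one-out CV, the 10-cell AR and 16-cell GR factorial designs, paired Wilcoxon comparison |

## CLI

A single entry point `causact` with subcommands:

```sh
# parse + ground a model file, write a TSV grounding report
causact ground --domain kitchen.lisp --out grounding.tsv

# generate a 15-run synthetic corpus (sensors.csv / annotation.csv /
# truth.json per run + manifest.json)
causact simulate --n-runs 15 --seed 0 --out corpus/

# train the decision-tree observation model on labelled window CSVs
causact train-om --windows run0.csv --windows run1.csv \
    --protocol pessimistic --out om.json

# filter an observation CSV (exact filter by default, or --particles N)
causact infer --domain kitchen.lisp --om om.json --obs run1.csv \
    --seed 1 --goal-mode multi --truth pasta --out result.json

# HMM baseline
causact hmm-train --annotations ann.csv --out hmm
causact hmm-infer --transition hmm.transition.csv --prior hmm.prior.csv \
    --om om.json --obs run1.csv --out hmm_result.json

# evaluation harness
causact evaluate --predicted pred.csv --truth truth.csv
causact feature-select --corpus corpus/ --exclude-coords --out sweep.json
causact factorial --design ar --n-runs 6 --seed 0 --out cells.csv
```

## Model dialect

UTF-8 s-expressions; supported sections are `(:types child - parent …)`,
`(:objects name - type …)`, `(:predicates (name ?v - type …) …)`,
`(:action name :parameters … :duration (normal M SD | geometric P |
uniform A B | empirical FILE) :precondition … :effect … :observation
class)`, `(:init atoms…)` and `(:goal name (and atoms…))` (several named
goals allowed). Preconditions are conjunctions/negations over atoms plus
`(= ?x ?y)` equality atoms; effects are add/delete conjunctions. See
`causact.kitchen.kitchen_source()` for a complete example.

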