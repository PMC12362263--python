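# equivnet

Simulation of **stimulus equivalence** — the emergence of untrained
conditional discriminations (reflexivity, symmetry, transitivity) after
training only a subset of relations — with a projective-simulation
agent, a graph-diffusion consolidation step, and Relational Density
Theory instrumentation.

The package is for behavioral scientists and computational modellers
who want to run matching-to-sample (MTS) experiments *in silico*:
define stimulus classes and a phase schedule, train a cohort of agents
to a mastery criterion, consolidate derived relations, probe
entailment, and track how the density, volume and mass of each
relational network evolve trial by trial.

## The model

**Agent memory.** Every stimulus the agent perceives becomes a *clip*,
a node in a weighted directed graph.  The edge weights (h-values) are
updated by differential reinforcement with damping toward a resting
value of 1:

    h(t+1) = h(t) − γ·(h(t) − 1) + λ

with λ = +1 on a correct match and −1 on an incorrect one (the reverse
edge is mirrored).  Choice among comparison stimuli follows a softmax
over h-values, `p_i ∝ exp(β·h_i)`, with temperature β_h during
training and β_t during testing; unseen edges score at the resting
weight h₀ so novel comparisons are picked at chance.

**Consolidation (Network Enhancement).** The reinforcement rule alone
never creates derived relations.  Periodically the whole weight matrix
is de-noised by a diffusion built from a K-nearest-neighbour
transition kernel P (symmetrized, with self-loop regularization):

    W(t+1) = α · K W(t) K + (1−α) · K

where the kernel K is P itself (directed variant, DNE) or the
symmetric localized kernel T (SNE).  Because K is row-stochastic the
iteration is a contraction and always converges.  Directly experienced
edges are never overwritten — consolidation only *adds* derived
(transitive, equivalence, reflexive) relations.  It can run once at
the end of training or after every mastered phase; comparing the two
schedules is the package's flagship experiment.

**Relational Density Theory.** Each class's network is summarized per
trial by volume measures (true and empirical nodal distance, class
size, number of relations) and density measures (intra-class mean
transition probability, class accuracy, mean h-value); relational mass
is their product, `Rm = Rp × Rv`.  Pearson correlations between every
density and volume series quantify the inverse density–volume
relationship the theory predicts.

## Worked example

```python
from equivnet import make_fixture, run_cohort

config = make_fixture("two_class_linear")   # two 3-member classes, phases A-B then B-C
cohort = run_cohort(config, schedule="end_of_training")
print(cohort.per_phase.to_string(index=False))
print("derived-relation test accuracy:", cohort.test_accuracies)
r = cohort.correlations.mean_r("mean_transition_probability", "class_size")
print(f"mean r(density, class size) = {r:.3f}")
```

prints

```
    phase  trials_per_block  mean_blocks_to_mastery  mean_final_accuracy
phase1_AB                24                2.666667             0.944444
phase2_BC                24                2.666667             0.916667
derived-relation test accuracy: {'A-C': 1.0, 'C-A': 1.0, 'B-A': 1.0}
mean r(density, class size) = -0.886
```

The three agents each needed two to three 24-trial blocks to reach the
0.9 mastery criterion per phase.  After consolidation, the never-trained
A–C, C–A and B–A probes are answered perfectly — the agents derived
symmetry and transitivity from A–B and B–C training alone.  The strong
negative correlation says intra-class relation strength (density) falls
as the class gains members (volume), the inverse relationship predicted
by Relational Density Theory.

The same machinery scales to the built-in `cotter_stewart` fixture: a
four-class design (two five-member and two three-member classes, four
comparison-only foils) trained over five phases of 48/48/24/24/72
trials per block, run as a 15-agent cohort under both consolidation
schedules:

```
equivnet replicate-cotter-stewart --n-agents 15 --seed 0 --outdir results/
```

which writes the phase summary table, per-agent metric time series,
checkpoint relation counts, correlation summaries and a reproducibility
manifest.

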