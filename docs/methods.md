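# Methods

## The agent and the task

The agent is a projective-simulation learner whose memory is a weighted
directed graph over *clips* — one clip per stimulus it has perceived.
A matching-to-sample (MTS) trial presents a sample stimulus and a set
of comparison stimuli; the agent picks a comparison by sampling the
softmax distribution `p_i ∝ exp(β·h_i)` over the edges from the sample
to each comparison, and the chosen edge receives differential
reinforcement

    h ← h − γ·(h − 1) + λ ,

λ = `reward_correct` (+1) on a match, `reward_incorrect` (−1)
otherwise.  The update damps every weight toward the resting value 1
(the fixed point at λ = 0), so h = 1 doubles as the initial weight h₀
and as the score of a never-seen edge at choice time — novel
comparisons are picked at chance.  h-values are unbounded in both
directions; a strongly punished edge simply becomes very unlikely
under the softmax.

Design choices here, made where the procedure was genuinely open:

- **Mirrored reinforcement** (`mirror_updates`, default on): the
  reverse edge receives the same λ.  Without it, symmetry relations
  could not exist before consolidation, while trained networks in this
  paradigm clearly contain them mid-training.
- **Global damping** (`global_damping`, default on): every stored edge
  is damped once per trial; the reinforced edge additionally receives
  λ.  At the study's γ = 0.001 this is a very slow forgetting process.
- **No clamping and no reflexive edges during training**: reflexive
  relations can only arise through consolidation.

A *block* presents every trained pair `presentations_per_pair` times
in random order; the comparison set of a trial is every stimulus
sharing the correct comparison's role letter (4-alternative MTS in the
replicated design), which is how never-trained, comparison-only
stimuli (D3, D4, E3, E4) enter the agent's memory as foils.  A phase
repeats blocks until block accuracy reaches the mastery criterion
(0.9), read as plain within-block accuracy — the simplest gate
consistent with "90% mastery before progressing".  Blocks-to-mastery
is the phase's time statistic.  Non-convergence within `max_blocks`
(50) is flagged, never silently truncated.

## Consolidation

Derived relations are introduced by a graph-diffusion de-noising step
applied to the whole weight matrix (negative weights clamped to zero
on entry):

1. *Localization.*  Each node selects its top-K neighbours by weight
   (ties broken by label order).  The selected weights are
   symmetrized — i stays coupled to j if either selected the other —
   and row-normalized so that each node keeps `self_retention` (0.5)
   of its transition mass on itself and distributes the rest over its
   neighbourhood.  Both regularizations follow the original network-
   enhancement construction, and both are load-bearing: for a
   linearly trained class the bare top-K kernel is bipartite, and a
   diffusion that accumulates only odd kernel powers can never place
   weight on even-hop (transitive, A→C) or reflexive positions.  With
   K = 1 (the study setting) the symmetrized graph can still fragment
   into strongest-link components for long chains — five-member
   classes sometimes derive only part of their transitive closure,
   which is visible in the entailment probes.  All-zero rows become
   uniform (isolated clips stay well-defined); zero columns in the
   symmetric kernel are skipped.
2. *Diffusion.*  `W ← α·K W K + (1−α)·K` iterated to a 1e-8 sup-norm
   change (at most 100 iterations), with kernel K = P for the directed
   variant (DNE, the default — it separates classes more cleanly) or
   the symmetric localized kernel T for SNE.  Row-stochasticity makes
   the map an ∞-norm contraction with rate α, so convergence is
   guaranteed and monitored anyway.
3. *Write-back.*  The converged matrix is rescaled to [0, max input h]
   (zeros preserved) so the training temperature β_h keeps its
   meaning, then written back with one rule: **directly experienced
   edges (trained, mirrored, and incorrect) keep their stored
   h-values**.  Consolidation therefore only adds derived relations —
   its stated purpose — and never erases the negative weights that
   encode learned rejections of foils.  An alternative reading that
   also excludes trained edges from the diffusion *input* is available
   as `baseline_mode="exclude_input"`.

The step runs on one of three schedules: `none`, `end_of_training`
(once, before the entailment probes), or `during_training` (after
every mastered phase).  It consumes no randomness, so matched-seed
cohorts share identical trial streams up to the first application.

## Density, volume, mass

All measures are computed per class per trial (`rdt_sampling_stride`
= 1), with class membership fixed to the experiment's declared members
— comparison-only foils do not count toward class size, though their
clips can serve as path intermediates.

Volume:

- **True nodal distance** — over all member pairs, the number of
  intermediate nodes on the shortest path through the *current* graph
  (edges above threshold h₀ + 1e-9, treated as undirected), derived
  and inter-class edges included.  A disconnected pair pays a finite
  penalty of (present members − 1), which produces the characteristic
  spike when a member first appears in the comparison role before its
  trained relation exists.
- **Empirical nodal distance** — the same count restricted to the
  directly trained relations, a pure training-structure fact that
  never depends on h-values.  Untrained disconnected pairs pay the
  same finite penalty.
- **Class size** — members sighted so far.
- **Number of relations** — directed intra-class edges above
  threshold.

Density:

- **Mean transition probability** — the agent's own softmax applied
  to the class: for every ordered pair of distinct members,
  `exp(β_h·h_ij)` normalized over the transitions from i to all class
  members *including the self transition* (absent edges read 0),
  averaged over pairs.  A single-member class scores exactly 1.0 (the
  early-trial spike); once weights saturate, the mean approaches
  1/(class size − 1), hence the measure's strong inverse relationship
  with the volume measures, and consolidation's weak derived and
  reflexive edges lower it further.  We considered normalizing only
  over stored outgoing edges instead; that variant saturates near 1
  for any trained class and carries almost no volume information, so
  the intra-class distribution is the measure the package reports.
- **Class accuracy** — cumulative proportion correct over trials whose
  sample belongs to the class.
- **Mean h-value** — mean intra-class weight above threshold;
  unbounded and skewable by heavily trained outliers, but independent
  of β_h.

Relational mass is the product of any density with any volume.  Cohort
analysis computes one Pearson r per (density, volume, class, agent)
over the trial series, then averages; zero-variance or too-short
series are reported missing, never zero.  A pooled mode concatenates
series instead.

## The replication experiment

The built-in `cotter_stewart` configuration reproduces a five-phase,
four-class linear training structure: classes 1–2 with five members
(A–E), classes 3–4 with three (A–C); phases train A–B (48 trials per
block), B–C (48), C–D (24, classes 1–2 only), D–E (24), then mixed
training of all twelve pairs (72); D3, D4, E3, E4 appear only as
foils.  Entailment probes (A–C, C–A, C–B, B–A for all classes; D–C,
E–D, A–E, E–A for the five-member classes) run after training with
β_t, no feedback, four presentations per tag and class.  Agent
parameters follow the study: γ = 0.001, K = 1, β_h = 0.1, β_t = 4,
α = 0.7, mastery 0.9, DNE, 15 agents (seeds base + 0..14, so any agent
is re-runnable in isolation).

`scripts/acceptance.py` runs both consolidation schedules at exactly
these settings (roughly a minute on one CPU) and reports the phase-5
and phase-1 cohort statistics and the mean density–volume
correlations.  The per-pair presentation counts (12 for phases 1–4, 6
for phase 5) are fixed by the published per-block trial counts.

## What the simulation does and does not show

The synthetic task uses abstract labels and a noiseless learner: there
is no stimulus generalization, no attention or motivation dynamics,
and no response latency (the usual laboratory proxy for relational
density) — the transition-probability density is the model-internal
stand-in.  Passing tests therefore validate the mechanisms (learning
rule, consolidation, metric definitions, schedule contrasts), not
quantitative predictions about human participants.

Known limitations:

- With block-level gating at 0.9, cohort mean mastered-block accuracy
  sits near 0.93–0.96 in every phase; configurations in which the
  mixed phase is passed near-perfectly would require trained
  discriminations far sharper than the 0.9 gate produces.
- K = 1 localization derives only the strongest-link spanning
  structure of large classes (see above); raising `k_neighbors`
  densifies the derived closure.
- Counterconditioning (reversing trained relations) and per-relation
  resistance tracking are out of scope; relational mass is computed at
  class level only.

Numerical conventions: softmax computed with max-subtraction; diffusion
tolerance 1e-8 with a 100-iteration cap and a divergence guard;
K-NN ties broken by label order; edge-existence threshold h₀ + 1e-9;
all randomness flows through a single seeded generator per agent.
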