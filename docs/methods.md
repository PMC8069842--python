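# Methods

This note records the model, the training procedure, the design choices that
were genuinely open, the numerical details, and the limits of what the
package's tests establish.

## Environment

The habitat is an `N×N` lattice with periodic boundaries and hard occupancy
exclusion (at most one agent per cell).  Time advances in discrete steps.
Within a step, one uniformly random permutation over *all* living agents is
drawn and agents act sequentially in that order, each action taking effect
immediately.  Sequential application resolves movement conflicts implicitly —
a later mover that targets a now-occupied cell is simply blocked — and the
per-step re-randomization avoids any species- or index-order bias.

Rules, per agent turn:

* Predator onto empty cell: moves.  Predator onto prey: eats it (reward +1),
  its starvation clock resets to 0, and with probability `bX` a newborn
  predator (clocks 0) appears in the vacated cell.  Predator onto predator:
  blocked.
* Prey onto empty cell: moves, and with probability `bY` a newborn prey
  (age 0) appears in the vacated cell.  A blocked or stationary prey does not
  reproduce — fecundity is tied to successful relocation.  Prey onto
  predator: the prey is eaten; the fed predator's starvation clock resets but
  it does not reproduce and receives no reward (reproduction and reward are
  attached to the predator's own move-and-eat).
* After all agents act, clocks advance: predators that ate nothing this step
  gain one starvation level and are removed on reaching `TX`; prey age one
  step and are removed at `TY`.  An optional predator maximum age `TX_age`
  (off by default) removes old predators the same way.

Rewards are antagonistic and capture-driven: the only nonzero rewards are +1
to a predator for a capture caused by its own move and −1 to the captured
prey.  The −1 is charged whichever side initiated the capture, folded into
the prey's final transition record.  The design rationale: if passive capture
were costless, prey returns (which are never positive) would make early death
weakly *preferable* to survival, no evasion pressure would exist, and the
co-evolution reliably degenerates to prey extermination; with the penalty,
evasion and the downstream population effects emerge.

Observations are `r×r×C` egocentric windows (`C = 2` species channels,
observer visible at the center of its own channel) with toroidal wrap-around;
a config toggle (`obs_padding`) instead zero-pads beyond the grid edge for
experiments on bounded perception, but periodic observation is the default
and matches the movement topology.  Windows are flattened channel-blocked
(predator plane first, row-major) before entering the networks.

Agents removed mid-step do not act that step; their open experience record is
closed as terminal.  Newborns first act on the following step.  An episode
ends at extinction of either species or at the step cap (`max_steps`,
default 2000).

## Policies and training

All agents of a species share one policy: a two-hidden-layer tanh perceptron
(64/64 by default) from the flattened window to nine logits, sampled through
a softmax.  Parameter sharing with decentralized execution keeps the learning
problem one policy per species while behavior stays heterogeneous through the
observations.  Weight initialization is Gaussian with 1/√fan-in scale and a
10⁻³-scaled final layer, so fresh policies act essentially uniformly — the
"random policy" baseline is exactly the untrained special case.

Training alternates approximate best responses.  For the learning species
(opponent parameters frozen and never touched — the detachment is structural,
verified bit-for-bit in tests):

1. **Critic.**  `Q(s,·)` (same architecture, nine outputs) descends
   `L(Q) = (1−γ)·E_{μ0,π}[Q(s0,a0)] + E_D[f*(δ)]` with residual
   `δ = r + γ·E_{a'~π}[Q(s',a')] − Q(s,a)` and `f*(y) = y²/2`.  All action
   expectations are exact nine-way sums rather than samples; terminal records
   use zero continuation.  `μ0` is estimated from stored episode-start
   observations.
2. **Actor.**  θ ascends the same objective plus `β·H(π_θ)`; the gradient is
   the exact total derivative with the critic detached (the residual term
   contributes `E[δ·γ·∇_θ E_{a'~π}Q(s',a')]`).

Gradients are computed by hand-written backpropagation through the small
dense networks, and parameters move under Adam with decoupled weight decay
(10⁻⁴).  The outer loop (per iteration: prey stage, predator stage, `h = 70`
fresh environment steps into a shared FIFO replay buffer, one strengthening
actor update per species) runs for a fixed iteration budget; the buffer is
reset once at procedure start, and episodes that terminate during collection
restart immediately with fresh placements.  One seed expands into independent
named streams (placement, policy-init, rollout, training), so runs are
bit-reproducible and stages can be re-seeded independently.

A known identity anchors the objective's correctness tests: on a tabular
MDP with data distribution `d_D`, the *minimized* objective equals
`ρ(π) − ½·E_{d_D}[(d_π/d_D)²]`, where `d_π` is the policy's normalized
discounted occupancy (for on-policy data, exactly `ρ(π) − ½`).  The test
suite verifies this against a dense linear-solve oracle to 10⁻³ on
enumerated ≤3-state MDPs.  The constant offset is a property of the
half-square regularizer `f(x) = x²/2` (whose divergence does not vanish at
`d = d_D`); it shifts the critic's landscape uniformly and leaves the actor's
gradient field pointing at the regularized return.

### Hyperparameters

| parameter | default | rationale |
|---|---|---|
| γ | 0.99 | long survival horizons; rewards are sparse captures |
| h | 70 steps | collection horizon between update iterations |
| iterations | 20 | policies stabilize within a few tens of iterations |
| inner steps | 50 | critic+actor pairs per best-response stage |
| batch | 256 | replay batch |
| buffer | 10⁵ | FIFO capacity per species |
| critic lr | 10⁻³ | |
| actor lr | 10⁻⁵ predator / 10⁻³ prey | see below |
| entropy β | 0.01 | keeps exploration alive without washing out skill |

The per-species actor asymmetry is the package's central stability choice.
With symmetric actor rates the predator stage — fed by a dense +1 capture
signal against the prey's sparse −1 — overshoots within a handful of
iterations: evaluation episodes end in prey extinction in under 40 steps at
every symmetric setting we scanned (rates 10⁻⁵…3·10⁻⁴, entropy 0.01…0.2,
10…50 inner steps, 10…40 iterations).  Letting prey adapt two orders of
magnitude faster than predators (the same ratio used for the Q-learning
comparison's per-species rates) keeps the arms race inside the sustainable
regime: both species survive full evaluation horizons across seeds, with
prey dominance.  Equal-speed pursuit on a torus is intrinsically
predator-favored — a predator adjacent to a fleeing prey captures it with
probability ≈ ½ per step through the turn-order lottery — so predator skill
is sharply destabilizing, and the asymmetry compensates.

## Analyses

* **Population series**: per-step counts plus an exact event audit (captures
  by each mechanism, births, starvation/age deaths).  Conservation identities
  (`Δprey = births − captures − age deaths`, `Δpred = births − starvation
  deaths`) hold exactly and are asserted over long random rollouts.
* **Summary statistics**: post-burn-in means, SDs, CVs, the prey-minus-
  predator dominance gap, and a dominant oscillation period read off the
  first autocorrelation peak above 0.2 (threshold chosen to ignore noise
  lags; a pure period-40 sinusoid is recovered to ±1).
* **Phase plane**: the (predator, prey) trajectory split at a policy-switch
  step, with per-segment centroids and excursion radii (max distance from
  centroid); the shoelace enclosed area detects closed cycles.
* **Swarming**: Clark–Evans ratio `R = mean NN distance / (0.5/√density)`
  with toroidal distances.  On a *lattice with occupancy exclusion* the CSR
  expectation of `R` exceeds 1 (≈1.16 at 20% density, ≈1.03 at 4%), so all
  aggregation judgments use Monte-Carlo CSR envelopes at matched `(n, N)` —
  and the calibration test checks the empirical mean against an exact
  hypergeometric nearest-neighbor oracle rather than against 1.
* **Robustness**: frozen trained policies re-run under ±20% initial counts,
  other grid sizes (counts scaled with area to preserve density), and
  predator age caps, reporting survival-to-cap and post-burn-in statistics.

## Scaled study conditions

Ecosystem-level tests run at desk scale: a 30×30 torus with 36 predators and
180 prey (the default 4%/20% densities), 10 outer training iterations, and
600-step evaluation episodes over five paired seeds; the transition
experiment switches policies at step 500 of an 1100-step episode.  These
sizes keep the full suite in tens of minutes on one CPU core while leaving
the dynamics qualitatively intact.

What the scaled runs show: co-evolved policies sustain both species for full
horizons in all seeds with consistent prey dominance; prey at episode end are
significantly aggregated below the CSR envelope (emergent swarming); phase
cycles tighten markedly after a random→trained switch (excursion radius
drops by ~35%); and the frozen policies survive across all perturbation
variants.

What they do not show: at this scale the *random* baseline is itself
ecologically stable — prey walking into predators feed the predator
population so effectively that the random ecosystem already sits at its
carrying capacity (≈150 predators / ≈190 prey, no extinctions in any probe
seed at N = 30, horizon 2000).  Consequently the trained equilibrium's mean
populations and survival times are statistically indistinguishable from the
random baseline's rather than above them, and the transition experiment
dampens fluctuations without raising means.  On smaller habitats (N = 20),
where demographic noise makes random-policy ecosystems genuinely fragile
(extinctions in half the probe seeds), the full contrast appears: random
runs collapse while trained runs persist with positive dominance gaps (see
`examples/02`).  The trained-vs-random ordering tests are nevertheless
specified and run at N = 30, and their outcomes are reported as measured.

## Known limitations

* Single-cell motion and equal speeds make open-field escape impossible;
  prey survival rests on avoidance, not outrunning, which narrows the stable
  training regimes.
* The critic/actor use exact action expectations but single-sample successor
  states; on stochastic dynamics the conjugate term is estimated with the
  usual replay bias.
* The Q-learning baseline is tabular over exact window patterns; it neither
  generalizes across patterns nor controls table growth, and is intended
  only as a reference dynamic, not a tuned competitor.
* Checkpoints store full float precision as hex strings in JSON —
  portable and bit-exact, but bulky for large networks.
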