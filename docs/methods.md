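# Methods

## Task model

A planning environment is a rooted out-tree. The start node carries no
reward; every node at depth *d* ≥ 1 hides a reward drawn independently
from that depth's distribution — a discrete uniform over a finite integer
set, or a zero-mean normal. Participants may reveal any node's reward for
a fixed click cost (default $1), in any order, before committing to a
start-to-leaf path; a trial's score is the sum of rewards on the chosen
path minus the fees paid. The *belief state* is the set of rewards
revealed so far; it is the only input to strategy policies and features.
Because every reward distribution has mean zero, the expected value of a
path under a belief is just the sum of its observed rewards.

Four presets are built in. The 3-step layouts have 3 first moves, one
forced second move each, and a binary final split (13 nodes, 6 paths).
Reward sets: increasing variance {−4,−2,+2,+4}/{−8,−4,+4,+8}/
{−48,−24,+24,+48} by depth; decreasing variance is the mirror image;
constant variance uses {−10,−5,+5,+10} at every depth. The increasing-
variance sets are chosen as the mirror of the decreasing-variance ones,
consistent with the variance ordering and the ±48 final outcomes; they
are configurable. The 5-step preset keeps the 3-branch trunk with binary
splits at the final two steps and normal rewards with σ = (1, 2, 4, 8, 32)
by depth; the branching is configurable since only the per-depth σ is
fixed. Environments serialize to YAML/JSON.

## Strategy library

A strategy maps a belief state to a distribution over the available
planning operations (unclicked nodes plus TERMINATE), choosing uniformly
among all operations it treats as functionally equivalent. Seventeen
strategies ship by default, spanning seven type labels: no planning;
random search; exhaustive search; myopic inspection of immediate outcomes
(complete and satisficing) and breadth-first sweeps; satisficing
depth-first search; best-first search (plain, satisficing, and after a
full immediate sweep); goal-setting variants that inspect final outcomes
first (satisficing on the best possible value, frugal positive-outcome
stopping, maximizing with limited backward planning, exhaustive, and
consecutive-second-maximum stopping); local search around already
observed nodes; and middle-out exploration. The registry accepts user
additions, so richer catalogues can be restored; registry order defines
the strategy index space used everywhere downstream.

Satisficing thresholds default to the canonical $48 aspiration level
where ±48 rewards exist; in the constant-variance preset, which has no
±48, the threshold is the maximum attainable path value (30), and for
normal rewards "best possible final outcome" is read as 2σ of the leaf
depth. After termination the simulator picks the expected-value-maximal
path with uniform tie-breaking; path choice is not part of the inference
model, which uses clicks only.

## Features and decision systems

The observation model describes each candidate operation by 26 features,
each assigned to exactly one of five decision systems and carrying a sign
(+1 increase / −1 decrease of that system's influence):

- *model-free values & heuristics*: depth, immediate/final-outcome
  indicators, parent/ancestor/successor/sibling-observed indicators,
  observed count on the action's path, membership in the best observed
  first-move branch;
- *Pavlovian*: best observed reward preceding/following the node on its
  path (+), observed loss preceding/following (−);
- *model-based metareasoning*: myopic value of information (expected
  improvement of the best path value from the observation, computed
  exactly for discrete rewards and by 15-node Gauss–Hermite quadrature
  for normal ones), the node's prior uncertainty, and uncertainty on the
  currently best path;
- *mental-effort avoidance*: a TERMINATE indicator and the number of
  clicks already made at termination;
- *satisficing & stopping*: aspiration-level-met indicator, best path
  value at termination, best/positive final-outcome found, positive
  immediate outcome found, and the explored fractions (overall,
  immediate, final) at termination.

Click-specific features are 0 for TERMINATE and stopping features are 0
for clicks, so all actions share one vector space. Values are raw
(unstandardized); fitted weights are therefore interpretable only jointly
with the feature manifest, which records name, category, and sign and is
hashed into all serialized outputs. The feature-to-system assignment is a
documented design choice of this package.

## Observation model

Strategy weights are fitted once at τ = 1 by maximum likelihood from 300
trials simulated with the strategy's generative procedure; with τ fixed
this is a convex multinomial-logit problem, solved by L-BFGS with an L2
ridge of 1e−4 for identifiability of collinear features. The
inference-time temperature τ of the softmax then rescales all strategies'
propensities jointly. The 300-trial default puts roughly 2,000 choice
observations behind each 26-dimensional fit, which recovers known softmax
policies' action distributions to a few percentage points; it is
configurable. The "average click likelihood" diagnostic reports both the
arithmetic mean of per-action probabilities (primary) and the geometric
mean.

## Sequence inference

Strategy sequences form a hidden Markov chain: uniform initial
distribution, abrupt transition prior (repeat with probability p_stay,
else jump uniformly), softmax emissions. The MAP sequence is decoded by
Viterbi in log space; ties are broken toward the lowest strategy id at
every backtrack step so decoding is deterministic. p_stay is fitted by
grid search over {0, 0.02, …, 1} (ties → smallest value) and τ by a
deterministic derivative-free search over [1e−2, 1e2] on a log scale — a
coarse log-grid scan followed by bounded scalar refinement, 50 objective
evaluations in total — maximizing the joint probability of the MAP
sequence. Hyperparameters are fitted per participant by default (a
shared mode is a flag), alternating once: τ at p_stay = 0.5, then
p_stay, then τ again.

A *gradual* transition prior — transition probability ∝
exp(−Δ(s_i, s_j)/bandwidth) with Δ the symmetrized-KL strategy distance —
is provided as a labelled stand-in variant for prior comparison only.
`compare_priors` ranks priors by AIC/BIC using the joint log-probability
of the data and the MAP sequence; emission terms alone cannot
distinguish priors that agree on the decoded sequence. k counts the two
fitted hyperparameters per prior and n is the number of trials.

## Strategy space analysis

Pairwise strategy distances are symmetrized KL divergences between the
distributions of whole trials (ground truth plus click sequence),
estimated by Monte Carlo: trials are sampled from each strategy's fitted
observation model at τ = 1 and scored under both. The diagonal is exactly
zero, the matrix exactly symmetric by construction, and negative
finite-sample KL estimates are clamped at zero with a kept count; each
entry carries its Monte-Carlo standard error. Ward's hierarchical
clustering of the distance matrix groups strategies into types;
`n_clusters` is a parameter because the canonical 13-type solution arose
from a much larger strategy catalogue and is not reproducible from a
reduced set — the built-in type labels in the strategy manifest are the
default grouping used for type-level accuracy.

The relative influence of decision system *ds* on a strategy is
RI_ds = |w_ds| / Σ_{ds'} |w_{ds'}|, where w_ds sums the strategy's
weights on the system's features with their manifest signs. All-zero
weights yield a uniform profile with a warning flag. Strategy performance
is the mean trial score over simulations, min–max normalized across
strategies to r^rel ∈ [0, 1].

## Synthetic data and validation studies

The generators emulate three regimes of strategy change: per-trial
random choice, abrupt Markov switching (default p_stay = 0.8), and
gradual drift — a Gaussian kernel (width 1.5 ranks) over the strategy
ordering given by the first principal coordinate of the distance matrix.
Clicks are sampled from the true strategy's fitted softmax model at a
generation temperature τ_gen (default 1), the same family the inference
uses; richer learning models (e.g., a fitted rational
strategy-selection learner, insight-like jumps) are not included, so the
generators bracket the plausible dynamics rather than reproduce any
specific learning theory. Recovery runs use 50 participants × 31 trials
per generator, sized for desk-scale minutes; larger runs are a parameter
change.

What passing recovery shows — and what it does not: clicks are generated
from the same observation-model family used for inference, so recovery
accuracy measures the separability of the strategies' click signatures
and the correctness of the decoder, not robustness to human behavior
that fits none of the built-in strategies, within-trial strategy mixing,
attention lapses, or timing effects (timestamps are read but unused).

The influence-trend study builds ground-truth sequences whose relative
influence on one decision system increases, decreases, or stays constant
(monotone trends visit each strategy once in sorted-influence order;
constant sequences sample within a 33rd/67th/100th percentile group),
then checks the Spearman correlation between trial index and the mean
inferred influence curve.

## Numerical choices and degenerate inputs

All likelihoods and the Viterbi recursion are computed in log space with
log-sum-exp; p_stay = 0 and 1 are handled exactly via −∞ transitions.
Zero-click trials contribute their single TERMINATE term. A single-trial
dataset makes all p_stay values tie, returning 0 by the tie rule.
Expected-value path ties are broken uniformly at random during
simulation but deterministically (lowest id) during decoding. Seeds
control every random source; SeedSequence spawning keeps streams
independent across strategies and participants.

## Known limitations

- The built-in strategy and feature sets are faithful to the families
  the method is described with, but are a curated subset; absolute
  accuracy numbers depend on the catalogue size and composition.
- Trees only: environments with cycles, multiple parents, or edge
  rewards are rejected at validation.
- MAP decoding only; no forward–backward posterior marginals, and no
  hierarchical pooling across participants.
- The gradual transition prior and the gradual-drift generator are
  documented stand-ins built on the strategy distance matrix.
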