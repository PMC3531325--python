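# Methods

## Game and representation

The game is the standard 10-round trust exchange: per round the investor is
endowed with $20 and sends a fraction *I* ∈ {0, ¼, ½, ¾, 1}; the transfer
is tripled; the trustee returns a fraction *R* ∈ {0, 1/6, 1/3, 1/2, 2/3} of
the tripled amount.  The trustee grid contains the exact-return anchor
(R = 1/3 repays exactly the investment) and the even-split anchor
(R = 1/2), the modal trustee behavior in such games; both grids are
configuration, not constants.  A zero investment collapses the trustee's
action set to a single null move, which contributes no trustee
log-likelihood term and no belief update about the trustee.  Money is kept
as floats and fractions are compared with a 1e-9 tolerance; exact
arithmetic buys nothing here since the trustee grid contains 1/6 and 2/3.

## Utility and types

Players have Fehr–Schmidt inequity-averse utility with the envy
(disadvantageous-inequality) term fixed to zero:
u(m_own, m_other; β) = m_own − β·max(m_own − m_other, 0).  The guilt
parameter β ≥ 0 is a player's private *type*.  The default type grid is
{0, 0.4, 1.0} — selfish, moderately averse, strongly averse — which keeps
exact Bayesian enumeration cheap while spanning qualitatively different
play; it is configurable.  The engine shares one utility tensor between
candidate partner types and the player's own guilt, so a player's guilt
must be a grid element; the generator and the fitting grid only ever use
grid values.

## Depth-of-thought recursion

A level-k player maintains a belief over the partner's type and interprets
the partner as a level-(k−1) player.  The recursion terminates in two
*myopic* policies that involve no further simulation:

* myopic trustee: softmax of the single-round repayment utilities;
* myopic investor: softmax of single-round investment utilities expected
  under the myopic trustee policy averaged over a belief about the
  trustee's type (uniform where the model in question carries none).

A level-0 player plans two rounds ahead for itself but interprets the
partner through these myopic policies; its nested partner model carries
only a belief about the player, which is what makes the second-order
expectation well defined at every level.  A level-1 player simulates a
level-0 partner (a planner with myopic interpretation); a level-2 player
simulates a level-1 partner.  Within a round the observation order is
fixed: everything on the trustee side of the hierarchy updates on the
investment before the repayment is chosen; everything on the investor side
updates when the repayment is revealed.  Zero total likelihood (possible
when discretized real data produce off-model actions) falls back to the
prior rather than failing.

## Action values and choice

The value of an action is its expected current-round utility under the
believed partner policy plus — except in the last round — the expectation,
over partner types and partner actions, of the best next-round expected
utility with all beliefs advanced by the same Bayes operator
(receding-horizon evaluation: the second step is immediate-only, matching
a two-round planning horizon).  The future term uses the *maximum* of
next-round values, not their softmax average: the recursion evaluates
optimal continuation, and stochasticity enters only at the choice layer.
Choices are softmax in the values with inverse temperature τ (units
1/dollar); τ = 0 is the uniform policy.  Simulated partners at every
nesting depth share the actor's τ — the model assumes players attribute
their own decision noise to others.  All expectations are exact
enumerations (no sampling).

Two implementations exist: the vectorized engine used everywhere, and a
plain-Python game-tree enumerator in the test suite; they agree to 1e-10
on every small game (≤2 rounds, ≤3 actions/side, ≤3 types, all levels and
roles, with per-branch belief updates).

## Fitting

Each player is scored by replaying the observed history: beliefs advance
on the true observations and each own action contributes
log softmax(τ·Q)[action].  The search is an exhaustive grid over
level {0,1,2} × guilt grid × noise grid (default τ ∈ {¼, ½, 1, 2, 4}),
with ties broken toward lower level, then lower guilt, then lower noise —
a pure grid makes ties and reproducibility exact.  The reference value is
the uniform policy: n·ln(1/5), i.e. −16.094 for ten investor choices.
Trustee rounds following a zero investment are excluded (no choice was
observable); an all-zero-investment history leaves the trustee
unidentifiable and is flagged as such.  Model comparison uses summed
log-likelihood without AIC/BIC correction: parameter counts are equal
across levels in this design.

## Interpersonal prediction errors

First-order: observed repayment ratio minus the belief-averaged modeled
expectation, conditioned on the round's actual investment, at repayment
reveal; undefined on zero-investment rounds.  Second-order: observed
investment ratio minus the nested trustee model's expectation of it, at
submission.  Errors are fractions internally; an output option scales by
100 (the percent-like scale on which high-minus-low contrasts land around
10–16).  Pooled within a depth-of-thought level, values are split into
quintiles by rank; quintiles 4–5 (strictly above the 60th percentile) form
the high group and quintiles 1–2 (at or below the 40th) the low group.
Tied blocks take the quintile of their smallest rank — conservative for
the high-vs-low contrast — and an all-equal input is wholly mid.  The
pooled (not per-subject) reading of the quintile split is implemented.
Event timing (reveal vs submission) is carried through exported tables;
no hemodynamic modeling of any kind is performed.

## RL comparison model

A model-free alternative: per-action values updated by a delta rule toward
the realized guilt utility of the round, Q(a) ← Q(a) + λ(u − Q(a)), and a
choice rule (1−b)·softmax(k·Q) + b·uniform.  The slope/lapse pair (k, b)
is this package's concrete realization of a choice-precision and
action-mixing parameterization; it represents the degenerate no-learning
optimum exactly (λ = 0 with symmetric initial values — or k = 0, or
b = 1 — is literally the uniform baseline).  Fitting is a grid over
λ × k × b × guilt with ties toward the smaller parameters.

## Synthetic cohorts

Each cohort draws investor levels from stated proportions (default
0.5/0.25/0.25) and guilt from a mixture over the grid (default
0.25/0.5/0.25 — most investors somewhat inequity-averse).  Healthy
trustees draw levels 0.5/0.25/0.25 and guilt 0.2/0.4/0.4 (cooperative
enough to repay); the *uncooperative* phenotype is a guilt-0, purely
myopic, near-greedy trustee who keeps whatever arrives — a behavioral
stand-in for partners who break cooperation, not a clinical model.  One
master seed spawns per-dyad substreams, so cohorts are reproducible and
individually re-simulable.

The generation noise default is τ = 0.5, calibrated so that level recovery
by the fitting grid is feasible but imperfect.  This calibration exposed a
real property of the model: at sharp noise (τ ≥ 2) the level-1 and level-2
partner models produce *identical* action distributions and the two levels
are exactly unidentifiable; only soft policies separate them, and even
then the mean log-likelihood gap between the level-1 and level-2 accounts
of a 10-round game is ~0.15 nats.  Level 0 versus the planning levels is
strongly identified (diagonal ≈ 0.95); the level-1/level-2 distinction is
third-order — the two nested trustee models differ only in how the modeled
trustee models the investor — and recovers at only ≈ 0.5–0.7.  Guilt
recovers within one grid step in ≈ 95% of dyads.  Readers should treat
level-1 vs level-2 labels on 10-round data as weakly determined.

What the generator does *not* emulate: human deviations from Bayesian
updating, round-to-round drift in preferences or attention, the personal
vs impersonal introduction manipulation (a group label only), and any
socio-economic covariates.  Passing tests therefore demonstrate internal
consistency of the analysis chain, not fidelity to human data.  One
visible consequence: simulated level-0 investors *learn* that cooperative
trustees repay and raise their offers, so their earnings deficit
(~0.35 SD) is milder than in human cohorts, and earnings contrasts at
n = 50/level are underpowered even though every directional ordering
(round-1 offers, totals, end-game decline of level-2 trajectories) holds.

## Problem sizes and runtime

Default experiment sizes were chosen to keep any full run on one CPU in
minutes: recovery uses 50 investors per level, model comparison and the
membership audit use a 100-dyad mixed cohort, cohort scripts mirror the
original group sizes (48 healthy / 55 uncooperative), and the chi-square
calibration uses 200 null replicates.  A single investor fit (45
candidate models × 10 rounds, exact enumeration throughout) takes well
under a second.

## Known limitations

* Levels above 2, continuous-type beliefs and a learnable envy parameter
  are out of scope by design.
* The exact level-0 likelihood, prior values and choice kernel of the
  original study are not public; the myopic terminator, uniform priors and
  the shared-τ softmax are documented substitutes, not reconstructions.
* Headline empirical numbers from the original 195-dyad cohort (mean
  maximal log-likelihood, level counts, Fisher p-values) depend on
  undeposited data and are reproduced only directionally on synthetic
  cohorts.
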