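# Methods

This note records the modelling assumptions, numerical choices and
calibration decisions behind `conseq`, and what the synthetic agents do and
do not establish about real behavior.

## Task generation

Episodes are generated from three parameters: horizon `n_H`, difficulty
`ΔS ∈ {0.01, 0.05, 0.1, 0.15, 0.2}` (constant within an episode) and gain
`G` (0.3 for horizon 1, 0.19 for horizon 2). The base mean is drawn
uniformly from `[n_H·G + ΔS_max/2, 1 − n_H·G − ΔS_max/2]` so that every
reachable stimulus along every choice path stays in `[0, 1]`; the bounds are
validated at configuration time and degenerate configurations (e.g.
`n_H = 2`, `G = 0.5`) are rejected. The default session is one 100-trial
horizon-0 block, two 100-trial horizon-1 blocks and three horizon-2 blocks
of 105, 105 and 90 trials (100 episodes per horizon). The screen side and
presentation order of the larger stimulus are independent fair coin flips
per trial, pre-sampled into the session plan so that a plan is bit-for-bit
replayable from its seed; both fields are logged so that exploratory
analyses of side- or order-based strategies remain possible later. ΔS is
drawn uniformly per episode; a fixed stimulus list shared across a cohort
can be exported (`SessionPlan.to_json`) and replayed.

## Neural layer

The two-population reduction is integrated with Euler–Maruyama at
`dt = 0.5 ms` from `r_L(0) = r_R(0) = 0`, with Gaussian increments scaled
by `σ√dt/τ`. Fixed biophysical constants: `F_max = 0.04 ms⁻¹`,
`θ = 0.015 ms⁻¹`, `k̃ = 0.022 ms⁻¹`, `ω₊ = 1.4`, `ω₋ = 1.5`. The decision
rule is a strict inequality `|r_L − r_R| > Δ` checked after every step; a
tie at exactly Δ does not trigger. Trials that do not cross by
`t_max = 4000 ms` (the task's response window) are recorded as
`no_decision` and excluded from RT-based analyses, mirroring the task's
error trials. All rates are ms⁻¹ internally; thresholds in Hz are converted
at the configuration boundary (25 Hz ↔ 0.025 ms⁻¹). Noiseless trajectories
converge first-order to a dense-step reference integration (tested).

Stimulus values map to drives through `λ = α + βs` with `α = −0.018`. With
that offset a strictly positive drive for every `s ∈ [0, 1]` is impossible
at the β values in use, so drives are floored at 0; trials whose stimuli
both fall below the floor are driven by noise alone and may time out. This
is the behavioral analogue of stimuli too dim to discriminate.

## Intention layer

The double-well process uses `τ_ψ = 10 ms`, Euler–Maruyama at `dt = 1 ms`,
basin classification at `|ψ − basin| ≤ eps = 0.02`, a state clamp at
`[−0.2, 1.2]` against noise-driven escape, and a 500 ms cutoff (unsettled
runs are classified by the nearest basin; they are rare because the drift
is strong away from the separatrix). A noiseless start exactly at the
separatrix `ψ0 = 0.5` is resolved by a single seeded fair coin flip.

The onset noise needs two regularizations the continuous form leaves open:
the singularity of a literal `1/t²` factor at `t = 0`, and its decay
timescale. We use `σ_ψ ξ(t) / (1 + t/2τ_ψ)²`: finite at onset, quadratic
decay, with the decay unfolding on the timescale of the process itself
(the linearized escape time from the separatrix is `τ_ψ`). Because the
noise is non-stationary and concentrated at onset, the *effective* kick a
trajectory receives also depends on the integration step; `dt = 1 ms`
(10 steps per `τ_ψ`) is part of the calibration, not merely an accuracy
setting. Two observable anchors fix this calibration: (i) from
`ψ0 = 0.45` with `σ_ψ = 0.4` roughly one in five trajectories escapes to
the far basin — a biased but not locked intention; (ii) initial biases in
the attainable band `[1/3, 2/3]` of the bias estimator must remain
probabilistic at the fitting value `σ_ψ = 0.6` (the stated purpose of
rescaling choice frequencies into that band is precisely to prevent
locking). A faster decay than `2τ_ψ` quenches the noise while the state is
still near the separatrix and effectively locks any bias beyond ±0.1,
which suppresses the decisional-uncertainty interpretation of `σ_ψ`.

## Strategy layer

`φ(E, T_E)` is updated once per episode per trial position (the batch and
per-trial formulations coincide because positions are disjoint within an
episode). Updates use the *intended* decision `ψ̃`, not the executed
choice, when perceptual noise makes them disagree — the update rule is
written in terms of the intention. `φ ∈ {0, 1}` are absorbing fixed points
and the update preserves `[0, 1]` for all parameter ranges in use
(property-tested); a clip guards pathological `k·R` products. `k = 0`
freezes the strategy. φ resets to `φ0` at every block boundary.

**Terminal-trial reward.** Between consecutive trials the subjective reward
is the observed mean shift `R = M(T_E+1) − M(T_E) = ±G`. The final trial of
an episode has no successor, so some convention is required. We define the
terminal signal symmetrically: magnitude `G`, sign positive iff the larger
stimulus was taken — at the last trial no future consequence remains, so
taking the larger container is exactly as "correct" there as the small
choice is earlier. This is the only within-episode signal of the available
candidates that drives `φ(last)` toward 1 within a 50-episode block at
learning rates near 0.4: the per-episode movement of φ is bounded by
`k·|R|·max φ²(1−φ)² = k·|R|/16`, and weaker candidates — chosen value minus
pair mean (`±ΔS/2`) or chosen minus foregone value (`±ΔS`) — move φ an
order of magnitude more slowly (both remain available via
`LearningParams.final_reward`). The same bound implies a hard limit worth
stating: with `k = 0.4`, `G = 0.3` and `φ0 = 0.5`, fifty updates cannot
carry φ past ≈ 0.21/0.79 (the continuum episode count from 0.5 to 0.2 is
`∫ dφ/(kG φ²(1−φ)²) ≈ 54 > 50`), so "φ converges to 0/1" within one block
is true as a trend, not as attained values.

## Behavioral metrics

PF is min–max normalized against the exhaustive enumeration of all
`2^(n_H+1)` choice paths of the episode. No-decision trials contribute zero
value (PF clamped to `[0, 1]` in that case), are excluded from P_oc and RT,
and do not advance the episode's mean chain (no choice exists to apply the
gain rule to). An episode counts as "optimal strategy employed" when every
trial's optimal-choice indicator is 1. For the learning time, episodes at
the hardest difficulty are excluded from the indicator stream when the
block contains more than one difficulty level (perceptual errors, not
strategy); `t_L` is the first episode that is itself optimal, with ≥9
optimal among the 10 episodes starting there (truncated end-of-block
windows require the same proportion, rounded up) and ≥75 % of the episodes
after that window optimal ("remaining" counts from the end of the window,
not from `t_L`). The index is reported in the original episode numbering of
its block, and the session-level `t_L` comes from the first block where the
criterion is met. Learning-group cut points (fast/medium/slow) are
configurable quantiles. VD defaults to the last 80 horizon-0 episodes,
hardest difficulty, decided trials only.

## Sequential fit

Step 1 fixes `σ = 0.001 ms⁻¹` and explores τ ∈ [25, 95] ms jointly with
`Δ = 2.57·10⁻⁴ τ + 0.0076` and β ∈ [0, 0.1] (α fixed). Each grid point
simulates a 100-trial horizon-0 block (the same pre-sampled stimuli across
points, for variance reduction) plus 500 dedicated hardest-difficulty
trials for VD, and is scored by `M̂ = KSD + 0.4·|VD_sim − VD_real|`. The
anticipation shift is estimated as `median(observed RT) − median(simulated
decision time)` per grid point and applied before the KSD. Ties break
toward the smaller (τ, β). Step 2 estimates `φ0 = (1 + f)/3` per trial
position from the first three complete episodes (the rescaling factor is
exposed but defaults to 3). Step 3 fixes `σ_ψ = 0.6`, sweeps
k ∈ [0, 2.5] (grid step 0.1 by default), runs 50 block simulations per k,
and minimizes `L + 0.1·I` where `L` is the absolute gap between the model's
mean learning time (not-learned runs imputed at block length + 1) and the
log's, and `I` the mean-square PF error over the first five episodes; the
grid argmin is reported without interpolation, ties toward smaller k.
Steps never revisit earlier estimates. Goodness of fit is the triple
`(1 − KSD, 1 − MSE(PF, first 5), 1 − |Δt_L|/n_episodes)`, clamped to
`[0, 1]`.

Default grid resolutions are τ step 2 ms, β step 0.005, k step 0.1; the
recovery harness uses coarser grids (τ step 5, β step 0.01, k step 0.25),
fewer Monte-Carlo repetitions (15–20 per k, 150–200 VD runs) and 300
simulated RT trials per grid point — the larger simulated RT sample
reduces the sampling floor of the two-sample KSD (~0.17 for 100-vs-100),
which otherwise dominates the τ objective.

## Parameter recovery: what it shows and its structural limit

`parameter_recovery` draws agents with τ ~ U(30, 90), β ~ U(0.03, 0.09),
k ~ U(0.2, 2.4), `φ0 = 0.5`, `σ = 0.001`, `σ_ψ = 0.6`, thresholds on the
τ–Δ line; simulates a 100-trial horizon-0 block plus a 50-episode
horizon-1 block per agent; and refits each log with the full three-step
pipeline.

The pipeline recovers τ and β well and k over most of its range, but k
recovery has a structural ceiling that users should understand. The bias
estimator reads the first three episodes; an agent with large k has often
*already learned* by episode 2–3, so the estimator absorbs the learned
policy into `φ0_hat ≈ (1/3, 2/3)`. Seeded at that bias, even a `k = 0`
model plays near-optimally (the 9-of-10 learning criterion passes at
per-episode success ≈ 0.9), so the learning-time objective barely
distinguishes learning rates for the fastest learners — the same
k/`φ0` confounding that appears when fitting real behavior (two logs
differing only in initial bias can yield similar k with different learning
times). The confound is a property of the sequential method at these task
parameters, not of its implementation; correlations between true and
recovered k are therefore high over the lower and middle range and
attenuate at the top.

## Synthetic agents vs. real participants

The generator reproduces the study conditions (session layout, difficulty
levels, gains, response window) and the model's own behavioral repertoire.
It does not emulate fatigue or attention lapses, motor execution and
mouse kinematics, response anticipation beyond a constant RT shift,
inter-block transfer of strategy (φ resets per block), or subjective
reward functions differing between individuals. Passing tests therefore
show internal consistency of the model–metric–fit loop and its qualitative
agreement with the published behavioral effect directions, not that human
data would be fit with any particular accuracy.

## Problem sizes

Test and validation runs use reduced problem sizes chosen to keep the full
suite fast while leaving the statistics decisive: 4-point parameter grids
with 20 repetitions per cell for trend checks, 30 seeded blocks for the
example-regime check, 20 agents at the coarse grids for recovery, and the
sequential fit's Monte-Carlo repetitions reduced as listed above. Library
defaults remain at the full resolutions.
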