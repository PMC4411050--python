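# Methods

## The data model

The unit of analysis is a simple directed graph over surveyed
individuals ("ego nominates alter"), with four node attributes: a
prosociality score (the mean of eight 5-point Likert items, hence a
multiple of 1/8 in [1, 5]), binary sex, a household-income band (1–5)
and a father's-education band (1–9). Income band 6 ("unable to
answer") is treated as missing: it is a non-numeric category that
cannot enter linear covariate terms. All model terms are complete-case
— a term touching a node with a missing attribute raises rather than
silently dropping dyads. Nominations of ids absent from the attribute
table (non-participants) are dropped with a logged count by default;
an `on_unknown="error"` mode turns them into load errors naming the
file row. Self-loops are always rejected; duplicate nominations
collapse to one tie with a warning.

## Mixing-matrix test

Nodes are dichotomized at a threshold (default: the median score 3).
The strict rule puts scores **above** the threshold in the "more"
group; because published analyses do not always state which side ties
fell on, the rule is a switch (`>` vs `>=`), and the CLI can assert an
expected split so a wrong switch fails loudly instead of silently
shifting group sizes.

Observed directed tie counts O(g, h) are cross-tabulated by ego group
g and alter group h. Expected counts under proportionate mixing are
E(g, h) = p_g p_h m with p_g the exact node share of group g and m the
total tie count; printed shares like 0.483/0.517 are treated as
rounded displays of 115/238 and 123/238. The Pearson statistic is
X² = Σ (O−E)²/E over the four cells.

**Degrees of freedom.** Because the group shares are known from the
node roster (no margins are fitted to the tie table), the large-sample
null reference for X² is the 3-df multinomial chi-square. The 1-df
convention familiar from 2x2 contingency tables with fitted margins is
nevertheless the one used in the published analysis this package
replicates, so `chi_square_test(df=...)` defaults to `df=1` and every
report carries a note that the expected counts derive from node-share
proportions. Under label-independent random ties, simulation confirms
the df=3 reference rejects at the nominal 5% rate while df=1 rejects
at ~30%; the calibration test in the suite therefore uses df=3. The
statistic itself is identical either way.

## ERGM terms

With A the adjacency matrix (A_ij = 1 for tie i→j) and x an attribute:

| term | statistic |
|---|---|
| `edges` | Σ A_ij |
| `nodematch(x)` | Σ A_ij 1[x_i = x_j] |
| `nodeocov(x)` / `nodeicov(x)` | Σ A_ij x_i, Σ A_ij x_j |
| `absdiff(x)` | Σ A_ij \|x_i − x_j\| |
| `edgecov(M)` | Σ A_ij M_ij |
| `odegree0` | #{i : out-degree(i) = 0} |
| `gwesp(α)` | e^α Σ_{k≥1} [1 − (1 − e^{−α})^k] EP_k |

EP_k is the number of ties with exactly k shared partners. For the
sqrt-product covariate M_ij = √(x_i x_j): it grows with either actor's
score but fastest when both are high, and the square root keeps it on
the attribute's own 1–5 scale, so its coefficient reads like the other
per-unit effects.

**gwesp decay α.** Published fits rarely state α, yet coefficients are
not comparable across decays, so α is an explicit configuration value
(default 0.25) echoed in every fit report, and the acceptance script
treats it as a sensitivity sweep rather than pretending a known value.
α is fixed during estimation (no curved-ERGM fitting of α).

**Shared-partner orientation.** On directed graphs "shared partner"
is ambiguous. The default is *transitive* (k is a shared partner of
i→j when i→k and k→j), matching the friend-of-a-friend closure
mechanism; *cyclic* (j→k, k→i) and *any* (k adjacent to both ends in
either direction) are selectable. The goodness-of-fit ESP distribution
follows the orientation of the fitted gwesp term.

**Change statistics.** Every term has a local toggle delta
g(y+ij) − g(y−ij) computed from the dyad's neighborhoods, never by a
full recount. For gwesp, writing r = 1 − e^{−α} and w(k) =
e^α(1 − r^k), adding i→j contributes w(sp(i,j)) for the new tie plus
r^k for each existing tie whose shared-partner count k rises by one
because the new tie completes a two-path for it (each affected tie
gains at most one partner per toggle; the affected sets for the three
orientations are enumerated in `_kernel.py`). The test suite verifies
exact agreement with brute-force recounts on hundreds of random
instances across all orientations.

## Sampling and estimation

**Sample space.** The survey capped nominations at seven, so the
models restrict the sample space to graphs with out-degree ≤ 7. The
Metropolis–Hastings sampler rejects, at the proposal stage, any
toggle-on that would breach the cap; since the target density is zero
outside the constrained space, this yields the ERGM restricted to it.

**Proposal.** The default is tie/no-tie (TNT): with probability 1/2
toggle a uniformly chosen existing tie, otherwise a uniform ordered
dyad, with the exact Hastings correction (including the edge cases of
an empty graph). TNT mixes far better on sparse networks — the
study-like regime has density ≈ 0.015. A plain uniform-dyad proposal
is retained for correctness checks; both are validated against exact
enumeration of all 64 directed graphs on three nodes (chi-square
screen over ~10⁵ retained draws, with and without the constraint).
The inner loop (toggle bookkeeping, gwesp deltas, running statistics)
is numba-compiled; throughput is a few million toggles per second.

**MPLE.** Logistic regression (IRLS via statsmodels) of tie indicators
on toggle deltas over all non-self dyads. Dyads whose toggle-on would
violate the out-degree cap are excluded — a conditioning approximation
to the exact constrained likelihood. MPLE is the exact MLE for
dyad-independent models and the initializer otherwise. Separation is
detected and reported with the most plausibly separating term.

**MCMC-MLE.** Geyer–Thompson iteration: simulate at θ₀, maximize the
importance-sampled log-likelihood ratio l(θ) − l(θ₀) = (θ−θ₀)ᵀg(y_obs)
− log mean exp((θ−θ₀)ᵀ g(Y)) by Newton–Raphson with step-halving, and
move θ₀. Steps are rejected (and the chain resampled) if the
importance weights' effective sample size falls below a floor (default
100). Iteration stops when the estimated gain drops below
`tol + T/(2 N_eff)`: the maximized gain estimate is itself biased
upward by about T/(2 N_eff) (the noise of a fitted T-dimensional
quadratic), where N_eff is the smaller of the weight ESS and the
batch-means effective draw count of the chain, so demanding less than
that floor would never terminate. Standard errors come from the
inverse covariance of simulated statistics at the final θ (the Fisher
information of an exponential family), estimated from a fresh sample
that also feeds the moment-matching diagnostic: at a trustworthy fit,
mean simulated statistics sit within ~3 Monte-Carlo SEs of the
observed ones (reported as `moment_z`). p-values are two-sided normal
on estimate/SE.

**Exact oracle.** For n ≤ 5 the full state space (2^{n(n−1)} graphs)
is enumerated in Gray-code order — each move is a single toggle handled
by change statistics — giving exact probabilities, the exact MLE
(Newton on the true log-likelihood) and exact information-based SEs.
This is the anchor for the sampler-frequency and MCMC-MLE agreement
tests; it refuses n > 5.

**Defaults.** burn-in 10⁵ toggles, sampling interval 10³, 10⁴ retained
draws, tolerance 10⁻⁴, at most 20 outer iterations — all configurable.
Tests and the acceptance script scale these to their problem sizes
(e.g. interval ~3000 and ~2500 draws for a 238-node fit; millions of
draws for the three-decimal n = 4 oracle comparison); the chosen sizes
are stated in each call.

## Goodness-of-fit

100 replicate networks (by default) are simulated from the fitted
model — retained draws of one chain started at the observed network —
and four distributions are compared as proportions: in-degree and
out-degree (per node), edgewise shared partners (per tie, fitted
orientation), and directed geodesic distance (per ordered pair, BFS,
with an "NR" bucket for unreachable pairs). Output is a quantile
envelope (min, 2.5%, median, 97.5%, max) per value bucket, a CSV table
and a panel plot with the observed curve drawn over the envelope.
Degree/ESP axes are truncated at the pooled 99.5th percentile to keep
tables finite. No formal GOF p-value is computed — the comparison is
deliberately visual/tabular, and a model may legitimately fail to match
higher-order distributions (geodesics, ESP) that were not its focus.

## Synthetic data

The generator emulates the regime the analysis targets, so every stage
is testable without access to any restricted survey data:

- **Prosociality**: mean of eight iid Likert draws. The default item
  distribution over {1..5} is (0.3289, 0.05, 0.1956, 0.05, 0.3754),
  solved so the *score* has mean 3.093 and SD 0.603 exactly in
  expectation (item variance is 8x the score variance for an 8-item
  mean), with 5% pinned on each middle response so all five occur.
  Real Likert items are typically unimodal; this solution trades shape
  realism for exact moment control, which is what the tests consume.
- **Sex**: Bernoulli with female share 137/238. **Income/education**:
  fixed band distributions (documented in `synth.py`) — plausible
  shapes, not estimates; the analysis only requires complete bands.
- **Network**: one draw from the study-like 7-term model (sex
  nodematch 3.808 and prosociality sqrt-product 0.211 — the published
  point estimates, planted so recovery checks have known truth; income
  −0.002 and education −0.045 likewise; edges −7.75, odegree0 2.6 and
  gwesp(0.25) 0.85 calibrated once so draws land near the observed
  descriptives: ~830 ties on 238 nodes, mean out-degree ~3.5, ~50
  zero-out-degree nodes, out-degree ≤ 7). Dyad-independent,
  unconstrained truths are drawn directly per dyad (closed form); the
  two generation paths are cross-validated against each other in the
  suite. Near-empty or near-complete draws raise a degeneracy error
  advising coefficient adjustment.

What passing recovery tests show: the estimators recover planted
coefficients with honest coverage *in this regime* (sparse, strong
homophily, capped out-degree, moderate closure). What they do not
show: robustness to attribute distributions unlike the generator's,
to missing-data mechanisms, or to model misspecification — real
friendship data carries joint attribute structure the generator does
not attempt.

## Numerical and design notes

- Dichotomization ties go down (`>` rule) by default; the switch and
  the CLI's expected-split assertion make the alternative explicit.
- Expected mixing counts always use exact node-share fractions.
- The MPLE design excludes only *absent* dyads at the out-degree cap;
  present ties stay (their toggle-off state is always feasible).
- Newton solves add a tiny ridge (1e−10–1e−12) before inversion;
  singular information falls back to pseudo-inverse.
- An exact MLE whose Newton iterates diverge (‖θ‖ > 60) is reported as
  separation: the observed statistics lie on the convex-hull boundary.
- Seeded determinism: every stochastic entry point takes a seed;
  sub-seeds are derived via `SeedSequence` so identical seeds
  reproduce samples, fits and recovery tables bit-for-bit.
- Significance labeling is left to the reader: raw p-values are
  reported without star thresholds.

## Known limitations

- MCMC-MLE standard errors ignore MPLE-start bias and Monte-Carlo
  error in θ itself; with short chains they can be mildly optimistic.
- The constrained MPLE's dyad exclusion is an approximation; no claim
  is made that it equals the exact constrained pseudo-likelihood.
- The exact oracle is limited to n ≤ 5 (n = 5 takes tens of seconds).
- `gwesp` with very large coefficients can place the sampler in a
  near-degenerate region; the degeneracy guards report rather than
  repair this.
- The mixing test is deliberately 2x2; richer trait scales belong to
  the ERGM path.
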