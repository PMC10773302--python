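# Methods

## Model

A population of fixed size N is represented as a symmetric N×N matrix
with entries in {−1, 0, +1}: association, no relationship, avoidance.
Self-ties are undefined (diagonal stored as 0). At time zero each
unordered pair is independently assigned +1 with probability
`p_assoc_init`, −1 with `p_avoid_init`, and 0 otherwise (defaults
0.1/0.1/0.8, the calibration of the reference design).

Each time step consists of exactly one death and one birth, in that
order: a uniformly sampled individual dies, its row and column are
cleared, a mother is sampled uniformly from the N−1 survivors, and her
offspring takes the freed matrix slot with a fresh identity in the
individual-id ledger. Clearing the deceased's ties **before** the mother
is read guarantees a newborn can never hold a tie to a dead individual;
the order of the two events within a step is a modelling choice (only
their per-step rates are constrained), and death-first additionally
guarantees the mother is alive. The mother and offspring always
associate.

### Inheritance mechanisms

Write r(m, x) for the mother's relation to a third party x and let the
offspring's tie be drawn per third party, in ascending slot order:

* **one_step** — r = +1: offspring tie +1 with probability Pn, else 0;
  r = −1: tie −1 with probability Pa, else 0; r = 0: tie +1 with
  probability Pr, −1 with Pr, 0 with 1 − 2·Pr. Individuals whose
  maternal tie failed to copy stay at 0 — they are *not* eligible for
  the Pr lottery, which is restricted to individuals unconnected to the
  mother. The three outcome probabilities sum to one in every row of
  this rule table (unit-tested).
* **two_step** — step one applies the one-step rule restricted to the
  mother's associates and avoidances (no random ties). Step two takes a
  snapshot of the post-step-one state: every individual still untied to
  the offspring is classified against the offspring's associate set
  (mother included). Under the default **count** rule a candidate with p
  positive and q negative ties to that set is a *potential associate* if
  p > q (adopted +1 with probability Pn), a *potential avoidance* if
  q ≥ p and p + q > 0 (adopted −1 with Pa), and *neutral* if p = q = 0
  (random tie via Pr as above). The alternative **fraction** rule
  (config switch `classification_rule="fraction"`) instead thresholds on
  the fraction of the associate set (> 50% positive / ≥ 50% negative);
  it leaves a gap class of nonzero-tied candidates that clear neither
  threshold, which form no tie. The count rule is the default because it
  is exhaustive and matches the canonical worked example. Because step
  two uses a single snapshot, adoptions made during step two do not feed
  back into classification; a sequential re-evaluating mode would be
  order-dependent in a way nothing in the model motivates.
* **random_associates** — a control in which maternal inheritance is
  zero: each third party becomes an associate independently with
  probability deg⁺(mother)/(N−2) (matching the mother's associate degree
  in expectation; override with `random_assoc_prob`), the mother tie is
  added, and avoidances are then adopted with probability Pa from
  candidates classified as potential avoidances **against the drawn
  associate set only** — including the mother there would smuggle
  maternal inheritance back in. No Pr random ties are formed, so this
  variant isolates the effect of the inheritance pathway itself.

### Parameters

| name | meaning | range | default |
| --- | --- | --- | --- |
| Pn | fidelity of inheriting an associate | [0, 1] | 0.5 |
| Pa | fidelity of inheriting an avoidance | [0, 1] | 0.5 |
| Pr | probability of each sign of random new tie | [0, 0.5] | 0.01 |
| N | population size | ≥ 2 | 50 |
| timesteps | birth–death steps per replicate | ≥ 0 | 1000 |

Pr is capped at 0.5 because the stay-null probability is 1 − 2·Pr. The
reference factorial design crosses Pa ∈ {0, 0.1, …, 0.8}, Pn ∈ {0.3, …,
0.8} and Pr ∈ {0.001, 0.01, 0.05}: 162 parameter sets, 100 replicates of
1000 steps each, chosen to span the inheritance fidelities observed in
empirical systems; 1000 steps (20 population turnovers at N = 50) lets
the structure metrics stabilize.

## Metrics

All structure metrics are computed on the association subnetwork (+1
ties only); avoidances are therefore invisible to them, which is the
crux of the phenomenon under study. Per recorded step:

* association and avoidance counts over unordered pairs (never
  double-counted) and density = associations / C(N, 2);
* global clustering as **weak transitivity**: 3 × triangles / connected
  triples. When the graph has no connected two-paths the ratio is
  undefined and recorded as NaN; aggregation drops NaNs and reports how
  many were dropped, rather than silently biasing means with an
  arbitrary zero;
* **modularity** of the partition found by walktrap community detection
  (random-walk agglomerative clustering, walk length 4 — the
  conventional default, exposed as `walktrap_steps` — cut at the
  maximum-modularity merge). The reported Q is computed by the package's
  own Newman–Girvan implementation, Q = Σ_c [e_c/m − (d_c/2m)²]; the
  graph library's modularity serves as an independent cross-check in the
  tests (agreement to 1e-10). An edgeless network is defined to have
  Q = 0 with every node its own community — a continuous-at-empty
  convention;
* a **signed triad census** over node triples whose three ties are all
  nonzero, split into +++, ++−, +−−, −−− (the middle two being the
  structurally unstable classes), computed with adjacency-matrix
  products and verified against exhaustive triple enumeration.

## Randomness and reproducibility

One `numpy` Generator per replicate drives everything in a fixed
documented order — death draw, mother draw, then tie draws in ascending
slot order — so a replicate is a pure function of (parameters, seed).
Sweep replicate seeds derive from
`SeedSequence((base_seed, set_index, replicate_index))`, which is stable
across platforms and makes the whole experiment a pure function of the
grid definition. Walktrap itself is deterministic.

## Trend classification

The sweep's qualitative claims ("Pn decreases modularity", "Pa has no
effect in the one-step model") are made precise with a pre-registered
rule: for each curve (one swept parameter, all other parameters fixed)
the Spearman rank correlation ρ between the swept values and the
per-set means is computed; |ρ| ≥ 0.7 over at least three sweep points is
classified increasing/decreasing by sign, anything weaker is flat. Rank
correlation is used because the claims are directional, not linear.

## What the tests do and do not show

The test suite verifies the simulator at a reduced scale — 20 replicates
of 500 steps at N = 50, sub-grids around the parameter regions where each
effect is expressed (e.g. the Pa effect on two-step modularity at
intermediate Pn, where the association network is neither saturated nor
empty) — with a fixed base seed. Passing shows the implemented mechanisms
reproduce the expected directions under those conditions; it does not
show effect sizes at the full 162-set × 100-replicate scale, which the
`sweep` command can run but the default suite does not, and it says
nothing about real animal populations: the generator assumes a closed
population, uniform mortality and fertility, no demographic structure,
ties formed only at birth and never rewired, and undirected, unweighted,
exactly tri-valued relationships.

## Known limitations

* Flatness tests inherit the usual fragility of accepting a null: a rank
  correlation on few points has nontrivial variance under a true null,
  and the |ρ| ≥ 0.7 threshold trades some false-flat risk against it.
* The two-step classification treats the associate set as unweighted;
  an individual associated with many of the offspring's associates is
  classified the same as one barely past the majority.
* "Stabilization" at 1000 steps is a design constant, not re-verified
  per run; the per-step trace CSV and the optional burn-in config field
  let users inspect or trim transients themselves.
* Under the random-associates control avoidances have no random source
  (no Pr) and decay to extinction once their carriers die, which is the
  intended behaviour of the control but means long runs of that variant
  say little about avoidance dynamics.
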