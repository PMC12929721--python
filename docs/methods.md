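# Methods

This note documents the model implemented by `socstruct`, the concrete
functional forms and parameter defaults it commits to, the numerical and
design choices that were genuinely open, and what the synthetic tests do and
do not establish.

## Structure representation

A social structure over an ordered agent set is a partition into nonempty
clusters plus typed inter-cluster edges.  `authority` and `mentorship`
edges are directed (superior → subordinate; mentor → mentee) and each
type's edge set must be acyclic — both relations are hierarchies, and a
cyclic "pecking order" is not a coherent one.  `friendship` is encoded
solely as cluster self-loops: a cluster with a loop is a clique whose
members are mutual friends; a cluster without one is just a role grouping.
Agents sharing a cluster are peers for every relation type (distance 0);
there are no within-cluster directed relations and at most one edge per
type per ordered cluster pair.

Cluster labels carry no meaning, so all aggregation goes through a
canonical form: members sorted by agent order within clusters, clusters
ordered by their smallest member.  Relation queries (`manager_of`,
`mentor_of`) read a *direct* inter-cluster edge by default; the transitive
reading ("anywhere above") is available via a flag but is not the default,
because the queries model immediate relationships ("is i j's manager"), not
reachability.

## Prior

The partition prior is a CRP with concentration α = 3, whose closed form is
the exchangeable partition probability function

    P(partition) = α^K · Π_k (n_k − 1)! / (α (α+1) ⋯ (α+n−1)).

Sampling uses a stick-breaking construction truncated at 50 components; at
α = 3 the expected unassigned stick mass is (α/(α+1))^50 ≈ 6·10⁻⁷, and the
sampler logs a warning if the realized leftover ever exceeds 10⁻⁴.
Exchangeability is enforced by testing (sampler frequencies vs. the EPPF by
chi-square), not by construction, since stick-breaking assigns labels.

Conditional on the partition, each unordered pair of distinct clusters
carries an edge with probability 0.5 per directed type, with direction
uniform given existence.  This decomposition (rather than independent
Bernoulli per *ordered* pair) keeps the no-edge mass at 0.5 per pair, which
is the natural reading of "probability 0.5 of an edge existing between each
pair of groups".  Friendship contributes an independent Bernoulli(0.5)
self-loop per cluster.  Cyclic directed configurations are handled by
rejection (log-prior −∞) rather than by renormalizing over DAGs: MH and the
enumeration oracle only ever need the unnormalized density, and rejection
composes correctly with incremental edge proposals.

## Interaction likelihoods

Each interaction factors into initiator, recipient and response stages.
The qualitative content of each stage is fixed by the intuitive theory the
model formalizes; the concrete forms below are this package's canonical
instantiation, kept behind the `stage_distributions` interface so they can
be swapped without touching inference.

**Authority / orders** — initiator weight `1 + n_subordinates(i)`;
recipient weight `(1 − β_down)^(d−1)` for a subordinate at hierarchy
distance d, `eps_up · (1 − β_up)^(d−1)` for a superior, `eps_lat` for peers
and unrelated agents; acceptance probability `β_pos` when the initiator is
strictly above the recipient, else `1 − β_pos`.  At β_down → 1 orders go
only to direct subordinates; at β_down → 0 all subordinates are equally
likely.

**Friendship / invitations** — initiator weight
`(1 + max(clique_size − 1, 0))^β_init`; recipient weight `β_high` within
the initiator's clique, `β_low` otherwise; acceptance
`β_high / (β_high + β_low)` within the clique, `β_low / (β_high + β_low)`
across.  At β_high = β_low the model is clique-blind and recipients are
uniform (this boundary is deliberately allowed by the parameter
validation).

**Mentorship / advice requests** — initiator weight
`β_request + (1 − β_request)·u` with u = 1 for mentor-having, mentee-less
agents, 0 for the reverse, and 0.5 for agents with both or neither (the
extremes are fixed by the theory; the midpoint is a documented
interpolation); recipient weight `β_recip · dist_discount^(d−1)` for a
mentor-side ancestor at distance d, `1 − β_recip` for a peer, `eps_m`
otherwise; acceptance `β_pos` for requests flowing up or laterally, else
`1 − β_pos`.

Every agent always has positive initiator and recipient weight, so all 120
single-step outcomes (5 agents, 3 types, 2 responses) have positive
likelihood under every structure and no observed sequence has empty
posterior support.  Interactions are conditionally independent given the
structure, so sequence log-likelihoods are order-invariant sums.

### Parameter defaults and why

| parameter | default | role |
|---|---|---|
| authority β_down | 0.8 | hierarchy strictness downward |
| authority β_up | 0.9 | strictness for (rare) upward orders |
| authority β_pos | 0.8 | social cost of refusing a superior |
| authority eps_up | 0.1 | baseline weight, upward recipients |
| authority eps_lat | 0.1 | baseline weight, peer/unrelated recipients |
| friendship β_init | 1.0 | clique-size effect on initiation |
| friendship β_high / β_low | 0.9 / 0.1 | cliquishness |
| mentorship β_request | 0.3 | flattens mentee-over-mentor initiation |
| mentorship β_recip | 0.7 | preference for mentors over peers |
| mentorship β_pos | 0.8 | cost of refusing a mentee/peer |
| mentorship dist_discount | 0.1 | decay per extra step toward distant mentors |
| mentorship eps_m | 0.1 | baseline for downstream/unrelated targets |

The β values are nominal working defaults, exposed in the configuration
file and replaceable by `fit_parameters_mle` when calibration data are
available.  Two defaults deserve their rationale spelled out:

* **eps_lat = eps_up = 0.1.**  The theory requires subordinates to be more
  likely order recipients than peers.  With β_down = 0.8 a distance-2
  subordinate has weight 0.2, so any peer baseline above 0.2 would invert
  that ordering for all but direct subordinates; 0.1 keeps peers below
  subordinates to depth 2 while leaving peer and upward orders "unlikely
  but possible".
* **dist_discount = 0.1.**  Advice requests should target direct mentors or
  peers.  The peer weight is 1 − β_recip = 0.3; a mentor-of-a-mentor must
  stay below it not only pointwise (β_recip · dist_discount = 0.07) but
  after posterior averaging, where structures containing incidental direct
  mentor edges contribute the full β_recip weight.  An exhaustive-posterior
  scan over the five-agent delegation example showed the sharp decay (0.1)
  yields the intended peer-over-distant-mentor prediction robustly across
  β_recip ∈ {0.5, 0.6, 0.7}, while milder decays do not.

## Posterior inference

`exhaustive_posterior` normalizes prior × likelihood over every canonical
structure, enumerated as set partitions × acyclic edge orientations ×
self-loop subsets.  It is exact and is the oracle for all sampler tests,
but the space grows super-exponentially (715 authority structures at 4
agents; ≈35 000 at 5), so it is guarded by a `max_agents` limit.

`mh_posterior` runs Metropolis–Hastings over (partition, typed edges).
Each sweep first reassigns every agent in random order: the proposal joins
an existing cluster with probability proportional to its size (excluding
the agent) or opens a new cluster with probability proportional to α, and a
newly opened cluster draws its incident edges from the edge prior.  Because
the assignment proposal is exactly the CRP predictive and new edges are
drawn from their prior, the prior factors cancel and the acceptance ratio
reduces to the likelihood ratio; proposals that would create a directed
cycle have zero prior mass and are rejected outright.  The sweep then
resamples every typed cluster pair and friendship self-loop independently
from the prior's edge states, again accepting by likelihood ratio.  The
default budget is 60 000 post-burn-in sweeps after 5 000 burn-in sweeps
(thinning 1); sequence likelihoods are cached per canonical structure, so a
run costs seconds at the study's scale of 3–5 agents.  Per-agent
reassignment is an MH proposal, not a full Gibbs scan — at these state
spaces the difference is immaterial and the proposal-correction algebra is
simpler.

Posterior mass is reported over visited canonical structures only;
unvisited structures have estimated probability 0.  This is an
approximation property of the sampler (the exact oracle is available at
small n).  Ranked summaries break probability ties by the canonical form's
lexicographic order, so outputs are deterministic given the seed.

## Prediction, influence and baselines

Next-interaction prediction marginalizes the recipient stage over the
posterior and renormalizes over the stated candidate set.  An absent agent
is treated as unavailable, not as removed from the structure: absence
conditions the prediction but does not change the inference.  The
renormalization happens after marginalizing (conditioning the mixture); the
per-structure-renormalization alternative is exposed as a flag.  Influence
queries map decision domains to relations (extra shift → manager, movie →
friend, optional class → mentor) and report unnormalized posterior relation
marginals.

The frequency baseline is deliberately asymmetric between its two uses:
next-interaction weights count undirected pair co-occurrence, while
influence counts directed initiator→decider events — each mirrors the
statistic its task exposes.  Unobserved pairs take the uniform-prior mean
0.5 by default (`mode="expected"`, deterministic); `mode="sampled"` draws
Uniform(0,1) per unobserved pair under the given seed.

## Stimuli and trial selection

Random sequences are uniform over the per-step outcome space (120 outcomes
at 5 agents with all types).  Informativeness filters discard sequences
with any interaction tuple repeated more than twice, more than one
uninvolved agent, or a rejection count outside {1, 2}.  In mixed-type
sequences the repeat-rule tuple includes the interaction type (for
single-type sequences both readings coincide); mixed-type generation can
additionally require every type to appear.

Structure-inference trials are classified by their top-4 posterior
probabilities into profiles using three thresholds (high ≥ 0.6; moderate
strictly between 0.15 and 0.6; improbable < 0.1; values in [0.1, 0.15] are
borderline): `one_high` = 1 high + 3 improbable, `high_and_moderate` =
1 + 1 + 2, `two_high` = 2 moderate + 2 improbable, `three_moderate` =
3 moderate + 1 non-probable (≤ 0.15).  The patterns are mutually exclusive
by their count signatures.  The numeric thresholds are package choices,
config-exposed.  Prediction trials are instead selected by the sum-squared
divergence between two models' aligned prediction vectors, descending, with
pool-index tie-breaks.

## Judgment analysis and synthetic respondents

Likert studies are z-scored within participant across all their responses
(sample SD, n−1; the population convention is available via `ddof=0`) and
averaged per item; slider studies are normalized per participant and trial
to probability distributions before averaging.  Zero-variance groups raise
a named error rather than propagating NaNs; an all-zero slider trial falls
back to uniform with a warning.  Model contrasts use percentile bootstrap
CIs over the difference in Pearson correlation, resampling participants
(the unit the preprocessing is organized around), significant when the 95%
interval lies entirely above zero.

The synthetic respondent model maps predictions to the response scale
(slider: 100·p clipped to [0, 100]; Likert: min-max within trial onto 1–7,
rounded) and adds Gaussian noise on that latent scale per participant and
item.  It emulates the *shape* of behavioral judgment tables — independent
raters, bounded discretized scales, response noise — but none of the
systematic features of real raters (anchoring, individual response styles,
attention lapses, correlated errors).  Passing end-to-end tests therefore
establishes that the pipeline is self-consistent — that the analysis
recovers the generating model from data shaped like the experiments' — not
that human judgments match the model.

## Problem sizes used by the test suite and acceptance script

Exact prior checks enumerate all partitions up to n = 7 (877 terms);
sampler goodness-of-fit uses 100 000 stick-breaking draws.  Sampler-vs-
oracle agreement runs ten filtered length-6 sequences at 3–4 agents under
all three sociology readings at the full 60 000 + 5 000 budget and requires
total-variation distance < 0.05.  Structure recovery simulates 100
interactions from a fixed 4-agent structure per sociology and requires MAP
recovery in ≥ 80% of 20 seeded replicates (exact posteriors).  The
delegation contrast runs the five-agent example at the full budget.  The
end-to-end study uses 12 candidate stimuli, 4 selected trials, 20 synthetic
participants at slider noise SD 2, reduced sampling (8 000 + 800), and
2 000 bootstrap replicates.

## Known limitations

* The stage equations are one coherent parameterization of the intuitive
  theory's constraints; other forms satisfying the same orderings exist and
  would shift quantitative (not qualitative) predictions.
* The MH sampler's support-only reporting underestimates the tail of very
  flat posteriors (many structures, few observations); use the exhaustive
  oracle when exactness at small n matters.
* No modeling of time: interactions are exchangeable given the structure,
  so the model cannot express structures that change mid-sequence.
* Influence scores are unnormalized probabilities; they are comparable
  across agents within a query, not across queries.
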