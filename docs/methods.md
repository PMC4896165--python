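# Methods

`profilegraph` implements a two-stage Bayesian analysis of dependence among
categorical variables: (1) Dirichlet-process (DP) profile clustering of
subjects with cluster-specific variable selection, and (2) reversible-jump
MCMC over graphical log-linear models, with the clustering output
translated into an edge-evidence matrix that both screens covariates and
informs the model-search proposals.  This note records the models, the
defaults, the numerical choices and the limitations.

## Stage 1: DP mixture of product multinomials with selection switches

Each subject i carries a profile x_i = (x_i1, ..., x_iP) of categorical
covariates, covariate p having M_p levels.  Conditional on an allocation
z_i = c, covariates are independent multinomials with cluster-specific
probabilities phi_pc.  Allocation weights follow a truncated stick-breaking
construction psi_c = V_c prod_{l<c} (1 - V_l), V_c ~ Beta(1, alpha), with
the final stick pinned at V_C = 1 so the weights sum to one and every Gibbs
conditional is exact (Ishwaran-James blocked sampler).  The truncation
grows adaptively (by 5, up to `max_truncation`) whenever the last cluster
becomes occupied; the default initial truncation is 50.

Cluster-specific binary switches gamma_pc decide whether covariate p
informs cluster c:

    P(x_p = x | z_i = c) = phi_pc(x)^gamma_pc * pi_p(x)^(1 - gamma_pc),

where pi_p is the sample-wide marginal of covariate p, held fixed at the
observed frequencies for the whole run.  Switches are Bernoulli(rho_p) with
a spike-and-slab prior on the selection probability:
rho_p = 0 when w_p = 0, rho_p ~ Beta(a_rho, b_rho) when w_p = 1,
w_p ~ Bernoulli(0.5).  The point mass forces a crisp separation between
covariates that drive the clustering and covariates that do not.

Hyperparameter defaults: lambda = 0.5 for the Dirichlet prior on each
phi_pc row; a_rho = b_rho = 1 (the Beta slab is otherwise unspecified in
the literature this follows, so the flat choice is used and configurable);
alpha ~ Gamma(2, 1), resampled by conjugacy from the stick variables.
Chains start from a random allocation into 10 groups, gamma = 1,
rho = 0.5.  A seed is mandatory; a seeded run is reproducible bit for bit.

One design point deserves emphasis: switches are defined for every cluster
up to the truncation, occupied or not, and the conditional for (w_p,
rho_p) counts all C clusters.  Empty clusters carry no data, so their
switches are free Bernoulli(rho_p) draws that integrate out of rho_p's
marginal posterior exactly; keeping them in the state makes every
conditional the exact conditional of one joint density.  The test suite
verifies this end to end by comparing the chain's joint distribution over
(z, gamma) on a 2-subject toy against exhaustive enumeration with the
continuous parameters integrated in closed form (total variation below
0.02).

The update sweep is fixed: allocations, phi, gamma, (w, rho),
sticks/alpha.  The (w, rho) step is a marginalized two-term Bayes decision
between the point mass and the slab when no switch is on, and a conjugate
Beta draw otherwise.

## Stage 1 summaries

**Similarity and representative partition.**  The posterior similarity
matrix S records co-clustering fractions over stored iterations.  The
"representative partition" is chosen by the least-squares criterion of
Dahl: candidates are produced by k-medoids (PAM) on the dissimilarity
1 - S for k = 1..10, and the candidate minimizing
sum_ij (S_ij - 1[same cluster])^2 is reported.  The original literature
leaves this summary algorithm open; the least-squares-against-S criterion
is this package's operationalization.

**Profiles.**  For each representative cluster, covariate and level, the
cluster-level probability at an iteration is the member-averaged
selection-weighted probability gamma*phi + (1-gamma)*pi.  The 95% credible
interval of its difference from the fixed sample frequency codes the cell
as '>' (interval above zero), '<' (below) or '0' (covers zero).  Averaging
through the switches means a covariate whose switches are off contributes
exactly the marginal, so unselected covariates code '0' by construction,
and a covariate with posterior median rho = 0 always codes '0'.

## The T-gamma edge-evidence matrix

For every stored iteration and every cluster with more than one subject,
the matrix gamma_p1,c * gamma_p2,c is accumulated with weight equal to the
cluster size; the sum is rescaled so its largest entry is 1.  Singleton
clusters are excluded; only post-burn-in iterations contribute.

Interpretation is deliberately asymmetric.  If two covariates are never
jointly selected in any cluster, they are independent, and a covariate
never selected at all is marginally independent of all the rest - so small
entries are evidence *against* edges.  The converse fails: jointly
selected covariates need not interact, and in strongly clustered data the
matrix shows a "spill-over" block of large entries among all important
covariates.  Large entries must therefore never be read as evidence *for*
an edge.  The tests check the usable direction as a property: on data
generated from known two-clique graphs, every entry below 0.1 corresponds
to a non-edge of the generator.

**Screening.**  Covariates with posterior median selection probability
below a threshold (default 0.15, configurable) are dropped before the
log-linear stage, and the reduction of the model space is reported (graph
count 2^(P(P-1)/2) and cell count prod M_p, before and after).  This is
the main practical payoff for sparse contingency tables: 100 binary
covariates of which 8 interact shrink from 2^4950 candidate graphs and
1.27e30 cells to 2^28 graphs and 256 cells.

## Stage 2: reversible-jump search over graphical log-linear models

Cell counts follow a Poisson log-linear model whose interaction terms are
exactly the non-empty complete subsets of an undirected graph on the
factors (main effects always present).  Designs use sum-to-zero contrasts,
so the prior is exchangeable over level relabelling; columns are ordered
intercept first, then terms by size and lexicographic order.  Cells are
enumerated with the last factor varying fastest.  Parameters carry a
unit-information normal prior N(0, n (X'X)^{-1}), intercept included; all
graphs are equally likely a priori.

Each iteration updates parameters with probability 0.6 (random-walk
Metropolis, proposal covariance from a cheap curvature surrogate
X' diag(y + 0.5) X + X'X/n, scaled by 2.38^2/d), otherwise attempts a
model move, choosing uniformly among adding, removing, or swapping one
edge.  Edge selection is either uniform over candidates or informed by
T-gamma:

* addition: probabilities proportional to t_gamma over current non-edges
  (uniform fallback if they are all zero);
* removal: probabilities complementary to the normalized t_gamma over
  current edges (a low-evidence edge is removed preferentially);
* swap: one removal draw and one addition draw.

Strategies: (a) uniform only; (b) informed only; (c) uniform for 75% of
model moves and informed for 25% (i.e. 30% and 10% of all iterations);
(d) an even 50/50 split.  Mixed strategies evaluate proposal
probabilities under the full uniform/informed mixture in both directions,
so the acceptance ratio is exact.

Across models, coordinates of surviving terms are carried over and
coordinates of newly created terms are drawn from their conditional slice
of the destination model's prior; the Jacobian is 1 and the acceptance
ratio reduces to the likelihood ratio, the ratio of the two models'
marginal priors over the shared coordinates, and the edge-proposal ratio
q(reverse)/q(forward).  The edge-proposal ratio is essential: informed
proposals are asymmetric, and the tests confirm that a strongly asymmetric
T-gamma leaves the stationary distribution unchanged (total variation
below 0.05 against an independent enumeration oracle).

Diagnostics reported per run: acceptance rate over attempted model moves
(skipped moves - e.g. a removal attempted on the empty graph - count as
attempted and rejected), normalized visit frequencies as posterior model
probabilities, and the first-hit iteration of the model with the highest
post-burn-in visit frequency.

**Enumeration oracle.**  For small P the package enumerates all graphs and
scores each by a Laplace approximation to the log marginal likelihood at
the posterior mode (trust-region Newton mode search with analytic gradient
and Hessian).  This is used to validate the RJ sampler, never to replace
it.

## Synthetic data

Two generators cover the study conditions:

* **Mixtures of graphical log-linear models.**  Subjects are drawn at the
  cell level (exact, no per-subject loops) from a small set of models: a
  dominant component (weight 0.8) plus two lighter ones emulating
  real-data heterogeneity.  Five presets mirror the benchmark designs:
  10 binary covariates with cliques ABCD+HIJ (7 interacting), ABCD+AFG
  (6, one shared hub), ABCD+AFG+HIJ (9); 20 three-level covariates with 6
  interacting (weights 0.42/0.29/0.29); and 100 binary covariates with 8
  interacting.  Secondary components use sub-cliques of the main model, so
  the union of generating edges equals the main model's edge set.  Only
  the interacting covariates are modelled jointly; every other covariate
  is generated independently and uniformly - materializing a 2^100 table
  is neither possible nor needed.

* **Cluster populations.**  A three-cluster mixture of product
  multinomials over six three-level covariates with weights (0.3, 0.3,
  0.4), in which two covariates have identical level probabilities in all
  clusters and hence carry no clustering signal.  Its closed-form
  marginals (e.g. pi_1(0) = 0.122, pi_5(0) = 0.8) anchor the worked
  example.

**Default coefficients.**  Main effects are zero; every within-clique
two-way term gets coefficient 0.25, which for binary factors under
sum-to-zero coding is a conditional log-odds ratio of 1; terms of three or
more factors get 0.1.  A pure highest-order interaction was rejected
deliberately: for a clique of four binary factors a single four-way term
produces *exactly zero* pairwise marginal association (marginalizing the
other two +/-1-coded factors gives 4 cosh(beta) regardless of the pair),
which would leave the clustering stage nothing to detect.  Coefficients
are overridable; posterior model probabilities depend on them, so none of
the published probability values are reproduction targets.

What the generators do not emulate: covariate measurement error, missing
data, continuous covariates, or the confounding structure of real
epidemiological samples.  Passing tests show the machinery is correct and
the screening/search behaviour holds under the stated generative
conditions, not that the method resolves interactions in arbitrary real
data.

## Problem sizes used in the automated checks

The test suite and the acceptance script run everything at desk scale,
chosen so each stage still has a sharp expected outcome: the worked
population at n = 2000 with 2000 burn-in + 4000 kept sweeps (thinned by
4); the two-clique ten-covariate design at n = 2000 with 1000 + 2000
sweeps; the 100-covariate screen at n = 3000 with 2000 + 2000 sweeps; the
Gibbs-vs-enumeration toy at 150 000 sweeps; RJ-vs-enumeration at 100 000
iterations; and the informed-vs-uniform comparison over 12 replicate
chains of 4000 iterations.

## Known limitations

* **Cluster-recovery ceiling in the worked population.**  Clusters 2 and 3
  of the worked example differ only in two covariates with overlapping
  level probabilities; the Bayes-optimal assignment computed with the true
  parameters misassigns about 15% of subjects and attains an adjusted Rand
  index of about 0.63 against the generating labels, independent of sample
  size.  Partition recovery on this population should be judged against
  that ceiling, not against 1.
* The representative-partition criterion and the parameter proposals
  between models are this package's own constructions where the source
  methodology leaves them unspecified; both are swappable.
* Large T-gamma entries carry no usable evidence for edge presence; in
  designs where all kept covariates interact heavily the matrix is nearly
  constant and the informed search degenerates gracefully to the uniform
  one.
* The search targets graphical models only; arbitrary hierarchical
  log-linear spaces and decomposability-restricted searches are out of
  scope, as is exact marginal-likelihood computation for large P.
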