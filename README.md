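# profilegraph

Bayesian profile clustering with variable selection, used to inform
log-linear graphical model search on sparse contingency tables.

## The problem

Epidemiologists and statisticians exploring dependence among P categorical
covariates face two exploding spaces at once: a P-way contingency table
with prod(M_p) cells and 2^(P(P-1)/2) candidate graphical log-linear
models.  Twenty covariates with three levels already imply 3^20 cells;
reversible-jump searches over such spaces do not converge in any practical
time.  Yet in many studies only a handful of covariates actually interact.

`profilegraph` implements a two-stage approach:

1. **Profile clustering with variable selection.**  A Dirichlet-process
   mixture of product multinomials partitions the subjects.  Each
   covariate p carries cluster-specific binary switches gamma_pc with
   selection probability rho_p under a spike-and-slab prior:

       P(x_p = x | z_i = c) = phi_pc(x)^gamma_pc * pi_p(x)^(1 - gamma_pc)

   A covariate whose switches stay off follows its sample-wide marginal
   pi_p in every cluster — and is then marginally independent of all other
   covariates, so it cannot form an edge in the generating graph.

2. **Informed reversible-jump model search.**  The chain's switches are
   condensed into the symmetric edge-evidence matrix T_gamma (cluster-size
   weighted co-selection frequencies, rescaled to maximum 1).  Covariates
   with posterior median rho_p below a threshold are dropped, shrinking
   the model space; the remaining entries of T_gamma steer edge
   addition/removal/swap proposals of a reversible-jump sampler over
   graphical log-linear models with unit-information priors
   N(0, n (X'X)^(-1)).

Small T_gamma entries reliably flag absent edges; large entries are *not*
evidence of presence (jointly selected covariates need not interact).  The
search therefore uses T_gamma to avoid low-probability regions, mixed with
uniform moves as a safeguard.  See `docs/methods.md` for the full model,
priors, proposal construction and limitations.

## Worked example

Six three-level covariates from a three-cluster population (weights 0.3,
0.3, 0.4) in which covariates E and F have identical level probabilities
in every cluster — they carry no clustering information:

```python
import numpy as np
import profilegraph as pg

rng = np.random.default_rng(7)
pop = pg.worked_example_population()
data, _ = pg.sample_cluster_population(pop, 2000, rng)

cfg = pg.DPConfig(iterations=2000, burnin=1000, thin=2, seed=7)
chain = pg.run_chain(data, pop.spec, cfg)
print("median rho:", np.round(chain.median_rho(), 2))

S = pg.similarity(chain)
part = pg.representative_partition(S, range(1, 11), seed=7)
print(pg.summarize_profiles(chain, part, data).to_frame().to_string())

screen = pg.screen_covariates(chain.median_rho(), pop.spec, threshold=0.15)
print("kept:", screen.kept, " dropped:", screen.dropped)
print("cells:", screen.full_cells, "->", screen.reduced_cells)
```

prints

```
median rho: [0.8  0.91 0.7  0.76 0.   0.  ]
                    A     B     C     D     E     F
Median(rho_p)    0.80  0.91  0.70  0.76  0.00  0.00
Cluster 1 (347)   <<>   <<>   <0>   <0>   000   000
...
Cluster 6 (948)   >><   >><   >0<   >0<   000   000
...
kept: ['A', 'B', 'C', 'D']  dropped: ['E', 'F']
cells: 729 -> 81
```

The posterior median selection probabilities separate the informative
covariates (0.70–0.91) from the uninformative ones (exactly 0, thanks to
the point mass of the spike-and-slab prior), so the screen drops E and F
and the table shrinks from 729 to 81 cells.  Each profile cell codes
whether a level is more ('>'), less ('<') or indistinguishably ('0')
frequent in that cluster than in the whole sample: the largest cluster
(948 subjects) is enriched for low levels of A and B and depleted at their
top level, matching the generating cluster it recovers, while E and F code
'000' everywhere.

Stage two then runs on the reduced table:

```python
kept = [pop.spec.index(name) for name in screen.kept]
red_spec = pg.FactorSpec(names=tuple(screen.kept),
                         levels=tuple(pop.spec.levels[i] for i in kept))
table = pg.ContingencyTable.from_subjects(data[:, kept], red_spec)
T = pg.build_tgamma(chain)
T_kept = pg.TGammaMatrix(values=T.values[np.ix_(kept, kept)],
                         names=red_spec.names)
rj = pg.run_search(table, pg.SearchStrategy("d"), T_kept,
                   pg.RJConfig(iterations=10000, burnin=1000, seed=7))
rj.summary()                         # top models, acceptance, first hit
```

A command-line interface mirrors the library:
`profilegraph simulate | cluster | summarize | tgamma | rjsearch | pipeline`.

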