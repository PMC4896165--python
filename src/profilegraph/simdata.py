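"""Synthetic populations for exercising the full pipeline.

Two generators are provided:

* mixtures of graphical log-linear models -- subjects are drawn from a small
  set of models (one dominant, the rest emulating real-data heterogeneity)
  with fixed mixture weights; cell probabilities are proportional to
  exp(X beta) and subjects are sampled at the cell level;

* a three-cluster multinomial population with known cluster weights and
  per-cluster level probabilities, in which two covariates are identical
  across clusters and hence carry no clustering information -- the worked
  example used throughout the docs and tests.

Five presets mirror the simulation designs the package is benchmarked on
(10 binary factors with 7 interacting, down to 100 binary factors with 8
interacting).  Default interaction coefficients put a conditional pairwise
log-odds ratio of 1 on every within-clique pair and a weak 0.1 coefficient
on each higher-order term; they are overridable, since posterior model
probabilities depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loglinear import (
    ContingencyTable,
    FactorSpec,
    Graph,
    LogLinearModel,
    build_design,
    cell_levels,
)


def default_coefficients(model: LogLinearModel, spec: FactorSpec,
                         pairwise: float = 0.25,
                         higher_order: float = 0.1) -> np.ndarray:
    """Zero main effects; `pairwise` on two-factor term columns (0.25 gives
    conditional log-OR 1 for binary factors under sum-to-zero coding);
    `higher_order` on columns of terms with three or more factors."""
    design = build_design(model, spec)
    beta = np.zeros(design.n_params)
    for term, sl in design.term_slices.items():
        if len(term) == 2:
            beta[sl] = pairwise
        elif len(term) >= 3:
            beta[sl] = higher_order
    return beta


def cell_probabilities(model: LogLinearModel, beta: np.ndarray,
                       spec: FactorSpec) -> np.ndarray:
    """Cell probability tensor (flattened, last factor fastest) ∝ exp(X beta)."""
    design = build_design(model, spec)
    eta = design.X @ np.asarray(beta, dtype=float)
    eta -= eta.max()  # intercept-invariant rescale against overflow
    p = np.exp(eta)
    return p / p.sum()


def sample_from_loglinear(model: LogLinearModel, beta: np.ndarray,
                          spec: FactorSpec, n: int,
                          rng: np.random.Generator):
    """Draw n subjects from one graphical log-linear model.

    Returns (data, table): an n x P matrix of levels in subject order
    (shuffled) and the corresponding contingency table.
    """
    probs = cell_probabilities(model, beta, spec)
    counts = rng.multinomial(n, probs)
    levels = cell_levels(spec)
    data = np.repeat(levels, counts, axis=0)
    rng.shuffle(data, axis=0)
    return data, ContingencyTable(spec=spec, counts=counts)


@dataclass
class GeneratorSpec:
    """A mixture of graphical log-linear models over a common factor spec.

    Only the factors that appear in some interaction ("active" factors) are
    modelled jointly; the component models live on the sub-spec of active
    factors, and every other factor is generated independently with uniform
    level probabilities.  This keeps generation exact for designs where the
    full table (e.g. 3^20 or 2^100 cells) could never be materialized.
    """

    spec: FactorSpec
    active: tuple                 # full-spec indices of the active factors
    components: list              # list of (LogLinearModel over active, beta)
    weights: np.ndarray
    n: int
    name: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.active = tuple(self.active)
        if len(self.components) != self.weights.size:
            raise ValueError("one weight per component required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        sub = self.active_spec
        for model, beta in self.components:
            d = build_design(model, sub).n_params
            if np.asarray(beta).size != d:
                raise ValueError("coefficient vector does not match the design")

    @property
    def active_spec(self) -> FactorSpec:
        return FactorSpec(
            names=tuple(self.spec.names[i] for i in self.active),
            levels=tuple(self.spec.levels[i] for i in self.active))

    def generating_edges(self) -> frozenset:
        """Union of the component graphs' edges, in full-spec indices."""
        out = set()
        for model, _ in self.components:
            for a, b in model.graph.edges:
                out.add(tuple(sorted((self.active[a], self.active[b]))))
        return frozenset(out)

    @classmethod
    def from_notation(cls, spec: FactorSpec, models: list, weights, n: int,
                      coefficients: list | None = None,
                      name: str = "") -> "GeneratorSpec":
        """Build from '+'-separated clique generators against the full spec.

        The active set is the union of factors touched by any edge; the
        component models are re-expressed on the active sub-spec.
        """
        full_models = [LogLinearModel.parse(m, spec) if isinstance(m, str)
                       else m for m in models]
        active = sorted({i for m in full_models for e in m.graph.edges
                         for i in e})
        if not active:
            active = list(range(spec.P))
        remap = {full: sub for sub, full in enumerate(active)}
        sub_spec = FactorSpec(
            names=tuple(spec.names[i] for i in active),
            levels=tuple(spec.levels[i] for i in active))
        parsed = []
        for m in full_models:
            edges = frozenset(
                (remap[a], remap[b]) for a, b in m.graph.edges)
            parsed.append(LogLinearModel.from_graph(
                Graph(len(active), edges)))
        if coefficients is None:
            coefficients = [default_coefficients(m, sub_spec) for m in parsed]
        return cls(spec=spec, active=tuple(active),
                   components=list(zip(parsed, coefficients)),
                   weights=weights, n=n, name=name)


def sample_mixture(gen: GeneratorSpec, rng: np.random.Generator):
    """Draw gen.n subjects from the mixture.

    Active factors come from the log-linear mixture; the remaining factors
    are independent and uniform over their levels.  Returns
    (data, active_table, component_counts); rows are shuffled so subject
    order carries no component information.  The contingency table covers
    the active factors only (the full table may be astronomically large).
    """
    comp_counts = rng.multinomial(gen.n, gen.weights)
    sub = gen.active_spec
    parts = []
    for (model, beta), m in zip(gen.components, comp_counts):
        if m > 0:
            part, _ = sample_from_loglinear(model, beta, sub, m, rng)
            parts.append(part)
    active_data = np.concatenate(parts, axis=0)
    rng.shuffle(active_data, axis=0)
    data = np.empty((gen.n, gen.spec.P), dtype=int)
    for j, i in enumerate(gen.active):
        data[:, i] = active_data[:, j]
    inactive = [i for i in range(gen.spec.P) if i not in gen.active]
    for i in inactive:
        data[:, i] = rng.integers(0, gen.spec.levels[i], size=gen.n)
    return data, ContingencyTable.from_subjects(active_data, sub), comp_counts


def preset_simulations(n_override: int | None = None) -> dict:
    """The five benchmark designs, keyed 1..5.

    1: n=10000, P=10 binary, 7 interacting covariates (ABCD + HIJ)
    2: n=10000, P=10 binary, 6 interacting (ABCD + AFG, shared covariate A)
    3: n=10000, P=10 binary, 9 interacting (ABCD + AFG + HIJ)
    4: n=5000,  P=20 three-level, 6 interacting (ABC + DEF)
    5: n=10000, P=100 binary, 8 interacting (ABCD + EFGH)

    The secondary mixture components use sub-cliques of the main model so
    the union of generating edges equals the main model's edge set.
    """
    designs = {
        1: (10, 2, 10000, ["ABCD+HIJ", "ABC+HIJ", "ABD+HIJ"], (0.8, 0.1, 0.1)),
        2: (10, 2, 10000, ["ABCD+AFG", "ABCD+AF", "ABC+AFG"], (0.8, 0.1, 0.1)),
        3: (10, 2, 10000, ["ABCD+AFG+HIJ", "ABCD+AFG+HI", "ABC+AFG+HIJ"],
            (0.8, 0.1, 0.1)),
        4: (20, 3, 5000, ["ABC+DEF", "AB+DEF", "ABC+DE"], (0.42, 0.29, 0.29)),
        5: (100, 2, 10000, ["ABCD+EFGH", "ABCD+EFG", "ABC+EFGH"],
            (0.8, 0.1, 0.1)),
    }
    out = {}
    for key, (P, M, n, models, weights) in designs.items():
        spec = FactorSpec.uniform(P, M)
        out[key] = GeneratorSpec.from_notation(
            spec, models, weights, n_override or n, name=f"simulation-{key}")
    return out


@dataclass
class ClusterPopulationSpec:
    """Mixture of product multinomials with known cluster structure."""

    spec: FactorSpec
    psi: np.ndarray                       # cluster weights
    phi: np.ndarray                       # (C, P, Mmax) level probabilities
    gamma: np.ndarray = field(default=None)   # (P, C) selection pattern

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.isclose(self.psi.sum(), 1.0):
            raise ValueError("cluster weights must sum to 1")
        if not np.allclose(self.phi.sum(axis=2), 1.0):
            raise ValueError("each phi row must be a probability vector")
        if self.gamma is None:
            # a covariate is non-informative when its rows agree across clusters
            g = np.ones((self.spec.P, self.psi.size), dtype=int)
            for p in range(self.spec.P):
                if np.allclose(self.phi[:, p, :], self.phi[0, p, :]):
                    g[p, :] = 0
            self.gamma = g

    def marginals(self) -> np.ndarray:
        """Closed-form marginal level frequencies pi_p(x) = sum_c psi_c phi_pc(x)."""
        return np.einsum("c,cpm->pm", self.psi, self.phi)


def worked_example_population() -> ClusterPopulationSpec:
    """The worked three-cluster population over six three-level covariates.

    Covariates 5 and 6 have identical rows across clusters (they do not
    contribute to the clustering); the marginal of level 0 for covariate 1
    is 0.3*0.01 + 0.3*0.01 + 0.4*0.29 = 0.122.
    """
    spec = FactorSpec.uniform(6, 3)
    phi = np.array([
        # cluster 1
        [[0.01, 0.3, 0.69], [0.01, 0.3, 0.69], [0.1, 0.1, 0.8],
         [0.1, 0.1, 0.8], [0.8, 0.1, 0.1], [0.8, 0.1, 0.1]],
        # cluster 2
        [[0.01, 0.5, 0.49], [0.01, 0.5, 0.49], [0.8, 0.1, 0.1],
         [0.8, 0.1, 0.1], [0.8, 0.1, 0.1], [0.8, 0.1, 0.1]],
        # cluster 3
        [[0.29, 0.7, 0.01], [0.29, 0.7, 0.01], [0.8, 0.1, 0.1],
         [0.8, 0.1, 0.1], [0.8, 0.1, 0.1], [0.8, 0.1, 0.1]],
    ])
    return ClusterPopulationSpec(spec=spec, psi=np.array([0.3, 0.3, 0.4]),
                                 phi=phi)


def sample_cluster_population(pop: ClusterPopulationSpec, n: int,
                              rng: np.random.Generator):
    """Draw n subjects: cluster from psi, levels from the cluster's phi rows.

    Returns (data, cluster_labels).
    """
    labels = rng.choice(pop.psi.size, size=n, p=pop.psi)
    P = pop.spec.P
    data = np.empty((n, P), dtype=int)
    u = rng.random((n, P))
    for c in range(pop.psi.size):
        members = labels == c
        for p in range(P):
            cdf = np.cumsum(pop.phi[c, p, : pop.spec.levels[p]])
            data[members, p] = np.searchsorted(cdf, u[members, p], side="right")
    data = np.minimum(data, np.asarray(pop.spec.levels) - 1)
    return data, labels
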