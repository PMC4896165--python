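"""Graphical log-linear models for contingency tables.

A graphical log-linear model is indexed by an undirected graph on the P
factors: its interaction terms are exactly the non-empty complete subsets
(cliques and sub-cliques) of the graph, and absent edges encode conditional
independence.  Cell counts are modelled as independent Poisson variables with
log-mean ``X @ beta`` where ``X`` uses sum-to-zero contrasts, and parameters
carry a unit-information Gaussian prior ``N(0, n (X'X)^{-1})``.

This module provides the model-space combinatorics, design-matrix
construction, likelihood/prior evaluation, within-model posterior sampling
and a Laplace approximation to the marginal likelihood that doubles as an
enumeration oracle on small factor sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize
from scipy.special import gammaln


class UnidentifiableModelError(ValueError):
    """Raised when a design matrix is rank deficient."""


@dataclass(frozen=True)
class FactorSpec:
    """Names and per-factor category counts of the P factors."""

    names: tuple[str, ...]
    levels: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(self.levels):
            raise ValueError("names and levels must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("factor names must be unique")
        if any(m < 2 for m in self.levels):
            raise ValueError("every factor needs at least 2 levels")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "levels", tuple(int(m) for m in self.levels))

    @property
    def P(self) -> int:
        return len(self.names)

    @classmethod
    def binary(cls, P: int, names: tuple[str, ...] | None = None) -> "FactorSpec":
        if names is None:
            names = tuple(_default_name(i) for i in range(P))
        return cls(names=tuple(names), levels=(2,) * P)

    @classmethod
    def uniform(cls, P: int, M: int) -> "FactorSpec":
        return cls(names=tuple(_default_name(i) for i in range(P)), levels=(M,) * P)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _default_name(i: int) -> str:
    # A..Z, then A1, B1, ... for larger factor sets
    letter = chr(ord("A") + i % 26)
    return letter if i < 26 else f"{letter}{i // 26}"


@dataclass(frozen=True)
class Graph:
    """Undirected graph on factor indices 0..P-1, edges stored as sorted pairs."""

    n_nodes: int
    edges: frozenset = frozenset()

    def __post_init__(self):
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loops are not allowed")
            if not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ValueError("edge endpoint out of range")
            norm.add((min(a, b), max(a, b)))
        object.__setattr__(self, "edges", frozenset(norm))

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    def add_edge(self, e) -> "Graph":
        return Graph(self.n_nodes, self.edges | {tuple(sorted(e))})

    def remove_edge(self, e) -> "Graph":
        return Graph(self.n_nodes, self.edges - {tuple(sorted(e))})

    def non_edges(self) -> list:
        return [
            (a, b)
            for a, b in itertools.combinations(range(self.n_nodes), 2)
            if (a, b) not in self.edges
        ]

    def sorted_edges(self) -> list:
        return sorted(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def count_graphical_models(P: int):
    """Number of graphical models on P factors: 2^(P(P-1)/2), exact integer."""
    if P < 1:
        raise ValueError("P must be at least 1")
    return 2 ** (P * (P - 1) // 2)


def count_cells(spec: FactorSpec):
    """Number of cells of the P-way table: product of the level counts."""
    out = 1
    for m in spec.levels:
        out *= m
    return out


def complete_subsets(g: Graph) -> list:
    """All non-empty vertex subsets inducing a complete subgraph.

    Enumerates maximal cliques (Bron–Kerbosch via networkx) and closes each
    under taking non-empty subsets, deduplicating across cliques.  Singletons
    are always present.  Result is sorted by (size, lexicographic).
    """
    terms = set()
    for clique in nx.find_cliques(g.to_networkx()):
        clique = sorted(clique)
        for r in range(1, len(clique) + 1):
            terms.update(itertools.combinations(clique, r))
    return sorted(terms, key=lambda t: (len(t), t))


@dataclass(frozen=True)
class LogLinearModel:
    """Hierarchical log-linear model generated by the complete subsets of a graph."""

    graph: Graph
    terms: tuple = field(default=None)

    def __post_init__(self):
        if self.terms is None:
            object.__setattr__(self, "terms", tuple(complete_subsets(self.graph)))

    @classmethod
    def from_graph(cls, graph: Graph) -> "LogLinearModel":
        return cls(graph=graph)

    @classmethod
    def parse(cls, text: str, spec: FactorSpec) -> "LogLinearModel":
        """Parse '+'-separated clique generators, e.g. ``"ABCD+AFG+E"``.

        Single-character factor names may be concatenated; otherwise the
        factors of a generator are comma separated.
        """
        edges = set()
        for gen in text.replace(" ", "").split("+"):
            if not gen:
                continue
            if "," in gen:
                members = gen.split(",")
            elif gen in spec.names:
                members = [gen]
            elif all(ch in spec.names for ch in gen):
                members = list(gen)
            else:
                raise ValueError(f"cannot resolve generator {gen!r}")
            idx = [spec.index(m) for m in members]
            edges.update(itertools.combinations(sorted(idx), 2))
        return cls.from_graph(Graph(spec.P, frozenset(edges)))

    def notation(self, spec: FactorSpec) -> str:
        """Clique-generator notation, e.g. ``'ABCD+AFG+E'``."""
        gx = self.graph.to_networkx()
        cliques = [tuple(sorted(c)) for c in nx.find_cliques(gx)]
        cliques.sort(key=lambda c: (-len(c), c))
        sep = "" if all(len(n) == 1 for n in spec.names) else ","
        return "+".join(sep.join(spec.names[i] for i in c) for c in cliques)


@dataclass
class ContingencyTable:
    """Counts over the Cartesian product of factor levels (last factor fastest)."""

    spec: FactorSpec
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float).ravel()
        if self.counts.size != count_cells(self.spec):
            raise ValueError("count vector length must equal the number of cells")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_subjects(cls, data: np.ndarray, spec: FactorSpec) -> "ContingencyTable":
        """Tabulate an n×P matrix of integer levels into cell counts."""
        data = np.asarray(data, dtype=int)
        idx = np.ravel_multi_index(data.T, spec.levels)
        counts = np.bincount(idx, minlength=count_cells(spec))
        return cls(spec=spec, counts=counts)


def cell_levels(spec: FactorSpec) -> np.ndarray:
    """(ncells, P) matrix of level combinations, last factor varying fastest."""
    grids = np.meshgrid(*[np.arange(m) for m in spec.levels], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _contrast(M: int) -> np.ndarray:
    """Sum-to-zero contrast rows for an M-level factor: M x (M-1)."""
    return np.vstack([np.eye(M - 1), -np.ones(M - 1)])


@dataclass
class DesignMatrix:
    """Design matrix of a log-linear model (intercept + one block per term)."""

    X: np.ndarray
    term_slices: dict
    model: LogLinearModel
    spec: FactorSpec

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def columns_for(self, terms) -> np.ndarray:
        """Column indices for the intercept plus the given terms."""
        cols = [0]
        for t in terms:
            s = self.term_slices[tuple(t)]
            cols.extend(range(s.start, s.stop))
        return np.asarray(cols)


def build_design(model: LogLinearModel, spec: FactorSpec) -> DesignMatrix:
    """Sum-to-zero design over cells; columns ordered intercept, then terms
    sorted by size then lexicographically."""
    levels = cell_levels(spec)
    ncells = levels.shape[0]
    contrasts = [_contrast(m) for m in spec.levels]
    blocks = [np.ones((ncells, 1))]
    term_slices = {}
    start = 1
    for term in sorted(model.terms, key=lambda t: (len(t), t)):
        block = np.ones((ncells, 1))
        for p in term:
            rows = contrasts[p][levels[:, p]]  # ncells x (Mp-1)
            block = (block[:, :, None] * rows[:, None, :]).reshape(ncells, -1)
        width = block.shape[1]
        term_slices[tuple(term)] = slice(start, start + width)
        start += width
        blocks.append(block)
    X = np.concatenate(blocks, axis=1)
    return DesignMatrix(X=X, term_slices=term_slices, model=model, spec=spec)


def log_likelihood(beta: np.ndarray, table: ContingencyTable, design: DesignMatrix) -> float:
    """Poisson log-likelihood of the cell counts: sum y*eta - exp(eta) - log(y!)."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    eta = design.X @ beta
    y = table.counts
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def _xtx_chol(design: DesignMatrix) -> np.ndarray:
    xtx = design.X.T @ design.X
    try:
        L = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError as err:
        raise UnidentifiableModelError(
            "design matrix is rank deficient; model is not identifiable"
        ) from err
    diag = np.diag(L)
    if diag.min() <= 1e-6 * diag.max():
        raise UnidentifiableModelError(
            "design matrix is numerically rank deficient")
    return L


def log_prior(beta: np.ndarray, design: DesignMatrix, n: int) -> float:
    """Unit-information Gaussian prior N(0, n (X'X)^{-1}) over all columns."""
    beta = np.asarray(beta, dtype=float)
    L = _xtx_chol(design)
    d = beta.size
    # log|cov| = d log n - log|X'X|;   quad = beta' X'X beta / n
    logdet_xtx = 2.0 * np.sum(np.log(np.diag(L)))
    quad = np.sum((L.T @ beta) ** 2) / n
    return float(-0.5 * (d * np.log(2 * np.pi) + d * np.log(n) - logdet_xtx + quad))


@dataclass
class FitResult:
    """Posterior sample and Laplace evidence for a single model."""

    samples: np.ndarray          # iterations x n_params
    mode: np.ndarray
    log_marginal: float          # Laplace approximation at the posterior mode
    acceptance_rate: float
    converged: bool


def _posterior_parts(table: ContingencyTable, design: DesignMatrix):
    y = table.counts
    n = max(table.n, 1)
    X = design.X
    xtx = X.T @ X
    prior_prec = xtx / n
    L = _xtx_chol(design)
    logdet_xtx = 2.0 * np.sum(np.log(np.diag(L)))
    d = X.shape[1]
    const = -0.5 * (d * np.log(2 * np.pi) + d * np.log(n) - logdet_xtx)

    def neg_logpost(beta):
        eta = X @ beta
        ll = np.sum(y * eta - np.exp(eta) - gammaln(y + 1))
        lp = const - 0.5 * beta @ prior_prec @ beta
        return -(ll + lp)

    def grad(beta):
        mu = np.exp(X @ beta)
        return -(X.T @ (y - mu) - prior_prec @ beta)

    def hess(beta):
        mu = np.exp(X @ beta)
        return X.T @ (mu[:, None] * X) + prior_prec

    return neg_logpost, grad, hess, d


def laplace_log_marginal(model: LogLinearModel, table: ContingencyTable,
                         design: DesignMatrix | None = None):
    """Laplace approximation to the log marginal likelihood at the posterior mode.

    Returns (log_marginal, mode, hessian_at_mode, converged).
    """
    if design is None:
        design = build_design(model, table.spec)
    neg_logpost, grad, hess, d = _posterior_parts(table, design)
    x0 = np.zeros(d)
    x0[0] = np.log(max(table.n, 1) / table.counts.size)  # start near mean count
    res = optimize.minimize(neg_logpost, x0, jac=grad, hess=hess,
                            method="trust-ncg", options={"maxiter": 500})
    mode = res.x
    H = hess(mode)
    sign, logdet_h = np.linalg.slogdet(H)
    lml = -neg_logpost(mode) + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet_h
    return float(lml), mode, H, bool(res.success and sign > 0)


def fit_within_model(model: LogLinearModel, table: ContingencyTable,
                     iterations: int, rng: np.random.Generator,
                     burnin: int | None = None,
                     prior_only: bool = False) -> FitResult:
    """Random-walk Metropolis under likelihood + unit-information prior.

    The proposal covariance is the inverse Hessian at the posterior mode
    scaled by 2.38^2/d; the Laplace log marginal likelihood is computed at
    the mode and returned alongside the sample.  With ``prior_only`` the
    likelihood is switched off and the sampler targets the prior (a
    validation aid: sample moments should match the prior's).
    """
    design = build_design(model, table.spec)
    if prior_only:
        return _sample_prior_only(design, table, iterations, rng, burnin)
    lml, mode, H, converged = laplace_log_marginal(model, table, design)
    neg_logpost, _, _, d = _posterior_parts(table, design)
    prop_chol = np.linalg.cholesky(np.linalg.inv(H)) * (2.38 / np.sqrt(d))
    if burnin is None:
        burnin = iterations // 5
    beta = mode.copy()
    lp = -neg_logpost(beta)
    samples = np.empty((iterations, d))
    accepted = 0
    total = iterations + burnin
    for it in range(total):
        prop = beta + prop_chol @ rng.standard_normal(d)
        lp_prop = -neg_logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
            accepted += 1
        if it >= burnin:
            samples[it - burnin] = beta
    return FitResult(samples=samples, mode=mode, log_marginal=lml,
                     acceptance_rate=accepted / total, converged=converged)


def _sample_prior_only(design, table, iterations, rng, burnin):
    n = max(table.n, 1)
    d = design.X.shape[1]
    prior_prec = (design.X.T @ design.X) / n
    L = _xtx_chol(design)

    def neg_logdens(beta):
        return 0.5 * beta @ prior_prec @ beta

    prop_chol = np.linalg.cholesky(np.linalg.inv(prior_prec)) * (2.38 / np.sqrt(d))
    if burnin is None:
        burnin = iterations // 5
    beta = np.zeros(d)
    lp = -neg_logdens(beta)
    samples = np.empty((iterations, d))
    accepted = 0
    for it in range(iterations + burnin):
        prop = beta + prop_chol @ rng.standard_normal(d)
        lp_prop = -neg_logdens(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
            accepted += 1
        if it >= burnin:
            samples[it - burnin] = beta
    return FitResult(samples=samples, mode=np.zeros(d), log_marginal=np.nan,
                     acceptance_rate=accepted / (iterations + burnin),
                     converged=True)


def all_graphs(P: int):
    """Iterate over every graph on P nodes (use only for small P)."""
    pairs = list(itertools.combinations(range(P), 2))
    for r in range(len(pairs) + 1):
        for subset in itertools.combinations(pairs, r):
            yield Graph(P, frozenset(subset))


def enumerate_model_posteriors(table: ContingencyTable) -> dict:
    """Laplace posterior over all graphical models (uniform graph prior).

    Exhaustive enumeration; intended as an oracle for small P.  Returns a
    dict mapping each graph's frozen edge set to its normalized posterior
    probability.
    """
    P = table.spec.P
    lmls = {}
    for g in all_graphs(P):
        lml, *_ = laplace_log_marginal(LogLinearModel.from_graph(g), table)
        lmls[g.edges] = lml
    mx = max(lmls.values())
    weights = {k: math.exp(v - mx) for k, v in lmls.items()}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}
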