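"""Reversible-jump MCMC over graphical log-linear models.

Each iteration updates the parameters of the current model (probability
0.6) or attempts a model move (probability 0.4), choosing uniformly among
adding, removing or swapping one edge.  Edge selection is either uniform
over candidates or informed by the T-gamma matrix: additions are drawn
proportionally to t_gamma over non-edges, removals with probabilities
complementary to the normalized t_gamma over current edges, and a swap
draws both.  Mixed strategies (c) and (d) use the informed rule for a fixed
fraction of model moves.

Across models, parameters of newly created terms are drawn from their
conditional slice of the new model's unit-information prior (Jacobian 1),
so the acceptance ratio needs only the likelihoods, the marginal priors of
the shared coordinates under each model, and the edge-proposal ratio
q(reverse)/q(forward) - the latter is essential because informed proposals
are asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .loglinear import (
    ContingencyTable,
    Graph,
    LogLinearModel,
    build_design,
    UnidentifiableModelError,
)
from .tgamma import TGammaMatrix

_STRATEGY_MODES = {
    # (uniform weight, informed weight), conditional on a model move.
    # (c): uniform in 30% of all iterations, informed in 10% -> 0.75 / 0.25
    # of the 40% of iterations that attempt a model move.
    "a": (1.0, 0.0),
    "b": (0.0, 1.0),
    "c": (0.75, 0.25),
    "d": (0.5, 0.5),
}


@dataclass(frozen=True)
class SearchStrategy:
    """Move mix of the sampler: 60% parameter updates, 40% model moves
    split equally over add/remove/swap, with the stated edge-selection mode."""

    label: str
    parameter_prob: float = 0.6
    model_prob: float = 0.4

    def __post_init__(self):
        if self.label not in _STRATEGY_MODES:
            raise ValueError("strategy label must be one of a, b, c, d")
        if abs(self.parameter_prob + self.model_prob - 1.0) > 1e-12:
            raise ValueError("move probabilities must sum to 1")

    @property
    def mode_weights(self):
        return _STRATEGY_MODES[self.label]

    @property
    def needs_tgamma(self) -> bool:
        return self.mode_weights[1] > 0


def edge_add_distribution(T: TGammaMatrix, g: Graph):
    """(candidates, probabilities) for an informed edge addition."""
    cand = g.non_edges()
    if not cand:
        return [], np.array([])
    w = np.array([T.entry(a, b) for a, b in cand])
    total = w.sum()
    if total <= 0:
        probs = np.full(len(cand), 1.0 / len(cand))
    else:
        probs = w / total
    return cand, probs


def edge_remove_distribution(T: TGammaMatrix, g: Graph):
    """(candidates, probabilities) for an informed edge removal
    (complementary to the normalized t_gamma of the current edges)."""
    cand = g.sorted_edges()
    if not cand:
        return [], np.array([])
    if len(cand) == 1:
        return cand, np.array([1.0])
    w = np.array([T.entry(a, b) for a, b in cand])
    total = w.sum()
    if total <= 0:
        probs = np.full(len(cand), 1.0 / len(cand))
    else:
        s = w / total
        probs = (1.0 - s) / (1.0 - s).sum()
    return cand, probs


def _mixture_edge_prob(T, g, edge, kind, mode_weights):
    """Proposal probability of a specific edge under the uniform/informed mix."""
    u_w, i_w = mode_weights
    cand = g.non_edges() if kind == "add" else g.sorted_edges()
    if not cand:
        return 0.0
    edge = tuple(sorted(edge))
    prob = u_w / len(cand)
    if i_w > 0:
        cands, informed = (edge_add_distribution(T, g) if kind == "add"
                           else edge_remove_distribution(T, g))
        prob += i_w * informed[cands.index(edge)]
    return prob


@dataclass
class _ModelEntry:
    """Cached per-model quantities keyed by the graph's edge set."""

    graph: Graph
    model: LogLinearModel
    design: object
    sigma: np.ndarray            # prior covariance n (X'X)^{-1}
    prior_prec: np.ndarray       # X'X / n
    prior_const: float           # log normalizing constant of the prior
    prop_chol: np.ndarray        # random-walk proposal Cholesky factor


class _Workspace:
    def __init__(self, table: ContingencyTable, rw_scale: float = 1.0):
        self.table = table
        self.y = table.counts
        self.n = max(table.n, 1)
        self.loggamma_y = float(gammaln(self.y + 1).sum())
        self.rw_scale = rw_scale
        self.cache: dict = {}

    def entry(self, graph: Graph) -> _ModelEntry:
        key = graph.edges
        if key not in self.cache:
            model = LogLinearModel.from_graph(graph)
            design = build_design(model, self.table.spec)
            X = design.X
            xtx = X.T @ X
            try:
                L = np.linalg.cholesky(xtx)
            except np.linalg.LinAlgError as err:
                raise UnidentifiableModelError(str(err)) from err
            d = X.shape[1]
            logdet_xtx = 2.0 * np.sum(np.log(np.diag(L)))
            prior_const = -0.5 * (d * np.log(2 * np.pi)
                                  + d * np.log(self.n) - logdet_xtx)
            sigma = self.n * np.linalg.inv(xtx)
            # cheap posterior-curvature surrogate for the random-walk proposal
            H = X.T @ ((self.y + 0.5)[:, None] * X) + xtx / self.n
            prop_cov = np.linalg.inv(H)
            prop_chol = np.linalg.cholesky(prop_cov) * (
                self.rw_scale * 2.38 / np.sqrt(d))
            self.cache[key] = _ModelEntry(
                graph=graph, model=model, design=design, sigma=sigma,
                prior_prec=xtx / self.n, prior_const=prior_const,
                prop_chol=prop_chol)
        return self.cache[key]

    def log_likelihood(self, entry: _ModelEntry, beta: np.ndarray) -> float:
        eta = entry.design.X @ beta
        with np.errstate(over="ignore"):
            mu = np.exp(np.minimum(eta, 700.0))
        return float(np.sum(self.y * eta) - mu.sum() - self.loggamma_y)

    def log_prior(self, entry: _ModelEntry, beta: np.ndarray) -> float:
        return float(entry.prior_const
                     - 0.5 * beta @ entry.prior_prec @ beta)

    def log_marginal_prior(self, entry: _ModelEntry, cols: np.ndarray,
                           values: np.ndarray) -> float:
        """Log density of the prior marginal over a subset of columns."""
        from scipy.linalg import solve_triangular
        sub = entry.sigma[np.ix_(cols, cols)]
        L = np.linalg.cholesky(sub)
        u = solve_triangular(L, values, lower=True)
        return float(-0.5 * (cols.size * np.log(2 * np.pi)
                             + 2 * np.sum(np.log(np.diag(L)))
                             + u @ u))

    def conditional_prior_draw(self, entry: _ModelEntry, shared_cols,
                               new_cols, shared_values, rng):
        """Draw the new columns from the prior conditional on the shared ones."""
        from scipy.linalg import solve_triangular
        sig = entry.sigma
        S = sig[np.ix_(shared_cols, shared_cols)]
        C = sig[np.ix_(new_cols, shared_cols)]
        N = sig[np.ix_(new_cols, new_cols)]
        L = np.linalg.cholesky(S)
        tmp = solve_triangular(L, C.T, lower=True)
        mean = tmp.T @ solve_triangular(L, shared_values, lower=True)
        cov = N - tmp.T @ tmp
        Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        return mean + Lc @ rng.standard_normal(new_cols.size)


def _map_beta(entry_from: _ModelEntry, entry_to: _ModelEntry,
              beta_from: np.ndarray, rng, ws: _Workspace):
    """Carry shared-term coordinates across models; draw new terms from the
    destination prior conditional.  Returns (beta_to, shared_terms)."""
    terms_from = set(entry_from.design.term_slices)
    terms_to = set(entry_to.design.term_slices)
    shared = sorted(terms_from & terms_to, key=lambda t: (len(t), t))
    cols_from = entry_from.design.columns_for(shared)
    cols_to = entry_to.design.columns_for(shared)
    beta_to = np.zeros(entry_to.design.n_params)
    beta_to[cols_to] = beta_from[cols_from]
    new_cols = np.setdiff1d(np.arange(entry_to.design.n_params), cols_to)
    if new_cols.size:
        beta_to[new_cols] = ws.conditional_prior_draw(
            entry_to, cols_to, new_cols, beta_from[cols_from], rng)
    return beta_to, shared


@dataclass
class Proposal:
    move: str                     # 'add' | 'remove' | 'swap' | 'param' | 'skip'
    graph: Graph | None = None
    beta: np.ndarray | None = None
    log_edge_ratio: float = 0.0   # log q(reverse) - log q(forward), edges only
    shared_terms: list = field(default_factory=list)


def propose_move(graph: Graph, beta: np.ndarray, strategy: SearchStrategy,
                 T: TGammaMatrix | None, ws: _Workspace,
                 rng: np.random.Generator) -> Proposal:
    """Draw one proposal according to the strategy's move mix."""
    entry = ws.entry(graph)
    if rng.random() < strategy.parameter_prob:
        prop = beta + entry.prop_chol @ rng.standard_normal(beta.size)
        return Proposal(move="param", graph=graph, beta=prop)
    move = ("add", "remove", "swap")[rng.integers(3)]
    mw = strategy.mode_weights
    if T is None:
        T = TGammaMatrix.uniform(ws.table.spec.names)

    def draw(kind, g):
        cand = g.non_edges() if kind == "add" else g.sorted_edges()
        if not cand:
            return None
        if rng.random() < mw[1]:
            cands, probs = (edge_add_distribution(T, g) if kind == "add"
                            else edge_remove_distribution(T, g))
            return cands[rng.choice(len(cands), p=probs)]
        return cand[rng.integers(len(cand))]

    with np.errstate(divide="ignore"):
        if move == "add":
            e = draw("add", graph)
            if e is None:
                return Proposal(move="skip")
            new_graph = graph.add_edge(e)
            log_ratio = (np.log(_mixture_edge_prob(T, new_graph, e, "remove", mw))
                         - np.log(_mixture_edge_prob(T, graph, e, "add", mw)))
        elif move == "remove":
            e = draw("remove", graph)
            if e is None:
                return Proposal(move="skip")
            new_graph = graph.remove_edge(e)
            log_ratio = (np.log(_mixture_edge_prob(T, new_graph, e, "add", mw))
                         - np.log(_mixture_edge_prob(T, graph, e, "remove", mw)))
        else:
            e_r = draw("remove", graph)
            e_a = draw("add", graph)
            if e_r is None or e_a is None:
                return Proposal(move="skip")
            new_graph = graph.remove_edge(e_r).add_edge(e_a)
            fwd = (np.log(_mixture_edge_prob(T, graph, e_r, "remove", mw))
                   + np.log(_mixture_edge_prob(T, graph, e_a, "add", mw)))
            rev = (np.log(_mixture_edge_prob(T, new_graph, e_a, "remove", mw))
                   + np.log(_mixture_edge_prob(T, new_graph, e_r, "add", mw)))
            log_ratio = rev - fwd
    if not np.isfinite(log_ratio):
        # reverse move impossible (informed weight zero): auto-reject
        return Proposal(move="skip")
    new_entry = ws.entry(new_graph)
    new_beta, shared = _map_beta(entry, new_entry, beta, rng, ws)
    return Proposal(move=move, graph=new_graph, beta=new_beta,
                    log_edge_ratio=float(log_ratio), shared_terms=shared)


def acceptance_log_ratio(proposal: Proposal, graph: Graph, beta: np.ndarray,
                         ws: _Workspace) -> float:
    """Full log acceptance ratio of a proposal from (graph, beta)."""
    entry = ws.entry(graph)
    if proposal.move == "skip":
        return -np.inf
    new_entry = ws.entry(proposal.graph)
    ll_new = ws.log_likelihood(new_entry, proposal.beta)
    ll_old = ws.log_likelihood(entry, beta)
    if proposal.move == "param":
        return (ll_new + ws.log_prior(entry, proposal.beta)
                - ll_old - ws.log_prior(entry, beta))
    shared = proposal.shared_terms
    cols_old = entry.design.columns_for(shared)
    cols_new = new_entry.design.columns_for(shared)
    lp_new = ws.log_marginal_prior(new_entry, cols_new, proposal.beta[cols_new])
    lp_old = ws.log_marginal_prior(entry, cols_old, beta[cols_old])
    return ll_new - ll_old + lp_new - lp_old + proposal.log_edge_ratio


@dataclass
class RJConfig:
    iterations: int = 10000
    burnin: int = 1000
    seed: int | None = None
    start_edges: frozenset = frozenset()
    rw_scale: float = 1.0

    def validate(self):
        if self.iterations < 1 or self.burnin < 0:
            raise ValueError("iteration counts must be positive")


@dataclass
class RJChain:
    """Visited models and move bookkeeping of one reversible-jump run."""

    model_keys: list              # one frozen edge set per iteration
    move_types: np.ndarray        # '<U6'
    accepted: np.ndarray          # bool
    burnin: int
    spec: object

    @property
    def iterations(self) -> int:
        return len(self.model_keys)

    def visit_frequencies(self) -> dict:
        """Post-burn-in visit fraction per model (posterior model probabilities)."""
        kept = self.model_keys[self.burnin:]
        freqs: dict = {}
        for k in kept:
            freqs[k] = freqs.get(k, 0) + 1
        total = len(kept)
        return {k: v / total for k, v in freqs.items()}

    def top_model(self):
        freqs = self.visit_frequencies()
        return max(freqs, key=freqs.get)

    def first_hit_iteration(self, key=None) -> int:
        """First iteration (from the start of the run) visiting the model
        with the highest post-burn-in visit frequency."""
        if key is None:
            key = self.top_model()
        for it, k in enumerate(self.model_keys):
            if k == key:
                return it
        return -1

    def model_move_acceptance_rate(self) -> float:
        """Accepted model moves over attempted model moves."""
        is_model = self.move_types != "param"
        attempted = is_model.sum()
        if attempted == 0:
            return float("nan")
        return float(self.accepted[is_model].sum() / attempted)

    def overall_acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def summary(self) -> dict:
        freqs = self.visit_frequencies()
        top = sorted(freqs.items(), key=lambda kv: -kv[1])[:5]
        names = self.spec.names if self.spec is not None else None
        return {
            "model_move_acceptance_rate": self.model_move_acceptance_rate(),
            "overall_acceptance_rate": self.overall_acceptance_rate(),
            "first_hit_iteration": self.first_hit_iteration(),
            "top_models": [
                {"edges": sorted(list(k)), "probability": v} for k, v in top
            ],
        }


def run_search(table: ContingencyTable, strategy: SearchStrategy,
               T: TGammaMatrix | None, config: RJConfig,
               rng: np.random.Generator | None = None) -> RJChain:
    """Run the reversible-jump chain and return the visited-model record."""
    config.validate()
    if strategy.needs_tgamma and T is None:
        raise ValueError(f"strategy ({strategy.label}) requires a T-gamma matrix")
    if T is not None and T.P != table.spec.P:
        raise ValueError("T-gamma dimension does not match the factor spec")
    if rng is None:
        if config.seed is None:
            raise ValueError("a seed (or an explicit generator) is required")
        rng = np.random.default_rng(config.seed)
    ws = _Workspace(table, rw_scale=config.rw_scale)
    graph = Graph(table.spec.P, config.start_edges)
    entry = ws.entry(graph)
    # start at the prior mean perturbed toward the data via one mode-free step
    beta = np.zeros(entry.design.n_params)
    beta[0] = np.log(max(table.n, 1) / table.counts.size)
    total = config.burnin + config.iterations
    model_keys = []
    move_types = np.empty(total, dtype="<U6")
    accepted = np.zeros(total, dtype=bool)
    for it in range(total):
        prop = propose_move(graph, beta, strategy, T, ws, rng)
        if prop.move == "skip":
            move_types[it] = "skip"
        else:
            logr = acceptance_log_ratio(prop, graph, beta, ws)
            move_types[it] = prop.move
            if np.log(rng.random()) < logr:
                accepted[it] = True
                graph, beta = prop.graph, prop.beta
        model_keys.append(graph.edges)
    return RJChain(model_keys=model_keys, move_types=move_types,
                   accepted=accepted, burnin=config.burnin, spec=table.spec)
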