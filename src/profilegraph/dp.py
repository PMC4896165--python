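"""Dirichlet-process mixture of product multinomials with variable selection.

Subjects carry P categorical covariates.  A truncated stick-breaking DP
allocates subjects to clusters; within cluster c, covariate p follows a
multinomial with parameters phi_pc when its binary selection switch
gamma_pc = 1, and the fixed sample-wide marginal pi_p when gamma_pc = 0:

    P(x_p = x | z_i = c) = phi_pc(x)^gamma_pc * pi_p(x)^(1 - gamma_pc)

Switches are Bernoulli(rho_p) with a sparsity prior on rho_p that places a
point mass at zero: rho_p = 0 when w_p = 0 and rho_p ~ Beta(a_rho, b_rho)
when w_p = 1, w_p ~ Bernoulli(0.5).  Covariates with posterior median rho_p
near zero are marginally independent of all others and can be dropped from
a downstream log-linear analysis.

Sampling is a blocked Gibbs sweep (allocations, phi, gamma, rho/w,
sticks/alpha) on the truncated stick representation with V_C = 1 at the
truncation point, which makes every conditional exact.  Switches are
defined for all clusters up to the truncation; empty clusters contribute a
free Bernoulli(rho_p) draw that integrates out of rho's posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loglinear import FactorSpec


@dataclass
class DPConfig:
    """Tuning knobs of the clustering sampler.

    lambda_dir     Dirichlet hyperparameter for the phi rows (0.5 default).
    a_rho, b_rho   Beta hyperparameters of the selection probability.
    alpha          initial DP concentration; resampled unless fix_alpha.
    alpha_shape/rate   Gamma prior for the concentration parameter.
    truncation     initial number of stick-breaking clusters.
    max_truncation hard cap for adaptive truncation growth.
    init_groups    subjects start randomly allocated to this many groups.
    """

    iterations: int = 20000
    burnin: int = 40000
    thin: int = 1
    lambda_dir: float = 0.5
    a_rho: float = 1.0
    b_rho: float = 1.0
    alpha: float = 1.0
    fix_alpha: bool = False
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    truncation: int = 50
    max_truncation: int = 100
    init_groups: int = 10
    seed: int | None = None

    def validate(self):
        if self.iterations < 1 or self.burnin < 0 or self.thin < 1:
            raise ValueError("iteration counts must be positive")
        if self.truncation < 2 or self.max_truncation < self.truncation:
            raise ValueError("invalid truncation settings")
        if min(self.lambda_dir, self.a_rho, self.b_rho,
               self.alpha_shape, self.alpha_rate) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class ClusterState:
    """Full state of the sampler at one iteration."""

    z: np.ndarray                 # (n,) allocations
    V: np.ndarray                 # (C,) stick variables, V[C-1] = 1
    alpha: float
    phi: np.ndarray               # (P, C, Mmax) rows are probability vectors
    gamma: np.ndarray             # (P, C) in {0,1}
    rho: np.ndarray               # (P,)
    w: np.ndarray                 # (P,) in {0,1}
    pi: np.ndarray                # (P, Mmax) fixed marginal frequencies

    @property
    def psi(self) -> np.ndarray:
        """Stick weights psi_c = V_c prod_{l<c} (1 - V_l)."""
        one_minus = np.concatenate([[1.0], np.cumprod(1.0 - self.V[:-1])])
        return self.V * one_minus

    @property
    def n_clusters(self) -> int:
        return self.V.size

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.z, minlength=self.n_clusters)


@dataclass
class ClusterChain:
    """Post-burn-in snapshots of the clustering sampler.

    Arrays are indexed by kept iteration: z (T,n), gamma (T,P,C),
    sizes (T,C), rho (T,P), phi (T,P,C,Mmax) stored float32.
    """

    spec: FactorSpec
    z: np.ndarray
    gamma: np.ndarray
    sizes: np.ndarray
    rho: np.ndarray
    phi: np.ndarray
    pi: np.ndarray
    config: DPConfig = field(default=None, repr=False)

    @property
    def n_iterations(self) -> int:
        return self.z.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.z.shape[1]

    def median_rho(self) -> np.ndarray:
        """Posterior median selection probability per covariate."""
        return np.median(self.rho, axis=0)


def subject_likelihood(x_i: np.ndarray, c: int, state: ClusterState) -> float:
    """Likelihood of one subject's profile under cluster c.

    prod_p phi_pc(x_ip)^gamma_pc * pi_p(x_ip)^(1-gamma_pc).
    """
    x_i = np.asarray(x_i, dtype=int)
    P = x_i.size
    out = 1.0
    for p in range(P):
        if state.pi[p, x_i[p]] <= 0.0:
            raise ValueError("observed level has zero marginal frequency")
        if state.gamma[p, c]:
            out *= state.phi[p, c, x_i[p]]
        else:
            out *= state.pi[p, x_i[p]]
    return float(out)


def marginal_frequencies(data: np.ndarray, spec: FactorSpec) -> np.ndarray:
    """Observed sample frequencies pi_p(x), padded to the max level count."""
    data = np.asarray(data, dtype=int)
    n, P = data.shape
    mmax = max(spec.levels)
    pi = np.zeros((P, mmax))
    for p in range(P):
        counts = np.bincount(data[:, p], minlength=spec.levels[p])
        pi[p, : spec.levels[p]] = counts / n
    return pi


def _draw_dirichlet_rows(rng, alpha_matrix, level_mask):
    """Row-wise Dirichlet draws via gamma variates; masked levels stay 0."""
    g = rng.gamma(np.where(level_mask, alpha_matrix, 1.0))
    g = np.where(level_mask, g, 0.0)
    return g / g.sum(axis=-1, keepdims=True)


class _Sampler:
    """Workspace for the blocked Gibbs sweep (vectorized over clusters)."""

    def __init__(self, data, spec, config, rng):
        self.x = np.asarray(data, dtype=int)
        self.n, self.P = self.x.shape
        if self.P != spec.P:
            raise ValueError("data width does not match the factor spec")
        for p in range(self.P):
            if self.x[:, p].min() < 0 or self.x[:, p].max() >= spec.levels[p]:
                raise ValueError(f"levels of factor {spec.names[p]} out of range")
        self.spec = spec
        self.cfg = config
        self.rng = rng
        self.mmax = max(spec.levels)
        self.level_mask = np.zeros((self.P, self.mmax), dtype=bool)
        for p in range(self.P):
            self.level_mask[p, : spec.levels[p]] = True
        self.pi = marginal_frequencies(self.x, spec)
        self.log_pi_x = np.log(self.pi[np.arange(self.P)[None, :], self.x])  # (n,P)
        C = config.truncation
        z0 = rng.integers(0, min(config.init_groups, C), size=self.n)
        self.state = ClusterState(
            z=z0,
            V=self._init_sticks(C),
            alpha=config.alpha,
            phi=_draw_dirichlet_rows(
                rng, np.full((self.P, C, self.mmax), config.lambda_dir),
                self.level_mask[:, None, :]),
            gamma=np.ones((self.P, C), dtype=np.int8),
            rho=np.full(self.P, 0.5),
            w=np.ones(self.P, dtype=np.int8),
            pi=self.pi,
        )

    def _init_sticks(self, C):
        V = self.rng.beta(1.0, self.cfg.alpha, size=C)
        V[-1] = 1.0
        return V

    # --- conditional updates, in the fixed sweep order -------------------

    def update_allocations(self):
        st = self.state
        C = st.n_clusters
        log_phi = np.log(np.maximum(st.phi, 1e-300))  # (P,C,M)
        # log-likelihood of each subject under each cluster
        loglik = np.zeros((self.n, C))
        for p in range(self.P):
            lp = log_phi[p][:, self.x[:, p]]            # (C,n)
            contrib = np.where(st.gamma[p][:, None] == 1, lp,
                               self.log_pi_x[:, p][None, :])
            loglik += contrib.T
        logw = np.log(np.maximum(st.psi, 1e-300))[None, :] + loglik
        logw -= logw.max(axis=1, keepdims=True)
        wts = np.exp(logw)
        wts /= wts.sum(axis=1, keepdims=True)
        u = self.rng.random(self.n)
        st.z = (wts.cumsum(axis=1) < u[:, None]).sum(axis=1)

    def _level_counts(self):
        """(P, C, Mmax) counts of levels per cluster."""
        st = self.state
        C = st.n_clusters
        counts = np.zeros((self.P, C, self.mmax))
        for p in range(self.P):
            flat = st.z * self.mmax + self.x[:, p]
            counts[p] = np.bincount(flat, minlength=C * self.mmax).reshape(C, self.mmax)
        return counts

    def update_phi(self, counts):
        st = self.state
        # counts enter the conditional only where gamma = 1
        eff = np.where(st.gamma[:, :, None] == 1, counts, 0.0)
        alpha_post = self.cfg.lambda_dir + eff
        st.phi = _draw_dirichlet_rows(self.rng, alpha_post, self.level_mask[:, None, :])

    def update_gamma(self, counts):
        st = self.state
        log_phi = np.log(np.maximum(st.phi, 1e-300))
        log_pi = np.log(np.maximum(self.pi, 1e-300))
        # sum over member subjects of log phi - log pi, per (p, c)
        delta = np.einsum("pcm,pcm->pc", counts, log_phi - log_pi[:, None, :])
        with np.errstate(divide="ignore"):
            log_odds = (np.log(st.rho) - np.log1p(-np.minimum(st.rho, 1 - 1e-12)))[:, None] + delta
        prob = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
        prob[st.rho <= 0.0, :] = 0.0
        st.gamma = (self.rng.random(prob.shape) < prob).astype(np.int8)

    def update_rho(self):
        st = self.state
        C = st.n_clusters
        a, b = self.cfg.a_rho, self.cfg.b_rho
        s = st.gamma.sum(axis=1)
        from scipy.special import betaln
        for p in range(self.P):
            if s[p] > 0:
                st.w[p] = 1
            else:
                # marginalized two-term Bayes step: point mass vs Beta slab
                log_slab = betaln(a, b + C) - betaln(a, b)
                p1 = 1.0 / (1.0 + np.exp(-log_slab))  # prior odds 0.5 : 0.5
                st.w[p] = 1 if self.rng.random() < p1 else 0
            if st.w[p] == 1:
                st.rho[p] = self.rng.beta(a + s[p], b + C - s[p])
            else:
                st.rho[p] = 0.0

    def alpha_conditional(self, V):
        """Gamma(shape, rate) parameters of alpha's conjugate conditional
        given the free sticks (the pinned V_C = 1 stick is excluded)."""
        shape = self.cfg.alpha_shape + (V.size - 1)
        rate = self.cfg.alpha_rate - np.log1p(-V[:-1]).sum()
        return shape, rate

    def update_sticks_alpha(self):
        st = self.state
        sizes = st.cluster_sizes()
        tail = sizes[::-1].cumsum()[::-1]
        above = np.concatenate([tail[1:], [0]])
        V = self.rng.beta(1.0 + sizes[:-1], st.alpha + above[:-1])
        st.V = np.concatenate([np.minimum(V, 1 - 1e-12), [1.0]])
        if not self.cfg.fix_alpha:
            shape, rate = self.alpha_conditional(st.V)
            st.alpha = self.rng.gamma(shape, 1.0 / rate)

    def maybe_grow_truncation(self):
        st = self.state
        C = st.n_clusters
        if C >= self.cfg.max_truncation:
            return
        if st.cluster_sizes()[-1] == 0:
            return
        grow = min(5, self.cfg.max_truncation - C)
        newV = self.rng.beta(1.0, st.alpha, size=grow)
        st.V = np.concatenate([st.V[:-1], [st.V[-1]], newV])
        st.V[-1] = 1.0
        # the stick that was pinned at 1 becomes free
        st.V[C - 1] = self.rng.beta(1.0, st.alpha)
        new_phi = _draw_dirichlet_rows(
            self.rng, np.full((self.P, grow, self.mmax), self.cfg.lambda_dir),
            self.level_mask[:, None, :])
        st.phi = np.concatenate([st.phi, new_phi], axis=1)
        new_gamma = (self.rng.random((self.P, grow)) < st.rho[:, None]).astype(np.int8)
        st.gamma = np.concatenate([st.gamma, new_gamma], axis=1)

    def sweep(self):
        self.update_allocations()
        counts = self._level_counts()
        self.update_phi(counts)
        self.update_gamma(counts)
        self.update_rho()
        self.update_sticks_alpha()
        self.maybe_grow_truncation()


def run_chain(data: np.ndarray, spec: FactorSpec, config: DPConfig,
              rng: np.random.Generator | None = None) -> ClusterChain:
    """Run the blocked Gibbs sampler and return post-burn-in snapshots.

    The sweep order is fixed: allocations, phi, gamma, rho/w, sticks/alpha.
    Marginal frequencies pi_p are fixed at the observed sample frequencies
    throughout.  With a seeded generator the run is reproducible bit for bit.
    """
    config.validate()
    if rng is None:
        if config.seed is None:
            raise ValueError("a seed (or an explicit generator) is required")
        rng = np.random.default_rng(config.seed)
    s = _Sampler(data, spec, config, rng)
    kept_z, kept_gamma, kept_sizes, kept_rho, kept_phi = [], [], [], [], []
    total = config.burnin + config.iterations
    for it in range(total):
        s.sweep()
        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            st = s.state
            kept_z.append(st.z.astype(np.int32).copy())
            kept_gamma.append(st.gamma.copy())
            kept_sizes.append(st.cluster_sizes().astype(np.int32))
            kept_rho.append(st.rho.copy())
            kept_phi.append(st.phi.astype(np.float32))
    C = max(a.shape[1] for a in kept_gamma)

    def _pad(arr, width, axis):
        pad = [(0, 0)] * arr.ndim
        pad[axis] = (0, width - arr.shape[axis])
        return np.pad(arr, pad)

    return ClusterChain(
        spec=spec,
        z=np.stack(kept_z),
        gamma=np.stack([_pad(g, C, 1) for g in kept_gamma]),
        sizes=np.stack([_pad(c, C, 0) for c in kept_sizes]),
        rho=np.stack(kept_rho),
        phi=np.stack([_pad(f, C, 1) for f in kept_phi]),
        pi=s.pi,
        config=config,
    )
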