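"""Posterior summaries of the clustering chain.

Produces the co-clustering similarity matrix, a representative partition
(least-squares/Dahl criterion against the similarity matrix, candidates from
k-medoids on the dissimilarity 1 - S), and per-cluster covariate profiles
coded with '<', '0', '>' symbols: for each covariate level the 95% credible
interval of (cluster-level probability - sample frequency) determines the
symbol, with cluster-level probabilities averaged over members so that
unselected covariates (gamma = 0) contribute the fixed marginal and code '0'.
All summaries are invariant to cluster relabelling in the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .dp import ClusterChain


def similarity(chain: ClusterChain) -> np.ndarray:
    """n x n co-clustering fractions over the stored iterations."""
    if chain.n_iterations < 1:
        raise ValueError("chain has no stored iterations")
    T, n = chain.z.shape
    C = int(chain.z.max()) + 1
    rows = np.tile(np.arange(n), T)
    cols = (chain.z + (np.arange(T) * C)[:, None]).ravel()
    Z = sparse.csr_matrix(
        (np.ones(T * n, dtype=np.float32), (rows, cols)), shape=(n, T * C)
    )
    S = np.asarray((Z @ Z.T).todense()) / T
    np.fill_diagonal(S, 1.0)
    return S


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 50) -> np.ndarray:
    """Plain PAM-style k-medoids on a precomputed dissimilarity matrix."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        dist = D[:, medoids].min(axis=1)
        total = dist.sum()
        if total <= 0:
            medoids.append(int(rng.integers(n)))
        else:
            medoids.append(int(rng.choice(n, p=dist / total)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[j] = members[np.argmin(within)]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def _dahl_score(S: np.ndarray, labels: np.ndarray) -> float:
    """Least-squares distance between a partition and the similarity matrix."""
    same = labels[:, None] == labels[None, :]
    return float(np.sum((S - same) ** 2))


def representative_partition(S: np.ndarray, k_range=range(1, 11),
                             seed: int = 0) -> np.ndarray:
    """Partition minimizing sum_{ij} (S_ij - 1[same cluster])^2.

    Candidates come from k-medoids on 1 - S for each k in k_range; the
    candidate with the smallest least-squares criterion wins.
    """
    rng = np.random.default_rng(seed)
    D = 1.0 - S
    best_labels, best_score = None, np.inf
    for k in k_range:
        if k < 1 or k > S.shape[0]:
            continue
        labels = (np.zeros(S.shape[0], dtype=int) if k == 1
                  else _kmedoids(D, k, rng))
        score = _dahl_score(S, labels)
        if score < best_score:
            best_labels, best_score = labels, score
    return best_labels


@dataclass
class SummaryProfile:
    """Representative-cluster profiles: symbols, sizes and median rho."""

    symbols: np.ndarray       # (n_rep_clusters, P, Mmax) of '<', '0', '>'
    cluster_sizes: np.ndarray
    median_rho: np.ndarray
    spec: object

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the published layout: one symbol string per cell."""
        rows = {}
        rows["Median(rho_p)"] = [f"{m:.2f}" for m in self.median_rho]
        for c in range(self.symbols.shape[0]):
            label = f"Cluster {c + 1} ({self.cluster_sizes[c]})"
            rows[label] = [
                "".join(self.symbols[c, p, : self.spec.levels[p]])
                for p in range(self.spec.P)
            ]
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(self.spec.names))


def summarize_profiles(chain: ClusterChain, partition: np.ndarray,
                       data: np.ndarray, ci: float = 0.95) -> SummaryProfile:
    """Symbol-coded profiles of the representative clusters.

    Per iteration the probability of level m for representative cluster A is
    the member-averaged selection-weighted probability
    gamma * phi + (1 - gamma) * pi; the credible interval of its difference
    from the fixed sample frequency decides '<' (CI below 0), '>' (CI above
    0) or '0' (CI covers 0).
    """
    data = np.asarray(data, dtype=int)
    T, n = chain.z.shape
    P = chain.spec.P
    mmax = chain.pi.shape[1]
    partition = np.asarray(partition)
    groups = np.unique(partition)
    sizes = np.array([(partition == g).sum() for g in groups])
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    onehot = partition[:, None] == groups[None, :]        # (n, G)
    weights = onehot / sizes[None, :]
    diffs = np.empty((T, len(groups), P, mmax), dtype=np.float32)
    for t in range(T):
        zt = chain.z[t]
        for p in range(P):
            g_t = chain.gamma[t, p, zt].astype(np.float32)     # (n,)
            phi_t = chain.phi[t, p, zt]                        # (n, Mmax)
            prob = g_t[:, None] * phi_t + (1.0 - g_t[:, None]) * chain.pi[p][None, :]
            diffs[t, :, p, :] = weights.T @ prob - chain.pi[p][None, :]
    lo = np.quantile(diffs, lo_q, axis=0)
    hi = np.quantile(diffs, hi_q, axis=0)
    # tolerance so a difference that is zero up to round-off codes '0'
    tol = 1e-6
    symbols = np.full((len(groups), P, mmax), "0", dtype="<U1")
    symbols[hi < -tol] = "<"
    symbols[lo > tol] = ">"
    return SummaryProfile(symbols=symbols, cluster_sizes=sizes,
                          median_rho=chain.median_rho(), spec=chain.spec)
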