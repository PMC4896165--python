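"""The T-gamma edge-evidence matrix.

Translates the clustering chain's variable-selection switches into evidence
about log-linear edges: per iteration, every cluster with more than one
subject contributes gamma_p1,c * gamma_p2,c for each covariate pair,
weighted by cluster size; the accumulated matrix is rescaled to maximum 1.
A small entry flags a pair unlikely to be joined by an edge in a highly
supported graphical model (small entries are specific to non-edges); large
entries are NOT reliable evidence of edge presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp import ClusterChain
from .loglinear import count_cells, count_graphical_models, FactorSpec


@dataclass
class TGammaMatrix:
    """Symmetric P x P matrix of rescaled co-selection evidence in [0, 1]."""

    values: np.ndarray
    names: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("T-gamma matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("T-gamma matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1 + 1e-9):
            raise ValueError("T-gamma entries must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def P(self) -> int:
        return self.values.shape[0]

    def entry(self, p1: int, p2: int) -> float:
        return float(self.values[p1, p2])

    @classmethod
    def uniform(cls, names) -> "TGammaMatrix":
        P = len(names)
        v = np.ones((P, P)) - np.eye(P)
        return cls(values=v, names=tuple(names))


def build_tgamma(chain: ClusterChain) -> TGammaMatrix:
    """Accumulate cluster-size-weighted switch products over the chain.

    Clusters of size <= 1 are excluded.  The result is invariant to
    iteration order and rescaled so its largest entry is 1 (an all-zero
    accumulation is returned as-is).
    """
    if chain.gamma is None or chain.gamma.size == 0:
        raise ValueError("chain carries no selection switches")
    T, P, C = chain.gamma.shape
    acc = np.zeros((P, P))
    for t in range(T):
        w = chain.sizes[t].astype(float)
        w[w <= 1] = 0.0
        G = chain.gamma[t].astype(float)          # (P, C)
        acc += (G * w[None, :]) @ G.T
    np.fill_diagonal(acc, 0.0)
    mx = acc.max()
    if mx > 0:
        acc /= mx
    return TGammaMatrix(values=acc, names=chain.spec.names)


@dataclass
class ScreeningResult:
    """Covariates kept/dropped by the marginal-independence screen."""

    kept: list
    dropped: list
    full_models: int
    full_cells: int
    reduced_models: int
    reduced_cells: int


def screen_covariates(rho_medians, spec: FactorSpec,
                      threshold: float = 0.15) -> ScreeningResult:
    """Drop covariates whose posterior median selection probability is below
    the threshold; such covariates are marginally independent of the rest
    and cannot form edges, so the log-linear stage runs on the reduced set.

    Also reports the model-space bookkeeping: graph and cell counts before
    and after the reduction.
    """
    rho_medians = np.asarray(rho_medians, dtype=float)
    if rho_medians.size != spec.P:
        raise ValueError("need one median per covariate")
    kept = [spec.names[p] for p in range(spec.P) if rho_medians[p] >= threshold]
    dropped = [n for n in spec.names if n not in kept]
    kept_idx = [spec.index(n) for n in kept]
    reduced = FactorSpec(
        names=tuple(kept), levels=tuple(spec.levels[i] for i in kept_idx)
    ) if kept else None
    return ScreeningResult(
        kept=kept,
        dropped=dropped,
        full_models=count_graphical_models(spec.P),
        full_cells=count_cells(spec),
        reduced_models=count_graphical_models(len(kept)) if kept else 1,
        reduced_cells=count_cells(reduced) if reduced else 1,
    )
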