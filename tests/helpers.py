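"""Shared helpers for assembling small clustering chains in tests."""

import numpy as np

import profilegraph as pg
from profilegraph.dp import ClusterChain, DPConfig


def make_chain(z, gamma, phi, pi, levels=None):
    """Assemble a ClusterChain from explicit arrays (T, n) / (T, P, C) ..."""
    z = np.asarray(z, dtype=np.int32)
    gamma = np.asarray(gamma, dtype=np.int8)
    phi = np.asarray(phi, dtype=np.float32)
    pi = np.asarray(pi, dtype=float)
    T, P, C = gamma.shape
    sizes = np.stack([np.bincount(zt, minlength=C) for zt in z]).astype(np.int32)
    if levels is None:
        levels = (pi.shape[1],) * P
    spec = pg.FactorSpec(names=tuple(chr(65 + p) for p in range(P)),
                         levels=tuple(levels))
    rho = gamma.mean(axis=2, dtype=float)
    return ClusterChain(spec=spec, z=z, gamma=gamma, sizes=sizes, rho=rho,
                        phi=phi, pi=pi, config=DPConfig())
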