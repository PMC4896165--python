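"""File formats: covariate matrices, long-format contingency tables,
T-gamma matrices and clustering chains.

All formats are plain text.  Covariate data is a CSV with one header row of
covariate names and integer-coded levels 0..Mp-1.  Contingency tables are
long-format CSV: one column per factor plus a final ``count`` column;
missing cells are zero-filled on read (with a warning).  T-gamma matrices
are labelled square CSV with the upper triangle populated and mirrored on
read.  Chains round-trip through gzipped JSON-lines plus a CSV of the
per-iteration selection-probability draws.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dp import ClusterChain, DPConfig
from .loglinear import ContingencyTable, FactorSpec, count_cells
from .tgamma import TGammaMatrix


def write_covariates(data: np.ndarray, spec: FactorSpec, path) -> None:
    pd.DataFrame(np.asarray(data, dtype=int),
                 columns=list(spec.names)).to_csv(path, index=False)


def read_covariates(path, levels: tuple | None = None):
    """Read a covariate CSV; returns (data, spec).

    Levels default to 1 + the observed maximum per column.
    """
    df = pd.read_csv(path)
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.floor(vals)):
                raise ValueError(f"column {col!r} has non-integer levels")
            df[col] = vals.astype(int)
        if df[col].min() < 0:
            raise ValueError(f"column {col!r} has negative levels")
    data = df.to_numpy(dtype=int)
    if levels is None:
        levels = tuple(int(m) for m in data.max(axis=0) + 1)
    else:
        for j, col in enumerate(df.columns):
            if data[:, j].max() >= levels[j]:
                bad = int(np.argmax(data[:, j] >= levels[j]))
                raise ValueError(
                    f"column {col!r}, row {bad}: level out of range")
    spec = FactorSpec(names=tuple(df.columns), levels=tuple(levels))
    return data, spec


def write_table(table: ContingencyTable, path) -> None:
    from .loglinear import cell_levels
    levels = cell_levels(table.spec)
    df = pd.DataFrame(levels, columns=list(table.spec.names))
    df["count"] = table.counts.astype(int)
    df.to_csv(path, index=False)


def read_table(path, spec: FactorSpec | None = None) -> ContingencyTable:
    df = pd.read_csv(path)
    if "count" not in df.columns:
        raise ValueError("contingency CSV needs a 'count' column")
    names = [c for c in df.columns if c != "count"]
    lv = df[names].to_numpy()
    if not np.all(lv == np.floor(lv)):
        raise ValueError("factor levels must be integers")
    lv = lv.astype(int)
    if spec is None:
        spec = FactorSpec(names=tuple(names),
                          levels=tuple(int(m) for m in lv.max(axis=0) + 1))
    ncells = count_cells(spec)
    counts = np.zeros(ncells)
    idx = np.ravel_multi_index(lv.T, spec.levels)
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate cells in contingency CSV")
    counts[idx] = df["count"].to_numpy()
    if idx.size < ncells:
        warnings.warn(f"{ncells - idx.size} cells missing; filled with zeros")
    return ContingencyTable(spec=spec, counts=counts)


def write_tgamma(T: TGammaMatrix, path) -> None:
    v = T.values.copy()
    v[np.tril_indices(T.P)] = np.nan
    pd.DataFrame(v, index=list(T.names), columns=list(T.names)).to_csv(path)


def read_tgamma(path) -> TGammaMatrix:
    df = pd.read_csv(path, index_col=0)
    names = tuple(df.columns)
    v = df.to_numpy(dtype=float)
    if v.shape[0] != v.shape[1]:
        raise ValueError("T-gamma matrix must be square")
    mask = ~np.isnan(v)
    both = mask & mask.T
    if np.any(both & ~np.isclose(np.where(both, v, 0),
                                 np.where(both, v.T, 0))):
        raise ValueError("T-gamma matrix entries are asymmetric")
    v = np.where(np.isnan(v), 0.0, v)
    v = np.maximum(v, v.T)
    np.fill_diagonal(v, 0.0)
    return TGammaMatrix(values=v, names=names)


def write_chain(chain: ClusterChain, path, rho_csv=None) -> None:
    """Chain snapshots as gzipped JSON-lines (header line + one line per
    stored iteration); optionally the rho draws as CSV."""
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        header = {
            "names": list(chain.spec.names),
            "levels": list(chain.spec.levels),
            "pi": chain.pi.tolist(),
        }
        fh.write(json.dumps(header) + "\n")
        for t in range(chain.n_iterations):
            rec = {
                "z": chain.z[t].tolist(),
                "gamma": chain.gamma[t].tolist(),
                "sizes": chain.sizes[t].tolist(),
                "rho": chain.rho[t].tolist(),
                "phi": np.round(chain.phi[t], 6).tolist(),
            }
            fh.write(json.dumps(rec) + "\n")
    if rho_csv is not None:
        pd.DataFrame(chain.rho, columns=list(chain.spec.names)).to_csv(
            rho_csv, index=False)


def read_chain(path) -> ClusterChain:
    with gzip.open(path, "rt") as fh:
        header = json.loads(fh.readline())
        z, gamma, sizes, rho, phi = [], [], [], [], []
        for line in fh:
            rec = json.loads(line)
            z.append(rec["z"])
            gamma.append(rec["gamma"])
            sizes.append(rec["sizes"])
            rho.append(rec["rho"])
            phi.append(rec["phi"])
    spec = FactorSpec(names=tuple(header["names"]),
                      levels=tuple(header["levels"]))
    return ClusterChain(
        spec=spec,
        z=np.asarray(z, dtype=np.int32),
        gamma=np.asarray(gamma, dtype=np.int8),
        sizes=np.asarray(sizes, dtype=np.int32),
        rho=np.asarray(rho, dtype=float),
        phi=np.asarray(phi, dtype=np.float32),
        pi=np.asarray(header["pi"], dtype=float),
        config=DPConfig(),
    )
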