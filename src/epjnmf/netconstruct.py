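"""Co-expression / co-methylation network construction.

Gene profile matrices (genes x samples) are turned into weighted
undirected networks in two steps: (1) the gene-gene Pearson correlation
matrix; (2) a PCIT-style trio filter that removes edges whose correlation
cannot be defended against any third gene, keeping the absolute
correlation of the survivors as edge weight. For every gene trio
(x, y, z) the first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

are computed, the local tolerance for testing edge (x, y) against z is
the average ratio of partial to direct correlation over the two competing
edges,

    eps_z = ( |r_xz.y / r_xz| + |r_yz.x / r_yz| ) / 2 ,

and edge (x, y) fails the trio when |r_xy| < eps_z |r_xz| and
|r_xy| < eps_z |r_yz|, i.e. it is the weakest of the trio under the
tolerance. An edge is removed only if it fails in every informative trio;
trios with a vanishing direct correlation in a ratio denominator are
skipped as uninformative. The filter never adds edges and is invariant to
positive rescaling of any gene's profile.

Pairing a co-expression layer with a co-methylation layer over the shared
genes yields the two-layer network in which epigenetic modules are sought
as common modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .multinet import MultiNetwork

logger = logging.getLogger(__name__)

_EPS = 1e-12
#: minimum shared genes for a meaningful joint network
MIN_SHARED_GENES = 10


@dataclass
class ProfileMatrix:
    """Gene profiles: a genes x samples real matrix with labels."""

    values: np.ndarray
    gene_labels: list[str]
    sample_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile values must be a 2-D matrix")
        g, s = self.values.shape
        if len(self.gene_labels) != g or len(self.sample_labels) != s:
            raise ValueError("label lengths do not match the value matrix")
        if np.any(~np.isfinite(self.values)):
            raise ValueError(
                "profiles contain missing values; drop or impute before use"
            )
        if s < 3:
            raise ValueError(f"need >= 3 samples for correlation, got {s}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        """Load a TSV (genes in rows, header of sample IDs).

        Rows containing missing values are dropped and logged; imputation
        is intentionally not performed.
        """
        t = pd.read_csv(path, sep="\t", index_col=0)
        bad = t.isna().any(axis=1)
        if bad.any():
            logger.warning(
                "dropping %d gene(s) with missing values", int(bad.sum())
            )
            t = t.loc[~bad]
        return cls(
            values=t.to_numpy(dtype=float),
            gene_labels=[str(x) for x in t.index],
            sample_labels=[str(x) for x in t.columns],
        )


def correlation_network(profiles: ProfileMatrix) -> np.ndarray:
    """Gene x gene Pearson correlation matrix with zeroed diagonal.

    Zero-variance genes get all-zero correlations (with a warning).
    """
    vals = profiles.values
    sd = vals.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); correlations set to 0",
            stacklevel=2,
        )
    safe = np.where(flat[:, None], 0.0, vals - vals.mean(axis=1, keepdims=True))
    denom = np.where(flat, 1.0, sd) * np.sqrt(vals.shape[1])
    Z = safe / denom[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    R[flat, :] = 0.0
    R[:, flat] = 0.0
    np.fill_diagonal(R, 0.0)
    return R


def _partial(r_ab, r_ac, r_bc):
    """First-order partial correlation r_ab.c; 0 where the denominator degenerates."""
    d2 = (1.0 - r_ac**2) * (1.0 - r_bc**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r_ab - r_ac * r_bc) / np.sqrt(np.maximum(d2, 0.0))
    return np.where(d2 <= _EPS, 0.0, out)


def pcit_filter(corr: np.ndarray) -> np.ndarray:
    """PCIT-style trio filter; returns a non-negative weighted adjacency.

    See the module docstring for the decision rule. Surviving edges carry
    weight |r|; pairs with r = 0 never gain an edge.
    """
    R = np.asarray(corr, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n) or not np.allclose(R, R.T):
        raise ValueError("corr must be a symmetric square matrix")
    if np.any(np.diag(R) != 0):
        raise ValueError("corr must have a zero diagonal")
    absR = np.abs(R)
    if np.any(absR >= 1.0 - _EPS):
        warnings.warn(
            "perfectly correlated gene pair(s); their partial correlations "
            "are treated as 0",
            stacklevel=2,
        )

    # failed[x, y]: has (x, y) failed every informative trio so far?
    failed = np.ones((n, n), dtype=bool)
    informative = np.zeros((n, n), dtype=bool)
    for z in range(n):
        rxz = R[:, z][:, None]  # broadcast over y
        ryz = R[z, :][None, :]
        rxy = R
        pc_xz_y = _partial(rxz, rxy, ryz)
        pc_yz_x = _partial(ryz, rxy, rxz)
        with np.errstate(divide="ignore", invalid="ignore"):
            eps_z = 0.5 * (np.abs(pc_xz_y / rxz) + np.abs(pc_yz_x / ryz))
        valid = (np.abs(rxz) > _EPS) & (np.abs(ryz) > _EPS)
        idx = np.arange(n)
        valid[idx == z, :] = False
        valid[:, idx == z] = False
        valid[idx[:, None] == idx[None, :]] = False
        fails = (absR < eps_z * np.abs(rxz)) & (absR < eps_z * np.abs(ryz))
        informative |= valid
        failed &= np.where(valid, fails, True)

    removed = failed & informative  # edges with no informative trio survive
    W = np.where(removed, 0.0, absR)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def build_multinetwork(
    expr: ProfileMatrix, meth: ProfileMatrix
) -> MultiNetwork:
    """Two-layer network: filtered co-expression plus co-methylation.

    Profiles are restricted to the (sorted) shared gene set; fewer than
    ``MIN_SHARED_GENES`` shared genes is an error.
    """
    shared = sorted(set(expr.gene_labels) & set(meth.gene_labels))
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} shared gene(s); need >= {MIN_SHARED_GENES}"
        )
    logger.info("building 2-layer network on %d shared genes", len(shared))

    def restrict(p: ProfileMatrix) -> ProfileMatrix:
        pos = {g: i for i, g in enumerate(p.gene_labels)}
        rows = [pos[g] for g in shared]
        return ProfileMatrix(
            values=p.values[rows], gene_labels=shared, sample_labels=p.sample_labels
        )

    layers = [
        pcit_filter(correlation_network(restrict(p))) for p in (expr, meth)
    ]
    return MultiNetwork(layers, vertex_labels=shared)
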