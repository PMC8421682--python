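"""Partition comparison (NMI) and per-module diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multinet import (
    MultiNetwork,
    Partition,
    module_density,
    multi_connectivity,
)


@dataclass(frozen=True)
class ContingencyTable:
    """Overlap counts N_ij = |C_i ∩ C*_j| between two partitions."""

    N: np.ndarray

    @property
    def row_sums(self) -> np.ndarray:
        return self.N.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.N.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.N.sum())


def contingency(P: Partition, Pstar: Partition) -> ContingencyTable:
    """|P| x |P*| table of module overlap counts."""
    if P.n != Pstar.n:
        raise ValueError(f"partition sizes differ: {P.n} vs {Pstar.n}")
    N = np.zeros((P.k, Pstar.k), dtype=int)
    np.add.at(N, (P.assignment - 1, Pstar.assignment - 1), 1)
    return ContingencyTable(N=N)


def nmi(P: Partition, Pstar: Partition) -> float:
    """Normalized mutual information between two hard partitions.

        NMI = -2 Σ_ij N_ij log(N_ij N / (N_i. N_.j))
              / [Σ_i N_i. log(N_i./N) + Σ_j N_.j log(N_.j/N)]

    i.e. mutual information normalized by the arithmetic mean of the two
    partition entropies. Natural logarithms are used (the value is
    base-invariant); 0·log 0 is taken as 0. Equals 1 iff the partitions
    are identical up to module relabeling, and 0 for independent ones.
    When both partitions are the trivial single module (zero denominator)
    the value is defined as 1, since the partitions are then equal.
    """
    table = contingency(P, Pstar)
    N = table.N.astype(float)
    n = table.total
    a = table.row_sums.astype(float)
    b = table.col_sums.astype(float)

    denom = np.sum(a * np.log(a / n)) + np.sum(b * np.log(b / n))
    if denom == 0.0:  # both partitions trivial
        return 1.0 if P.k == Pstar.k == 1 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = N * np.log(N * n / np.outer(a, b))
    num = -2.0 * np.nansum(terms)
    return float(num / denom)


def module_diagnostics(net: MultiNetwork, p: Partition) -> pd.DataFrame:
    """Per-module size, per-layer edge density, and multi-connectivity."""
    rows = []
    for j, members in enumerate(p.modules(), start=1):
        row: dict[str, float] = {"module": j, "size": len(members)}
        for m in range(net.M):
            row[f"density_layer{m + 1}"] = module_density(net, m, members)
        row["multi_connectivity"] = multi_connectivity(net, members)
        rows.append(row)
    return pd.DataFrame(rows)
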