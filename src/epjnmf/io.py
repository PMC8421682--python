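"""Readers and writers for networks, partitions and profile matrices.

All formats are plain TSV:

* weighted edge lists — three columns ``source  target  weight``, one file
  per layer, no header;
* dense adjacency — square matrix with a header row and a leading label
  column;
* partition table — two columns ``vertex_label  module_id`` with module
  ids in ``1..k``;
* profile matrix — genes in rows, header row of sample IDs, leading
  column of gene labels.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .multinet import MultiNetwork, Partition

logger = logging.getLogger(__name__)


def read_edgelists(
    paths: Sequence[str | Path],
) -> MultiNetwork:
    """Load one weighted edge-list file per layer into a MultiNetwork.

    The vertex set is the union of labels over all layers, ordered
    lexicographically; the same order is used for every layer. Duplicate
    rows for a pair overwrite (last wins); both orientations are set.
    """
    tables = [
        pd.read_csv(p, sep="\t", header=None, names=["source", "target", "weight"])
        for p in paths
    ]
    labels: set[str] = set()
    for t in tables:
        labels.update(t["source"].astype(str))
        labels.update(t["target"].astype(str))
    order = sorted(labels)
    index = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    layers = []
    for t in tables:
        W = np.zeros((n, n))
        src = t["source"].astype(str).map(index).to_numpy()
        dst = t["target"].astype(str).map(index).to_numpy()
        w = t["weight"].to_numpy(dtype=float)
        W[src, dst] = w
        W[dst, src] = w
        layers.append(W)
    return MultiNetwork(layers, vertex_labels=order)


def write_edgelist(path: str | Path, W: np.ndarray, labels: Sequence[str]) -> None:
    """Write the upper triangle of a symmetric adjacency as a TSV edge list."""
    i, j = np.nonzero(np.triu(W, k=1))
    pd.DataFrame(
        {
            "source": [labels[a] for a in i],
            "target": [labels[b] for b in j],
            "weight": W[i, j],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_adjacency(paths: Sequence[str | Path]) -> MultiNetwork:
    """Load dense labelled adjacency TSVs (one per layer) into a MultiNetwork.

    All files must carry identical label sets; rows/columns are reordered
    to the lexicographic label order shared across layers.
    """
    frames = [pd.read_csv(p, sep="\t", index_col=0) for p in paths]
    order = sorted(str(x) for x in frames[0].index)
    layers = []
    for k, f in enumerate(frames):
        f.index = f.index.astype(str)
        f.columns = f.columns.astype(str)
        if sorted(f.index) != order or sorted(f.columns) != order:
            raise ValueError(f"layer file {k} has a different label set")
        layers.append(f.loc[order, order].to_numpy(dtype=float))
    return MultiNetwork(layers, vertex_labels=order)


def write_partition(
    path: str | Path, p: Partition, labels: Sequence[str] | None = None
) -> None:
    """Write a partition as a two-column TSV (vertex_label, module_id)."""
    if labels is None:
        labels = [f"v{i}" for i in range(p.n)]
    if len(labels) != p.n:
        raise ValueError("label count does not match partition size")
    pd.DataFrame({"vertex": list(labels), "module": p.assignment}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_partition(
    path: str | Path, labels: Sequence[str] | None = None
) -> tuple[Partition, list[str]]:
    """Read a partition TSV; returns the partition and its vertex labels.

    If ``labels`` is given, rows are aligned to that order; otherwise the
    file's lexicographic label order is used.
    """
    t = pd.read_csv(path, sep="\t", header=None, names=["vertex", "module"])
    t["vertex"] = t["vertex"].astype(str)
    t = t.set_index("vertex")
    order = sorted(t.index) if labels is None else [str(x) for x in labels]
    try:
        a = t.loc[order, "module"].to_numpy(dtype=int)
    except KeyError as e:
        raise ValueError(f"partition file is missing vertices: {e}") from e
    return Partition(assignment=a), list(order)
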