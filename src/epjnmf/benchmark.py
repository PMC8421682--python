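"""Planted-partition (GN-style) benchmarks for multilayer networks.

Each layer is an independent realization of the classic four-community
benchmark generalized to arbitrary size: n vertices split into q
equal-size communities, expected per-vertex degree fixed (16 in the
classic setup), of which ``z_out`` edges on average leave the vertex's own
community. Edges are sampled independently with

    p_in  = (degree - z_out) / (n/q - 1),
    p_out = z_out / (n - n/q),

so the expected degree equals ``degree`` for every noise level. Larger
``z_out`` buries the planted structure in noise.

Two multilayer variants mirror the standard evaluation protocol:
*homogeneous* nets (all layers share one z_out) and *heterogeneous* nets
(layer 1 at a fixed z_out, remaining layers at a second, varying level).
All layers share the planted partition; only the noise realization and,
for heterogeneous nets, the noise level differ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .multinet import MultiNetwork, Partition

__all__ = ["GnConfig", "generate_snapshot", "generate_homo_net", "generate_heter_net"]


@dataclass(frozen=True)
class GnConfig:
    """Parameters of the multilayer planted-partition benchmark.

    ``z_out`` may be a single number (shared by all layers) or one value
    per layer. The expected per-vertex degree is held at ``degree``
    regardless of ``z_out``.
    """

    n: int = 128
    q: int = 4
    degree: float = 16.0
    z_out: float | tuple[float, ...] = 1.0
    M: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n % self.q:
            raise ValueError(f"n={self.n} not divisible by q={self.q}")
        if self.M < 1:
            raise ValueError("at least one layer is required")
        z = self.z_out
        if np.ndim(z) == 0:
            z = (float(z),) * self.M
        else:
            z = tuple(float(v) for v in z)
            if len(z) != self.M:
                raise ValueError(f"{len(z)} z_out values for M={self.M} layers")
        object.__setattr__(self, "z_out", z)
        for zv in z:
            p_in, p_out = self.edge_probs(zv)
            if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
                raise ValueError(
                    f"z_out={zv} with degree={self.degree} gives edge "
                    f"probabilities outside [0, 1] (p_in={p_in:.3g}, "
                    f"p_out={p_out:.3g})"
                )

    @property
    def community_size(self) -> int:
        return self.n // self.q

    def edge_probs(self, z_out: float) -> tuple[float, float]:
        """(p_in, p_out) realizing expected degree at noise level z_out."""
        s = self.community_size
        p_in = (self.degree - z_out) / (s - 1)
        p_out = z_out / (self.n - s) if self.n > s else 0.0
        return p_in, p_out

    def planted_partition(self) -> Partition:
        return Partition(
            assignment=np.repeat(np.arange(1, self.q + 1), self.community_size)
        )


def generate_snapshot(cfg: GnConfig, layer: int) -> tuple[np.ndarray, Partition]:
    """Sample one 0/1 adjacency for ``layer`` plus the planted partition.

    The layer's RNG stream is derived from ``(cfg.seed, layer)`` so layers
    are mutually independent yet individually reproducible.
    """
    if not 0 <= layer < cfg.M:
        raise IndexError(f"layer index {layer} out of range 0..{cfg.M - 1}")
    p_in, p_out = cfg.edge_probs(cfg.z_out[layer])
    part = cfg.planted_partition()
    same = part.assignment[:, None] == part.assignment[None, :]
    P = np.where(same, p_in, p_out)
    rng = np.random.default_rng([cfg.seed, layer])
    draws = rng.random((cfg.n, cfg.n))
    upper = np.triu(draws < P, k=1)
    A = (upper | upper.T).astype(float)
    return A, part


def _assemble(cfg: GnConfig) -> tuple[MultiNetwork, Partition]:
    layers = []
    part = cfg.planted_partition()
    for m in range(cfg.M):
        A, _ = generate_snapshot(cfg, m)
        layers.append(A)
    return MultiNetwork(layers), part


def generate_homo_net(cfg: GnConfig) -> tuple[MultiNetwork, Partition]:
    """M independent layers at one shared noise level, common planted truth."""
    if len(set(cfg.z_out)) != 1:
        raise ValueError("homogeneous net requires a single z_out level")
    return _assemble(cfg)


def generate_heter_net(
    cfg: GnConfig, z_fixed: float = 4.0, z_var: float = 1.0
) -> tuple[MultiNetwork, Partition]:
    """Layer 1 at noise ``z_fixed``; all remaining layers at ``z_var``."""
    if cfg.M < 2:
        raise ValueError("heterogeneous net needs at least 2 layers")
    cfg = replace(cfg, z_out=(z_fixed,) + (z_var,) * (cfg.M - 1))
    return _assemble(cfg)
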