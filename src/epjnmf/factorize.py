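"""Joint non-negative matrix tri-factorization of multilayer networks.

All M adjacency matrices are factorized simultaneously as

    W_m  ~=  B H F_m ,        B (n x k), H (k x k), F_m (k x n), all >= 0,

sharing the basis B and factor H across layers while each layer keeps its
own coefficient matrix F_m. The shared basis forces the k latent features
to explain every layer at once, which is what makes the extracted modules
*common* modules. The joint objective

    e(B, H, F) = sum_m || W_m - B H F_m ||_F^2

is minimized by cyclic multiplicative updates (one sweep updates B, then
H, then each F_m):

    B   <- B   * [sum_m W_m F_m' H'] / [B sum_m (H F_m)(H F_m)'] ,
    H   <- H   * [B' (sum_m W_m F_m')] / [B' B H sum_m F_m F_m'] ,
    F_m <- F_m * [H' B' W_m] / [H' B' B H F_m] ,

with elementwise products/divisions and denominators floored at
``DENOM_FLOOR``. Each update is the standard majorize-minimize
multiplicative rule for its block, so a sweep never increases the
objective, and an exactly factorizable input is a fixed point. Vertices
are assigned to modules by the argmax over each row of B.

The optimization is non-convex; ``fit`` therefore restarts from multiple
random strictly positive initializations and keeps the run with the
lowest final objective. One sweep costs O(k n^2 M).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .multinet import MultiNetwork, Partition

logger = logging.getLogger(__name__)

#: floor applied to multiplicative-rule denominators to avoid 0/0
DENOM_FLOOR = 1e-12


@dataclass
class FactorSet:
    """Non-negative factors of a joint tri-factorization.

    B is the shared n x k basis, H the shared k x k factor, and F a list
    of M per-layer k x n coefficient matrices.
    """

    B: np.ndarray
    H: np.ndarray
    F: list[np.ndarray]

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.F = [np.asarray(Fm, dtype=float) for Fm in self.F]
        n, k = self.B.shape
        if self.H.shape != (k, k):
            raise ValueError(f"H must be {k}x{k}, got {self.H.shape}")
        for m, Fm in enumerate(self.F):
            if Fm.shape != (k, n):
                raise ValueError(f"F[{m}] must be {k}x{n}, got {Fm.shape}")
        for name, mats in (("B", [self.B]), ("H", [self.H]), ("F", self.F)):
            for mat in mats:
                if np.any(mat < 0):
                    raise ValueError(f"factor {name} has negative entries")

    @property
    def k(self) -> int:
        return self.B.shape[1]

    def copy(self) -> "FactorSet":
        return FactorSet(self.B.copy(), self.H.copy(), [f.copy() for f in self.F])


@dataclass
class FitResult:
    """Outcome of one (multi-restart) optimization."""

    factors: FactorSet
    objective_trace: np.ndarray
    iterations: int
    seed: int | None
    partition: Partition
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def objective(net: MultiNetwork, fs: FactorSet) -> float:
    """Joint squared Frobenius reconstruction error sum_m ||W_m - B H F_m||^2."""
    if fs.B.shape[0] != net.n or len(fs.F) != net.M:
        raise ValueError(
            f"factor shapes (n={fs.B.shape[0]}, M={len(fs.F)}) do not match "
            f"network (n={net.n}, M={net.M})"
        )
    BH = fs.B @ fs.H
    return float(
        sum(
            np.linalg.norm(net.layer(m) - BH @ fs.F[m]) ** 2
            for m in range(net.M)
        )
    )


def _check_finite(mat: np.ndarray, which: str) -> None:
    if not np.all(np.isfinite(mat)):
        raise FloatingPointError(f"non-finite values produced by the {which} update")


def update_step(
    net: MultiNetwork, fs: FactorSet, update_h: bool = True
) -> FactorSet:
    """One full multiplicative sweep (B, then H, then each F_m).

    Returns a new FactorSet; the input is not modified. With
    ``update_h=False`` the factor H is left untouched (bi-factor mode,
    typically with H initialized to the identity).
    """
    W = [net.layer(m) for m in range(net.M)]
    B, H = fs.B.copy(), fs.H.copy()
    F = [Fm.copy() for Fm in fs.F]

    # B update: A_m = H F_m held fixed
    WFt = [W[m] @ F[m].T for m in range(net.M)]  # n x k, reused below
    num = sum(WFt[m] @ H.T for m in range(net.M))
    A_gram = sum((H @ F[m]) @ (H @ F[m]).T for m in range(net.M))
    B *= num / np.maximum(B @ A_gram, DENOM_FLOOR)
    _check_finite(B, "B")

    if update_h:
        num = B.T @ sum(WFt)
        F_gram = sum(Fm @ Fm.T for Fm in F)
        H *= num / np.maximum(B.T @ B @ H @ F_gram, DENOM_FLOOR)
        _check_finite(H, "H")

    BH = B @ H
    G = BH.T @ BH
    for m in range(net.M):
        F[m] *= (BH.T @ W[m]) / np.maximum(G @ F[m], DENOM_FLOOR)
        _check_finite(F[m], f"F[{m}]")

    return FactorSet(B, H, F)


def extract_modules(B: np.ndarray) -> Partition:
    """Assign each vertex to the column with its maximal basis loading.

    Ties go to the lowest column index. Columns that receive no vertex
    are dropped and module ids renumbered so the partition has no empty
    module; an all-zero row is assigned to module 1 with a warning.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2:
        raise ValueError("B must be an n x k matrix")
    if np.any(B < 0):
        raise ValueError("B must be non-negative")
    if np.any(np.all(B == 0, axis=1)):
        warnings.warn(
            "all-zero basis rows assigned to module 1", stacklevel=2
        )
    raw = B.argmax(axis=1)  # argmax takes the lowest index on ties
    kept = np.unique(raw)
    if kept.size < B.shape[1]:
        logger.info(
            "dropping %d empty module column(s); k reduced to %d",
            B.shape[1] - kept.size,
            kept.size,
        )
    remap = {old: new for new, old in enumerate(kept, start=1)}
    return Partition(assignment=np.array([remap[j] for j in raw]), k=kept.size)


#: off-diagonal mass of the initial H (strictly positive, near identity)
H_INIT_OFFDIAG = 0.05


def _init_factors(
    net: MultiNetwork, k: int, rng: np.random.Generator, use_h: bool
) -> FactorSet:
    """Random strictly positive factors respecting the symmetry of W.

    B is uniform on (0, 1] scaled by mean(W)^(1/3); each F_m starts at
    B.T (the layers are symmetric, so the stationary points have F_m
    close to a rescaled B.T); H starts at the identity plus a small
    strictly positive uniform perturbation. Strict positivity matters:
    multiplicative updates can never revive an entry initialized at
    zero. The near-identity H and symmetric warm start suppress the
    rotational degeneracy of the tri-factor parametrization, which
    otherwise traps a sizable fraction of restarts in local optima.
    """
    scale = max(float(np.mean([W.mean() for W in net.layers])), DENOM_FLOOR) ** (
        1.0 / 3.0
    )
    B = (1.0 - rng.random((net.n, k))) * scale  # uniform on (0, 1]
    if use_h:
        # scaled like B and F so the whole trajectory is equivariant
        # under W -> cW (every factor then carries a c^(1/3))
        H = (np.eye(k) + H_INIT_OFFDIAG * (1.0 - rng.random((k, k)))) * scale
    else:
        H = np.eye(k)
    F = [B.T.copy() for _ in range(net.M)]
    return FactorSet(B, H, F)


def fit(
    net: MultiNetwork,
    k: int,
    restarts: int = 50,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
    use_h: bool = True,
) -> FitResult:
    """Multi-restart joint tri-factorization with argmax module extraction.

    Parameters
    ----------
    net
        Multilayer network to factorize.
    k
        Number of latent features / modules, 2 <= k < n.
    restarts
        Independent random initializations; the restart with the lowest
        final objective wins.
    tol
        Convergence threshold on the relative per-sweep objective
        decrease ``(e_prev - e) / max(e_prev, DENOM_FLOOR)``.
    max_iter
        Sweep cap per restart.
    seed
        Master seed; restart r draws its factors from the stream derived
        from ``(seed, r)``, so results are reproducible and restarts
        independent.
    use_h
        If False, run the bi-factor variant W_m ~= B F_m (H pinned to the
        identity and never updated).
    """
    if not 2 <= k < net.n:
        raise ValueError(f"k must satisfy 2 <= k < n={net.n}, got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    best: FitResult | None = None
    for r in range(restarts):
        rng = (
            np.random.default_rng([seed, r])
            if seed is not None
            else np.random.default_rng()
        )
        fs = _init_factors(net, k, rng, use_h)
        trace = [objective(net, fs)]
        converged = False
        for _ in range(max_iter):
            fs = update_step(net, fs, update_h=use_h)
            trace.append(objective(net, fs))
            rel = (trace[-2] - trace[-1]) / max(trace[-2], DENOM_FLOOR)
            if rel < tol:
                converged = True
                break
        if best is None or trace[-1] < best.objective:
            best = FitResult(
                factors=fs,
                objective_trace=np.asarray(trace),
                iterations=len(trace) - 1,
                seed=seed,
                partition=extract_modules(fs.B),
                converged=converged,
            )
    assert best is not None
    return best
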