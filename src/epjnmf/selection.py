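"""Rank selection by the instability of matrix factorization.

NMF has no intrinsic criterion for the number of latent features k. The
stability heuristic exploits non-convexity itself: refit the model from
many independent random initializations and measure how much the
recovered bases disagree. At the true number of modules the basis columns
lock onto the planted structure and restarts agree (low instability);
under- or over-specified k forces arbitrary merges or splits that vary
from run to run (high instability). The selected k minimizes the mean
pairwise basis dissimilarity across restarts.

Dissimilarity between two bases is one minus the mean best-match column
cosine, symmetrized over both matching directions — 0 for bases equal up
to column permutation and positive rescaling, 1 for column-wise
orthogonal bases.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .factorize import fit
from .multinet import MultiNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InstabilityProfile:
    """Per-k instability of the factorization over random restarts."""

    k_values: tuple[int, ...]
    instability: tuple[float, ...]
    runs: int
    seed: int | None

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.k_values, self.instability))


def factor_dissimilarity(Ba: np.ndarray, Bb: np.ndarray) -> float:
    """Column-matching dissimilarity between two n x k bases, in [0, 1].

    Columns are L2-normalized, the k x k matrix C of column cosines is
    formed, and the result is ``1 - (sum_i max_j C_ij + sum_j max_i C_ij)
    / (2k)``. Invariant to column permutation and positive column
    rescaling of either basis; a zero column contributes zero cosines
    (with a warning).
    """
    Ba = np.asarray(Ba, dtype=float)
    Bb = np.asarray(Bb, dtype=float)
    if Ba.shape != Bb.shape:
        raise ValueError(f"shape mismatch: {Ba.shape} vs {Bb.shape}")
    k = Ba.shape[1]

    def normalize(B: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(B, axis=0)
        if np.any(norms == 0):
            warnings.warn("zero basis column; its cosines set to 0", stacklevel=3)
        return B / np.where(norms == 0, 1.0, norms)

    C = normalize(Ba).T @ normalize(Bb)
    return float(1.0 - (C.max(axis=1).sum() + C.max(axis=0).sum()) / (2 * k))


def instability(
    net: MultiNetwork,
    k: int,
    runs: int = 50,
    seed: int | None = None,
    **fit_kwargs,
) -> float:
    """Mean pairwise basis dissimilarity over single-restart fits.

    Each run uses a distinct RNG stream derived from ``(seed, k, run)``;
    extra keyword arguments are forwarded to :func:`~epjnmf.factorize.fit`.
    """
    if runs < 2:
        raise ValueError("instability needs at least 2 runs")
    bases = []
    for r in range(runs):
        run_seed = None if seed is None else _derive_seed(seed, k, r)
        try:
            res = fit(net, k, restarts=1, seed=run_seed, **fit_kwargs)
        except Exception as e:  # annotate which run failed
            raise RuntimeError(f"fit failed in instability run {r} (k={k})") from e
        bases.append(res.factors.B)
    pairs = list(itertools.combinations(bases, 2))
    return float(np.mean([factor_dissimilarity(a, b) for a, b in pairs]))


def _derive_seed(seed: int, k: int, run: int) -> int:
    # fold (seed, k, run) into one stream-defining integer below 2**31
    return int(np.random.SeedSequence([seed, k, run]).generate_state(1)[0] % (2**31))


def select_k(
    net: MultiNetwork,
    k_min: int = 2,
    k_max: int = 10,
    runs: int = 50,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[int, InstabilityProfile]:
    """Scan candidate k and return the one with minimal instability.

    Ties are broken toward the smaller k (logged when they occur).
    """
    if not 2 <= k_min < k_max < net.n:
        raise ValueError(
            f"need 2 <= k_min < k_max < n={net.n}, got [{k_min}, {k_max}]"
        )
    ks = list(range(k_min, k_max + 1))
    vals = [instability(net, k, runs=runs, seed=seed, **fit_kwargs) for k in ks]
    best = int(np.argmin(vals))  # first minimum -> smallest k on ties
    if vals.count(vals[best]) > 1:
        logger.info("instability tie at %.6g; choosing smallest k", vals[best])
    profile = InstabilityProfile(
        k_values=tuple(ks), instability=tuple(vals), runs=runs, seed=seed
    )
    return ks[best], profile
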