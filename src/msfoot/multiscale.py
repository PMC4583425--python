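"""Dyadic multiscale reparameterization of inhomogeneous Poisson intensities.

A per-base Poisson intensity vector ``mu`` of length ``L = 2**J`` is
equivalent to a total rate ``lambda0`` plus ``J`` scales of left/right split
probabilities ``p_jk``: scale 1 splits the window in half, scale 2 splits
each half into quarters, and so on down to adjacent base pairs at scale
``J``.  The Poisson likelihood of a count vector factorizes *exactly* into a
Poisson term for the total count and one binomial term per split, which is
what makes the hierarchical footprint model tractable: heterogeneity across
sites can be placed independently on each split probability.

The module provides the bijective transform in both directions, the dyadic
count pyramid (the sufficient statistics of the factorized likelihood), and
the factorized Poisson log-likelihood itself, whose exact agreement with the
plain per-base Poisson log-likelihood is the central correctness oracle of
the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MultiscaleParams",
    "CountPyramid",
    "PyramidStack",
    "forward_transform",
    "inverse_transform",
    "build_pyramid",
    "build_pyramid_stack",
    "stack_site",
    "factorized_poisson_loglik",
]


def _dyadic_depth(L: int) -> int:
    """Return J = log2(L), raising if L is not a power of two >= 2."""
    if L < 2 or (L & (L - 1)) != 0:
        raise ValueError(f"window length must be a power of 2 and >= 2, got {L}")
    return int(L).bit_length() - 1


@dataclass
class MultiscaleParams:
    """Total intensity plus dyadic split probabilities.

    Attributes
    ----------
    lambda0 : float
        Total intensity in the window (sum of per-base rates).
    p : list of ndarray
        ``p[j-1]`` holds the ``2**(j-1)`` split probabilities at scale ``j``
        (left-child mass over parent mass), ordered left to right.  A split
        whose parent carries zero mass is undefined and stored as ``nan``;
        the inverse transform maps it to two zero children.
    """

    lambda0: float
    p: list

    @property
    def J(self) -> int:
        return len(self.p)

    @property
    def L(self) -> int:
        return 2 ** len(self.p)

    @property
    def n_parameters(self) -> int:
        """1 (total) + 1 + 2 + ... + L/2 splits = L parameters in all."""
        return 1 + sum(len(pj) for pj in self.p)


@dataclass
class CountPyramid:
    """Dyadic sufficient statistics of one count vector.

    ``splits[j-1]`` is a ``(2**(j-1), 2)`` integer array of
    ``(parent_count, left_count)`` pairs at scale ``j``; ``total`` is the
    scale-0 sum.  At every node ``left <= parent`` and each parent equals
    the sum of its two children one scale down.
    """

    total: int
    splits: list

    @property
    def J(self) -> int:
        return len(self.splits)

    @property
    def L(self) -> int:
        return 2 ** len(self.splits)

    def reconstruct(self) -> np.ndarray:
        """Invert the pyramid back to the per-base count vector."""
        cur = np.array([self.total], dtype=np.int64)
        for pairs in self.splits:
            left = pairs[:, 1]
            right = pairs[:, 0] - left
            cur = np.empty(2 * len(left), dtype=np.int64)
            cur[0::2] = left
            cur[1::2] = right
        return cur


def forward_transform(mu: np.ndarray) -> MultiscaleParams:
    """Map a nonnegative intensity vector to (lambda0, split probabilities).

    Splits over a zero-mass parent are undefined and returned as ``nan``.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.ndim != 1:
        raise ValueError("mu must be one-dimensional")
    J = _dyadic_depth(mu.shape[0])
    if np.any(mu < 0):
        raise ValueError("intensities must be nonnegative")
    levels = [mu]
    for _ in range(J):
        levels.append(levels[-1][0::2] + levels[-1][1::2])
    levels = levels[::-1]  # levels[j] has 2**j sums; levels[0] = [lambda0]
    p = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(1, J + 1):
            parent = levels[j - 1]
            left = levels[j][0::2]
            pj = np.where(parent > 0, left / np.where(parent > 0, parent, 1.0), np.nan)
            p.append(pj)
    return MultiscaleParams(lambda0=float(mu.sum()), p=p)


def inverse_transform(params: MultiscaleParams) -> np.ndarray:
    """Map (lambda0, splits) back to the per-base intensity vector.

    ``nan`` splits are treated as zero-mass subtrees (both children zero),
    the only consistent limit; elsewhere the map is the exact inverse of
    :func:`forward_transform`.
    """
    cur = np.array([params.lambda0], dtype=float)
    for pj in params.p:
        pj = np.asarray(pj, dtype=float)
        if len(pj) != len(cur):
            raise ValueError("split array lengths do not form a dyadic pyramid")
        ok = ~np.isnan(pj)
        left = np.where(ok, cur * np.where(ok, pj, 0.0), 0.0)
        right = np.where(ok, cur - left, 0.0)
        cur = np.empty(2 * len(left), dtype=float)
        cur[0::2] = left
        cur[1::2] = right
    return cur


def build_pyramid(x: np.ndarray) -> CountPyramid:
    """Compute the dyadic count pyramid of a nonnegative count vector."""
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    x = x.astype(np.int64)
    J = _dyadic_depth(x.shape[0])
    levels = [x]
    for _ in range(J):
        levels.append(levels[-1][0::2] + levels[-1][1::2])
    levels = levels[::-1]
    splits = []
    for j in range(1, J + 1):
        parent = levels[j - 1]
        left = levels[j][0::2]
        splits.append(np.column_stack([parent, left]))
    return CountPyramid(total=int(x.sum()), splits=splits)


class PyramidStack:
    """Vectorized pyramids for an (N sites, S replicates, L bases) tensor.

    ``parents[j-1]`` and ``lefts[j-1]`` are ``(N, S, 2**(j-1))`` integer
    arrays; ``totals`` is ``(N, S)``.  The stack also caches the
    count-dependent log binomial coefficients and their per-site sum, which
    are constant in the model parameters.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts)
        if counts.ndim == 2:  # single replicate convenience
            counts = counts[:, None, :]
        if counts.ndim != 3:
            raise ValueError("counts must be (N, S, L) or (N, L)")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        counts = counts.astype(np.int64)
        self.N, self.S, self.L = counts.shape
        self.J = _dyadic_depth(self.L)
        levels = [counts]
        for _ in range(self.J):
            levels.append(levels[-1][..., 0::2] + levels[-1][..., 1::2])
        levels = levels[::-1]
        self.totals = levels[0][..., 0]
        self.parents = [levels[j - 1] for j in range(1, self.J + 1)]
        self.lefts = [levels[j][..., 0::2] for j in range(1, self.J + 1)]
        self._logbc_persite = None
        self._groups = None

    @property
    def shape(self):
        return (self.N, self.S, self.L)

    def logbc_persite(self) -> np.ndarray:
        """Per-site sum over replicates and nodes of log C(parent, left)."""
        if self._logbc_persite is None:
            from scipy.special import gammaln

            acc = np.zeros(self.N)
            for n, k in zip(self.parents, self.lefts):
                acc += (
                    gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                ).sum(axis=(1, 2))
            self._logbc_persite = acc
        return self._logbc_persite

    def node_groups(self):
        """Unique (parent, left) pairs per node, for aggregated M-steps.

        Returns a list over scales; entry ``j-1`` is a list over the scale's
        nodes of ``(parents_u, lefts_u, inverse)`` where ``inverse`` indexes
        the flattened (N*S,) observations into the unique pairs.
        """
        if self._groups is None:
            groups = []
            for n_arr, k_arr in zip(self.parents, self.lefts):
                per_scale = []
                K = n_arr.shape[2]
                base = int(n_arr.max()) + 2
                for k in range(K):
                    n_flat = n_arr[:, :, k].ravel()
                    k_flat = k_arr[:, :, k].ravel()
                    code = n_flat * base + k_flat
                    uniq, inv = np.unique(code, return_inverse=True)
                    per_scale.append((uniq // base, uniq % base, inv))
                groups.append(per_scale)
            self._groups = groups
        return self._groups


def build_pyramid_stack(counts: np.ndarray) -> PyramidStack:
    """Build vectorized dyadic pyramids for a count tensor."""
    return PyramidStack(counts)


def stack_site(pyramids: Sequence[CountPyramid]) -> PyramidStack:
    """Assemble one site's per-replicate pyramids into an N=1 stack."""
    rows = [p.reconstruct() for p in pyramids]
    return PyramidStack(np.asarray(rows)[None, :, :])


def factorized_poisson_loglik(x: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood via the multiscale factorization.

    Computes ``log Poisson(total | lambda0) + sum_nodes log Binomial(left |
    parent, p_jk)``, which equals the plain per-base Poisson log-likelihood
    exactly.  A base with ``mu == 0`` but ``x > 0`` (equivalently a
    zero-mass parent with a positive count) yields ``-inf``, returned as a
    value rather than raised.  Zero-count parents contribute exactly 0.
    """
    x = np.asarray(x)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape:
        raise ValueError("x and mu must have the same length")
    params = forward_transform(mu)
    pyr = build_pyramid(x)
    ll = float(stats.poisson.logpmf(pyr.total, params.lambda0))
    for pj, pairs in zip(params.p, pyr.splits):
        parent = pairs[:, 0]
        left = pairs[:, 1]
        active = parent > 0
        if not np.any(active):
            continue
        pa = pj[active]
        if np.any(np.isnan(pa)):
            return float("-inf")  # counts where the intensity carries no mass
        ll += float(stats.binom.logpmf(left[active], parent[active], pa).sum())
    return ll
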