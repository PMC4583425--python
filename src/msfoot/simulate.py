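"""Forward sampling from the generative footprint hierarchy.

Each site draws a binding indicator Z ~ Bernoulli(mix).  Per replicate, the
total rate lambda0 is gamma(alpha, alpha/lambda0_bar) for the site's
component, the window total is Poisson(lambda0), and the total is then
thinned down the dyadic pyramid: at every node a split probability is drawn
from Beta(p_bar*tau, (1-p_bar)*tau) for bound sites (or taken as the
constant 0.5 / drawn from the flexible-background beta for unbound sites)
and the left child is Binomial(parent, p).  Leaf k of the pyramid is base
pair k of the window.

RNG draw order is fixed and portable: the Z vector first, then for each
replicate in turn the gamma rates, the Poisson totals, and then one beta
vector (always drawn, for both components, so the stream does not depend on
Z), one flexible-background beta vector when applicable, and one binomial
vector per node, breadth-first and left-to-right.

``make_fixture`` provides canned parameter sets used throughout the test
suite and docs; their values are the package's reference study conditions
and are documented in :data:`FIXTURE_PROFILES`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .likelihoods import BoundParams, UnboundParams
from .multiscale import forward_transform

__all__ = [
    "SimulatedDataset",
    "simulate_dataset",
    "split_ratio_diagnostic",
    "SplitRatioDiagnostic",
    "make_fixture",
    "FIXTURE_PROFILES",
]


@dataclass
class SimulatedDataset:
    """Counts plus ground truth from one simulation run."""

    counts: np.ndarray  # (N, S, L) int64
    z_true: np.ndarray  # (N,) bool
    bound: BoundParams
    unbound: UnboundParams
    mix: float
    seed: Optional[int]
    latent: Optional[dict] = None  # lambda0 (N, S) and p per scale (N, S, K)

    @property
    def shape(self):
        return self.counts.shape

    def save(self, prefix: str):
        """Write counts/truth as NPZ plus a sidecar JSON of generator params."""
        np.savez(
            f"{prefix}.npz", counts=self.counts, z_true=self.z_true.astype(np.int8)
        )
        meta = {
            "bound": self.bound.to_dict(),
            "unbound": self.unbound.to_dict(),
            "mix": self.mix,
            "seed": self.seed,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str) -> "SimulatedDataset":
        arrs = np.load(f"{prefix}.npz")
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        return cls(
            counts=arrs["counts"],
            z_true=arrs["z_true"].astype(bool),
            bound=BoundParams.from_dict(meta["bound"]),
            unbound=UnboundParams.from_dict(meta["unbound"]),
            mix=float(meta["mix"]),
            seed=meta["seed"],
        )

    def export_tables(self, prefix: str, chrom: str = "chrSim"):
        """Write synthetic BED sites and per-replicate count TSVs.

        Windows are laid out non-overlapping along a synthetic chromosome so
        the files can exercise the BED/count readers end to end.
        """
        N, S, L = self.counts.shape
        with open(f"{prefix}.sites.bed", "w") as fh:
            for i in range(N):
                start = 1000 + i * 2 * L
                fh.write(f"{chrom}\t{start}\t{start + L}\tsite_{i}\t10.0\t+\n")
        for s in range(S):
            np.savetxt(
                f"{prefix}.counts.rep{s}.tsv", self.counts[:, s, :], fmt="%d",
                delimiter="\t",
            )
        with open(f"{prefix}.truth.tsv", "w") as fh:
            fh.write("name\tbound\n")
            for i, z in enumerate(self.z_true):
                fh.write(f"site_{i}\t{int(z)}\n")
        with open(f"{prefix}.params.json", "w") as fh:
            json.dump(
                {
                    "bound": self.bound.to_dict(),
                    "unbound": self.unbound.to_dict(),
                    "mix": self.mix,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )


def simulate_dataset(bound: BoundParams, unbound: UnboundParams, N: int, S: int,
                     L: int, mix: float, seed=None,
                     return_latent: bool = False) -> SimulatedDataset:
    """Sample N sites x S replicates x L bases from the full hierarchy."""
    if not 0.0 <= mix <= 1.0:
        raise ValueError(f"mix must lie in [0, 1], got {mix}")
    J = int(L).bit_length() - 1
    if 2**J != L:
        raise ValueError("L must be a power of 2")
    if bound.J != J:
        raise ValueError("bound params do not match the requested window")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    z = rng.random(N) < mix
    counts = np.empty((N, S, L), dtype=np.int64)
    lam_lat = np.empty((N, S)) if return_latent else None
    p_lat = [np.empty((N, S, 2**j)) for j in range(J)] if return_latent else None

    for s in range(S):
        shape = np.where(z, bound.alpha[s], unbound.alpha_o[s])
        mean = np.where(z, bound.lambda0_bar[s], unbound.lambda0_bar_o[s])
        lam0 = rng.gamma(shape, mean / shape)
        total = rng.poisson(lam0)
        if return_latent:
            lam_lat[:, s] = lam0
        cur = total[:, None]  # parents at the current scale, (N, 2**(j-1))
        for j in range(J):
            K = 2**j
            left = np.empty((N, K), dtype=np.int64)
            for k in range(K):
                a = bound.p_bar[j][k] * bound.tau[j]
                b = (1.0 - bound.p_bar[j][k]) * bound.tau[j]
                p = rng.beta(a, b, size=N)  # drawn for every site; masked below
                if unbound.flexbg:
                    ao = unbound.p_bar_o[j][k] * unbound.tau_o[j]
                    bo = (1.0 - unbound.p_bar_o[j][k]) * unbound.tau_o[j]
                    p_un = rng.beta(ao, bo, size=N)
                else:
                    p_un = 0.5
                p = np.where(z, p, p_un)
                left[:, k] = rng.binomial(cur[:, k], p)
                if return_latent:
                    p_lat[j][:, s, k] = p
            right = cur - left
            cur = np.empty((N, 2 * K), dtype=np.int64)
            cur[:, 0::2] = left
            cur[:, 1::2] = right
        counts[:, s, :] = cur

    latent = None
    if return_latent:
        latent = {"lambda0": lam_lat, "p": p_lat}
    return SimulatedDataset(
        counts=counts, z_true=z, bound=bound, unbound=unbound, mix=float(mix),
        seed=None if isinstance(seed, np.random.Generator) else seed, latent=latent,
    )


@dataclass
class SplitRatioDiagnostic:
    """Observed vs binomial-resimulated half-window cut ratios.

    Under a fixed-profile (multinomial) model the left-half count of each
    site is Binomial(total, pooled ratio); excess spread of the observed
    ratios over the resimulated ones is the overdispersion signature of
    cross-site heterogeneity.
    """

    observed: np.ndarray
    expected: np.ndarray
    pooled_ratio: float
    n_excluded: int

    @property
    def variance_ratio(self) -> float:
        """var(observed) / var(expected); nan when fewer than two sites."""
        if len(self.observed) < 2:
            return float("nan")
        return float(np.var(self.observed) / np.var(self.expected))


def split_ratio_diagnostic(counts: np.ndarray, window=None,
                           seed=None) -> SplitRatioDiagnostic:
    """Per-site left-half/total cut ratios and their binomial expectation.

    ``counts`` is (N, L) — pass one replicate or a replicate sum.  ``window``
    optionally restricts to a (start, stop) base range.  Zero-total sites
    are excluded and counted; with fewer than two usable sites the variance
    ratio is undefined (nan) and a warning is raised.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be (N, L); sum or select replicates first")
    if window is not None:
        start, stop = window
        counts = counts[:, start:stop]
    W = counts.shape[1]
    left = counts[:, : W // 2].sum(axis=1)
    total = counts.sum(axis=1)
    keep = total > 0
    n_excluded = int((~keep).sum())
    left, total = left[keep], total[keep]
    if len(total) < 2:
        warnings.warn("fewer than two sites with counts; variance undefined")
    pooled = float(left.sum() / total.sum()) if total.sum() > 0 else float("nan")
    observed = left / total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = rng.binomial(total, pooled) / total
    return SplitRatioDiagnostic(
        observed=observed, expected=expected, pooled_ratio=pooled,
        n_excluded=n_excluded,
    )


def _footprint_profile(L: int, depth: float) -> np.ndarray:
    """Mean cleavage intensity: hypersensitive shoulders, central dip.

    ``depth`` in [0, 1) scales the protection at the motif center; a slight
    left/right tilt keeps the profile generic (real footprints are rarely
    perfectly symmetric).
    """
    x = np.arange(L, dtype=float)
    c = (L - 1) / 2.0
    shoulders = 1.0 + 1.5 * np.exp(-(((x - c) / (L / 3.5)) ** 2))
    dip = 1.0 - depth * np.exp(-(((x - c) / (L / 9.0)) ** 2))
    tilt = 1.0 + 0.15 * (x - c) / L
    return shoulders * dip * tilt


def _tau_profile(J: int, base: float = 8.0) -> np.ndarray:
    """Scale precisions, smallest (most heterogeneity) at medium scales."""
    j = np.arange(1, J + 1, dtype=float)
    mid = (J + 1) / 2.0
    span = max((J - 1) / 2.0, 1.0)
    return base * 4.0 ** (np.abs(j - mid) / span)


def _profile_p_bar(L: int, depth: float):
    mu = _footprint_profile(L, depth)
    p = forward_transform(mu).p
    return [np.clip(pj, 0.02, 0.98) for pj in p]


#: Canned study conditions for the test suite and docs.  Each entry gives the
#: default (N, S, mix) and the component hyperparameters; ``lambda0_bar`` is
#: per replicate and is cycled when more replicates are requested.
FIXTURE_PROFILES = {
    "footprint_strong": dict(
        N=1000, S=2, L=64, mix=0.4, depth=0.8,
        alpha=(4.0, 4.0), lambda0_bar=(20.0, 20.0),
        alpha_o=(2.0, 2.0), lambda0_bar_o=(8.0, 8.0), tau_base=8.0,
    ),
    "footprint_weak": dict(
        N=1000, S=2, L=64, mix=0.4, depth=0.35,
        alpha=(4.0, 4.0), lambda0_bar=(12.0, 12.0),
        alpha_o=(2.0, 2.0), lambda0_bar_o=(8.0, 8.0), tau_base=8.0,
    ),
    "no_footprint": dict(
        N=1000, S=2, L=64, mix=0.4, depth=None,  # uniform splits, tau -> inf
        alpha=(4.0, 4.0), lambda0_bar=(20.0, 20.0),
        alpha_o=(2.0, 2.0), lambda0_bar_o=(8.0, 8.0), tau_base=1e6,
    ),
    "heterogeneous_replicates": dict(
        N=1000, S=2, L=64, mix=0.4, depth=0.8,
        alpha=(4.0, 4.0), lambda0_bar=(40.0, 10.0),  # 4-fold depth contrast
        alpha_o=(2.0, 2.0), lambda0_bar_o=(16.0, 4.0), tau_base=8.0,
    ),
}


def _cycle(values, S):
    values = list(values)
    return np.array([values[s % len(values)] for s in range(S)], dtype=float)


def fixture_params(profile_name: str, S: Optional[int] = None,
                   L: Optional[int] = None):
    """Generator parameters of a canned profile (without sampling)."""
    if profile_name not in FIXTURE_PROFILES:
        raise ValueError(
            f"unknown profile {profile_name!r}; choose from {sorted(FIXTURE_PROFILES)}"
        )
    spec = FIXTURE_PROFILES[profile_name]
    S = S or spec["S"]
    L = L or spec["L"]
    J = int(L).bit_length() - 1
    if spec["depth"] is None:
        p_bar = [np.full(2**j, 0.5) for j in range(J)]
        tau = np.full(J, spec["tau_base"])
    else:
        p_bar = _profile_p_bar(L, spec["depth"])
        tau = _tau_profile(J, spec["tau_base"])
    bound = BoundParams(
        p_bar=p_bar, tau=tau,
        alpha=_cycle(spec["alpha"], S), lambda0_bar=_cycle(spec["lambda0_bar"], S),
    )
    unbound = UnboundParams(
        alpha_o=_cycle(spec["alpha_o"], S),
        lambda0_bar_o=_cycle(spec["lambda0_bar_o"], S),
    )
    return bound, unbound, spec


def make_fixture(profile_name: str, seed=None, N: Optional[int] = None,
                 S: Optional[int] = None, L: Optional[int] = None,
                 mix: Optional[float] = None,
                 return_latent: bool = False) -> SimulatedDataset:
    """Sample one of the canned datasets; same seed gives identical data."""
    bound, unbound, spec = fixture_params(profile_name, S, L)
    return simulate_dataset(
        bound, unbound,
        N=N or spec["N"], S=S or spec["S"], L=L or spec["L"],
        mix=spec["mix"] if mix is None else mix,
        seed=seed, return_latent=return_latent,
    )
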