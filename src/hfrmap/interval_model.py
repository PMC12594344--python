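"""Interval-intersection model of the shared donor region.

Every selected recombinant carries a donor fragment covering the selected
locus. Modelling those fragments as i.i.d. intervals whose positions are
uniform given coverage of the marker, the region where donor DNA is present
in *all* n recombinants is

    Lambda_n = min_i(U_i) + min_i(L_i - U_i),

where L_i is the fragment length and U_i, uniform on [0, L_i), the left
overhang of fragment i over the marker. For large n the expectation obeys

    E(Lambda_n) ~ 2 * mu / n,      mu = 1 / E(1/L),

the harmonic mean of the marker-covering fragment lengths. Because mu is
dominated by short fragments, a minority of kb-scale tracts sharpens the
mapping resolution dramatically — the quantitative basis for the observed
~kb localisation precision of pooled selection mapping.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import FragmentLengthDistribution, harmonic_mean

__all__ = [
    "SharedRegionExperiment",
    "SharedRegionResult",
    "harmonic_mean",
    "simulate_shared_region",
    "expected_shared_region",
]


@dataclass(frozen=True)
class SharedRegionExperiment:
    """Monte-Carlo design: n selected recombinants, fragment-length law, replicates."""

    n: int
    dist: FragmentLengthDistribution
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class SharedRegionResult:
    """Per-replicate shared-region lengths and summaries (bases)."""

    lambda_samples: np.ndarray
    mean_lambda: float
    harmonic_mean_mu: float
    analytic_expectation: float

    @property
    def normalized_constant(self) -> float:
        """n * mean(Lambda_n) / mu; tends to 2 for large n."""
        return self._n * self.mean_lambda / self.harmonic_mean_mu

    _n: int = 1


def simulate_shared_region(exp: SharedRegionExperiment) -> SharedRegionResult:
    """Simulate Lambda_n = |intersection of n marker-covering fragments|.

    Per replicate, draws n lengths L_i from ``exp.dist`` and overhangs
    U_i ~ Uniform[0, L_i); fragment i is [marker - U_i, marker + L_i - U_i)
    and Lambda_n = min(U_i) + min(L_i - U_i). Genome edge effects are
    ignored (fragments are assumed small relative to the genome).
    """
    rng = np.random.default_rng(exp.seed)
    lam = np.empty(exp.n_reps)
    mu = exp.dist.harmonic_mean()
    # vectorised over replicates in manageable chunks
    chunk = max(1, int(5e6) // max(exp.n, 1))
    done = 0
    while done < exp.n_reps:
        m = min(chunk, exp.n_reps - done)
        lengths = exp.dist.sample(rng, m * exp.n).reshape(m, exp.n)
        u = rng.uniform(0.0, 1.0, size=(m, exp.n)) * lengths
        lam[done : done + m] = u.min(axis=1) + (lengths - u).min(axis=1)
        done += m
    res = SharedRegionResult(
        lambda_samples=lam,
        mean_lambda=float(lam.mean()),
        harmonic_mean_mu=mu,
        analytic_expectation=expected_shared_region(exp.dist, exp.n),
    )
    res._n = exp.n
    return res


def expected_shared_region(dist: FragmentLengthDistribution, n: int) -> float:
    """Large-n expectation 2*mu/n of the shared donor region length.

    Exact asymptotically; at small n it over- or under-shoots depending on
    the length law (Lambda_1 = E(L), and for fixed L, E(Lambda_2) = 2L/3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * dist.harmonic_mean() / n
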