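"""Shared fixtures and independent numerical oracles.

The oracles here are deliberately naive (direct series summation,
exact rational enumeration, closed-form normal equations) so they stay
independent of the scipy/statsmodels code paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction
from types import SimpleNamespace

import pytest
from hypothesis import settings

from bacm6a import gene_context as gc
from bacm6a import peaks as pk
from bacm6a import synthetic_data as syn

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def poisson_tail_oracle(k: int, lam: float) -> float:
    """Upper tail P(X >= k) by direct term-by-term summation.

    Sums the tail forward from the k-th term (no 1-minus cancellation),
    starting from the log-space term to stay finite for large k.
    """
    if k == 0:
        return 1.0
    log_term = k * math.log(lam) - lam - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > 0 and (i == k or term > total * 1e-18):
        total += term
        i += 1
        term *= lam / i
    return total


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact rational P(X >= k) for X ~ hypergeometric(N, K, n)."""
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if 0 <= n - x <= N - K
    )
    return Fraction(num, denom)


def ols_oracle(points) -> tuple[float, float]:
    """Closed-form normal-equations solution for a 1-D least squares line."""
    n = len(points)
    sx = sum(p[0] for p in points)
    sy = sum(p[1] for p in points)
    sxx = sum(p[0] ** 2 for p in points)
    sxy = sum(p[0] * p[1] for p in points)
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    return slope, intercept


@pytest.fixture(scope="session")
def default_sim():
    """The default seeded simulation: 10 genes, 20 planted sites,
    enrichment 10, 50,000 reads per library."""
    genome = syn.generate_genome(10, seed=1)
    sites = syn.plant_sites(genome, 20, seed=3)
    ip, inp = syn.simulate_reads(
        genome, sites, n_input_reads=50_000, enrichment_factor=10.0, seed=5
    )
    peaks = pk.call_peaks(ip, inp)
    for p in peaks:
        p.gene_id = gc.assign_gene(p, genome.genes)
        if p.gene_id is not None:
            gene = genome.gene(p.gene_id)
            p.context = gc.classify_context(p, gene)
    return SimpleNamespace(
        genome=genome, sites=sites, ip=ip, input=inp, peaks=peaks
    )
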