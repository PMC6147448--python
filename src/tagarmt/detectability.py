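"""Binomial detectability of mtDNA clusters in a finite sample.

A cluster at population frequency p is entirely absent from a sample of N
individuals with probability (1 - p)^N.  Solving (1 - p)^N = alpha for p
gives the smallest frequency at which a cluster is unlikely (at level
alpha) to be missed: p = 1 - alpha^(1/N).  Full precision is kept
internally; round only for display.
"""

from __future__ import annotations


def min_detectable_frequency(n: int, alpha: float = 0.05) -> float:
    """Smallest cluster frequency with miss probability <= alpha."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return 1.0 - alpha ** (1.0 / n)


def miss_probability(p: float, n: int) -> float:
    """Probability that a cluster at frequency p is absent from a sample of n."""
    if not 0 < p < 1:
        raise ValueError("frequency must lie in (0, 1)")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return (1.0 - p) ** n
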